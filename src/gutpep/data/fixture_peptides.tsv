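sequence	activities	source_id
KA	ACE inhibitor;inhibitor	fixture
IA	ACE inhibitor	fixture
LF	ACE inhibitor	fixture
QK	ACE inhibitor	fixture
GM	ACE inhibitor	fixture
RL	ACE inhibitor	fixture
VE	ACE inhibitor	fixture
AA	ACE inhibitor	fixture
PR	ACE inhibitor	fixture
LY	ACE inhibitor;antioxidative	fixture
AW	ACE inhibitor	fixture
EK	ACE inhibitor	fixture
EY	ACE inhibitor	fixture
AR	ACE inhibitor	fixture
KP	ACE inhibitor;antioxidative	fixture
VR	ACE inhibitor	fixture
VPK	ACE inhibitor	fixture
VK	ACE inhibitor	fixture
NY	ACE inhibitor	fixture
VF	ACE inhibitor	fixture
TF	ACE inhibitor	fixture
NF	ACE inhibitor	fixture
HL	ACE inhibitor;antioxidative	fixture
PLP	ACE inhibitor	fixture
GPFPIIV	ACE inhibitor	fixture
EMPFPK	ACE inhibitor	fixture
HK	ACE inhibitor	fixture
VY	ACE inhibitor;antioxidative	fixture
KE	ACE inhibitor	fixture
YAEERYPIL	ACE inhibitor	fixture
KG	ACE inhibitor	fixture
LW	ACE inhibitor	fixture
GR	ACE inhibitor	fixture
VPP	ACE inhibitor	fixture
IPP	ACE inhibitor	fixture
LV	stimulating	fixture
LL	stimulating;inhibitor	fixture
LI	stimulating	fixture
LHT	antioxidative	fixture
LK	antioxidative	fixture
TY	antioxidative	fixture
EL	antioxidative	fixture
EF	inhibitor;hypotensive	fixture
VA	inhibitor	fixture
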