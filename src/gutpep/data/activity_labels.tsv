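label	code
antiamnestic	1
ACE	2
ACE inhibitor	2
ACE-inhibitor	2
angiotensin converting enzyme inhibitor	2
antithrombotic	3
stimulating	4
glucose uptake stimulating	4
vasoactive substance release stimulating	4
regulating	5
ion flow regulating	5
stomach mucosal membrane activity regulating	5
phosphoinositol mechanism peptide	5
antioxidative	6
antioxidant	6
bacterial permease ligand	7
inhibitor	8
dipeptidyl peptidase IV inhibitor	8
DPP-IV inhibitor	8
dipeptidyl aminopeptidase IV inhibitor	8
dipeptidyl carboxypeptidase inhibitor	8
CaMPDE inhibitor	8
cyclic nucleotide phosphodiesterase inhibitor	8
neuropeptide inhibitor	8
hypotensive	9
activating ubiquitin mediated proteolysis	10
ubiquitin mediated proteolysis activating	10
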