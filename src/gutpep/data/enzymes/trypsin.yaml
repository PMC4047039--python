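# Trypsin cleavage specificity (Keil-style rules as applied by the common
# peptide-cutting tools). Offsets are relative to the scissile bond:
# -1 = P1, +1 = P1', -2 = P2. A leading "^" on a residue string means the
# complement within the 20-letter alphabet.
name: trypsin
rules:
  - kind: permit
    conditions: {-1: "KR", +1: "^P"}
  - kind: exception_permit
    conditions: {-2: "W", -1: "K", +1: "P"}
  - kind: exception_permit
    conditions: {-2: "M", -1: "R", +1: "P"}
  - kind: exception_block
    conditions: {-2: "C", -1: "K", +1: "D"}
  - kind: exception_block
    conditions: {-2: "D", -1: "K", +1: "D"}
  - kind: exception_block
    conditions: {-2: "C", -1: "K", +1: "H"}
  - kind: exception_block
    conditions: {-2: "C", -1: "K", +1: "Y"}
  - kind: exception_block
    conditions: {-2: "C", -1: "R", +1: "K"}
  - kind: exception_block
    conditions: {-2: "R", -1: "R", +1: "H"}
  - kind: exception_block
    conditions: {-2: "R", -1: "R", +1: "R"}
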