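# Chymotrypsin, high specificity: cleaves after the aromatic residues
# F/Y/W, not before proline; W-M bonds resist cleavage.
name: chymotrypsin_high
rules:
  - kind: permit
    conditions: {-1: "FYW", +1: "^P"}
  - kind: exception_block
    conditions: {-1: "W", +1: "MP"}
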