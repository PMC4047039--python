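# Pepsin at pH > 2: broader aromatic/hydrophobic P1 (F, L, W, Y), same
# proline exceptions as the pH 1.3 table.
name: pepsin_ph_gt2
rules:
  - kind: permit
    conditions: {-1: "FLWY"}
  - kind: exception_block
    conditions: {+1: "P"}
  - kind: exception_block
    conditions: {-2: "P"}
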