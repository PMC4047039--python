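# Pepsin at pH 1.3 (fasted gastric pH): cleaves after F or L; proline at
# P1' or P2 prevents cleavage. A compact stand-in for Keil's full
# statistical matrix capturing its dominant hydrophobic-P1,
# proline-disfavoured specificity; replaceable by a fuller transcription
# without code changes.
name: pepsin_ph1.3
rules:
  - kind: permit
    conditions: {-1: "FL"}
  - kind: exception_block
    conditions: {+1: "P"}
  - kind: exception_block
    conditions: {-2: "P"}
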