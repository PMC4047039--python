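# Chymotrypsin, low specificity: additionally cleaves after L, M and H,
# with the extra M-Y and H-{D,M,P,W} exceptions.
name: chymotrypsin_low
rules:
  - kind: permit
    conditions: {-1: "FYWLMH", +1: "^P"}
  - kind: exception_block
    conditions: {-1: "W", +1: "MP"}
  - kind: exception_block
    conditions: {-1: "M", +1: "Y"}
  - kind: exception_block
    conditions: {-1: "H", +1: "DMPW"}
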