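# Model diet: ~40 g protein/day for a healthy 60 kg adult, split across
# five protein-containing food groups; each group is represented by the
# bundled study proteins listed under `proteins` (mg/g for a multi-protein
# item is the unweighted mean over its members).
items:
  - name: Dairy
    grams_protein_per_day: 4
    proteins: [P02666]
  - name: Wheat products
    grams_protein_per_day: 14
    proteins: [P02863, P10385]
  - name: Soya products
    grams_protein_per_day: 3
    proteins: [P04347]
  - name: Chicken egg products
    grams_protein_per_day: 6
    proteins: [P01012]
  - name: Chicken meat
    grams_protein_per_day: 13
    proteins: [P60706, P13538]
# Gut endogenous protein secreted into the lumen per day (excluding
# microbial protein and sloughed cells), and the proteins whose mean mg/g
# represents the endogenous pool.
endogenous:
  grams_protein_per_day: 48.0
  proteins: [Q02817, P02768, P00790, P01350, P61626]
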