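# gutpep

In silico prediction of the bioactive peptides released by
gastrointestinal digestion of dietary and gut endogenous proteins.

Food proteins are an established source of latent bioactive peptides —
short sequences (2 to >40 residues) that, once freed by digestion, can
act as ACE inhibitors, antioxidants, DPP-IV inhibitors and more. Gut
*endogenous* proteins (mucins, serum albumin, digestive enzymes, gut
hormones) represent an even larger and more constant protein supply to
the gut lumen, and the same question applies to them. `gutpep` answers
it computationally for any protein with a known mature sequence:

1. **Rule-based digestion.** Pepsin, trypsin and chymotrypsin are
   modelled as declarative cleavage-rule tables over the P2–P2′ window of
   each peptide bond (e.g. trypsin: cut after K/R, not before P, with the
   classical exception rules). A protein is digested under the scenario
   its secretion site dictates — *gastric* (pepsin) and *gastric + small
   intestinal* (all three enzymes) for dietary and mouth/stomach-secreted
   proteins, *small intestinal only* (trypsin + chymotrypsin) for
   proteins entering at the intestinal level. Digestion is exhaustive:
   the cut set is the union of per-enzyme sites on the intact chain.
2. **Reference matching and frequency statistics.** Against a reference
   table of known bioactive peptides, the intact chain is scanned for
   every (overlapping) occurrence, and digest fragments are matched by
   full-sequence equality (a peptide still buried inside a longer
   fragment is not "released"). Three statistics summarise a protein of
   length *N*:

   - `A_O = round(1000 · a_O / N)` — occurrences of known bioactive
     sequences per 1000 residues of the intact chain;
   - `Y_j = round(100 · a_Oj / a_O)` — the share (%) of activity
     category *j* among all occurrences;
   - `A_D = round(1000 · a_D / N)` — distinct bioactive peptides
     released per 1000 residues after digestion.
3. **Daily quantities.** Treating each released peptide as a reference
   dipeptide (~255.8 Da), a protein releasing *n* peptides per molecule
   of molar mass *M* yields `n · 255.8 / M · 1000` mg of bioactive
   peptide per g of protein; a configurable model diet (~40 g
   protein/day) and a gut endogenous secretion pool (~48 g/day) convert
   this to mg/day.

The package ships the 33-protein registry of the underlying study
(accessions, secretion sites, mature chain lengths), the mature bovine
β-casein chain (P02666), five enzyme rule tables, a small curated
fixture of released bioactive peptides, and a synthetic-study generator
that plants peptides with provable release status for end-to-end
validation. It is a library first (`import gutpep`), with a thin
`gutpep` CLI (`digest`, `scan`, `profile`, `quantity`, `synth`) for
shell use.

## Worked example

```python
from gutpep import SCENARIOS, beta_casein_record, digest, fixture_db, match_digest

record = beta_casein_record()                    # P02666, 209 residues
frags = digest(record.sequence, SCENARIOS["gastric_plus_small_intestinal"])
profile = match_digest(frags, fixture_db(), accession=record.accession)
print(profile.released_sequences, profile.total_released, profile.AD)
```

prints

```
('EL', 'EMPFPK', 'GPFPIIV', 'HK', 'VK') 5 24
```

— after combined gastric and small-intestinal digestion, five distinct
known bioactive peptides (four ACE-inhibitory, one antioxidative) are
predicted to be released from β-casein, i.e. `A_D = 24` per 1000
residues. The antihypertensive precursors VPP and IPP are present in the
intact chain but are *not* released — consistent with their requiring
fermentation rather than gastrointestinal proteolysis. Running
`python examples/daily_quantity.py` continues the story to quantities:
β-casein's computed yield is 86.8 mg/g (M = 23 583 Da, 8 released
peptides per molecule), and the model diet totals ≈1.8 g of bioactive
peptides per day from dietary protein versus ≈2.7 g from the gut
endogenous pool.

Each script in `examples/` demonstrates one capability (digestion,
intact scanning, full profiling, quantities, synthetic validation) and
prints a short interpretation of its numbers.

Counts computed against the bundled fixture database are necessarily
much smaller than counts computed against a full bioactive-peptide
reference snapshot; supply your own export via `--peptide-db` /
`RunConfig(peptide_db=...)` for realistic profiling.

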