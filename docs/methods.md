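# Methods

## Digestion model

Proteolysis is modelled on the primary sequence alone. An enzyme is an
ordered list of declarative rules over a window of residues around each
candidate peptide bond, indexed in protease nomenclature (−1 = P1,
+1 = P1′, −2 = P2, …, bounded to ±4). Rule kinds are `permit`,
`exception_permit` and `exception_block`; a bond is cut iff some permit
or exception-permit fires and no exception-block fires. A condition
whose offset falls outside the chain makes its rule fail regardless of
kind: missing context can neither license nor veto a cut.

The bundled tables are:

* **trypsin** — permit P1 ∈ {K,R} with P1′ ≠ P; exception-permits
  W‑K‑P and M‑R‑P; exception-blocks [C/D]‑K‑D, C‑K‑H, C‑K‑Y, C‑R‑K,
  R‑R‑H, R‑R‑R. This is the classical Keil-derived rule set used by the
  standard peptide-cutting tools.
* **chymotrypsin_high** (default `chymotrypsin`) — P1 ∈ {F,Y,W},
  P1′ ≠ P, with W‑M blocked; **chymotrypsin_low** adds P1 ∈ {L,M,H}
  with M‑Y and H‑{D,M,P,W} blocked. High specificity is the default
  because it is the conservative choice when the variant is unknown.
* **pepsin_ph1.3** (default `pepsin`) — P1 ∈ {F,L} with proline at P1′
  or P2 blocking; **pepsin_ph_gt2** widens P1 to {F,L,W,Y}. These are
  deliberately compact tables capturing pepsin's dominant
  hydrophobic-P1, proline-disfavoured behaviour; pepsin's true
  specificity is a statistical positional matrix, and because the
  tables are plain data files a fuller transcription can be dropped in
  without code changes. Consequences of the compact form are visible in
  edge cases: e.g. β-casein's PLP stays buried inside an HLPLPLL
  fragment here, whereas matrix-based tools can liberate it. pH 1.3 is
  the default as the fasted-stomach condition.

Digestion is exhaustive and kinetics-free: no missed cleavages, no
efficiencies, no exopeptidase trimming. A multi-enzyme scenario cuts at
the union of per-enzyme sites computed on the *intact* chain, which
makes the result independent of enzyme order, makes smaller scenarios
produce coarser fragmentations of the same cut set (monotonicity), and
makes re-examining fragments in intact-chain context produce no new
cuts (idempotence). Fragments carry 1-based inclusive coordinates and
always tile the input exactly.

## Scenario assignment

Scenarios are a pure function of (origin, secretion sites): dietary →
gastric then gastric+small-intestinal; endogenous with mouth/stomach
sites → the same; endogenous with small-intestine/pancreas/duodenum/
colon sites → small-intestinal only; both levels → all three. Registry
rows may carry an explicit override for hormones whose single
descriptive site under-determines the set actually applicable (secretin
and promotilin are secreted at the intestinal level but also act on the
stomach and are treated as exposed to all three scenarios; mucin-5AC,
reaching only the proximal duodenum, is treated as gastric-level only).

## Counting rules

* **Intact scan**: every occurrence of every reference peptide counts,
  overlapping occurrences at distinct start positions count separately,
  and a peptide with k activity categories contributes its occurrences
  to all k per-category counts; the total `a_O` sums over all
  categories. This matches the published overall-frequency convention
  (e.g. 2250 occurrences in the 5159-residue mucin-2 giving an overall
  A_O of 436).
* **Digest matching**: a fragment matches only by full-sequence
  equality. The total `a_D` counts distinct matched sequences once
  each; per-category counts are reported in two modes — `unique`
  (distinct sequences, the default) and `occurrence` (fragment
  instances) — because published per-category release counts are
  internally ambiguous about deduplication. Neither mode claims to
  reproduce historical per-category tables count-for-count, which would
  in any case require the original reference-database snapshot.
* **Rounding**: A_O, A_D (×1000/N) and Y (×100/total) round to the
  nearest integer, half away from zero. The scalings are forced by all
  published count/value pairs.

## Quantity model

Released peptides are predominantly dipeptides, so mass conversion uses
a reference peptide of length 2 and mean composition: 2 × mean of the
20 free amino-acid average masses − one water = 255.8 Da (configurable
via `MassModel`, including the reference length). Protein molar masses
are average masses (residue sum + 18.02 Da water); the resulting
β-casein mass, 23 583 Da, reproduces the published 87 mg/g at 8
released peptides per molecule. The bundled model diet contributes
4/14/3/6/13 g protein per day from dairy/wheat/soya/egg/chicken-meat
groups; multi-protein groups use the unweighted mean of their member
proteins' mg/g. The endogenous pool defaults to 48 g protein/day — the
value implied by the published mean yield (56 mg/g) and daily total
(2689 mg/d); with these inputs the package computes 2688 mg/d, the
1 mg discrepancy being rounding in the published inputs.

## Synthetic data

`generate_study` builds proteins, a reference table and a ground-truth
manifest with three guarantees, all enforced by running the real
digestion/matching code post hoc (a violation triggers regeneration
from a spawned sub-seed):

* releasable plants are flanked by forced cleavage sites (e.g. G‑R
  before a tryptic plant, a G after its cleavable C-terminus) and
  contain no internal site, so exhaustive digestion liberates them
  exactly;
* non-releasable plants sit behind a residue no scenario enzyme cuts
  after, so they stay buried;
* background residues come from an alphabet with no cleavage P1
  residues (G,A,S,T,N,Q,E,V,I,D), and generated reference peptides end
  in a K the background never contains and are never suffixes of one
  another, so no reference peptide occurs outside the manifest.

This yields recall and precision of exactly 1.0 for the full pipeline
on synthetic studies — a correctness check, not evidence about real
proteins: the generator does not emulate realistic amino-acid
composition, reference-database content, or the dense cleavage-site
landscape of natural sequences. All randomness flows from one integer
master seed through numpy `SeedSequence` spawning, so regeneration is
byte-identical. Defaults (5 proteins of ≥120 residues, 20 reference
peptides of 2–9 residues — the released-peptide length range seen in
practice — plant rate 0.5) keep every test and example sub-second.

## Design choices and limitations

* Ambiguity codes (B/Z/X/U) are rejected by default and, on opt-in,
  treated as inert (never cleavable, never matching), since curated
  mature chains should not contain them.
* FASTA inputs are assumed to be mature chains; a length mismatch
  against the registry warns rather than truncating. Initiator
  methionine is kept when present.
* The bundled fixture database is a small curated set of released
  bioactive peptides (44 entries, mostly ACE-inhibitory di/tripeptides,
  plus the fermentation-only VPP/IPP); absolute per-protein counts
  against it are not comparable to counts against a full reference
  snapshot, which the user must supply for realistic profiling.
* Unmapped activity labels become open-ended OTHER categories rather
  than errors; only the ten tabulated categories have numeric codes.
* Out of scope by design: cleavage kinetics and probabilities, partial
  digestion, brush-border exopeptidases, tertiary-structure and
  food-processing effects, microbial and sloughed-cell protein,
  absorption/bioavailability, and any bioactivity efficacy claims.
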