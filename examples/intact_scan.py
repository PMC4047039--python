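"""Count known bioactive peptides buried in an intact protein chain.

The A_O statistic scales the occurrence count per 1000 residues; Y gives
each activity category's share (%) of all occurrences. Counts here use
the small bundled fixture database, so they are far below values computed
against a full reference snapshot.
"""

from gutpep import beta_casein_record, fixture_db, scan_intact
from gutpep.biodb import CATEGORY_DESCRIPTIONS

record = beta_casein_record()
db = fixture_db()
profile = scan_intact(record, db)

print(f"{record.name}: N = {profile.chain_length} residues")
print(f"total occurrences a_O = {profile.total_count} "
      f"(overall A_O = {profile.overall_AO} per 1000 residues)\n")
for category in sorted(profile.category_counts, key=str):
    name = CATEGORY_DESCRIPTIONS.get(category, str(category))
    print(f"  {name:<14} count {profile.category_counts[category]:>3}  "
          f"A_O {profile.category_AO(category):>3}  "
          f"Y {profile.category_Y(category):>3}%")

print("\nACE-inhibitory sequences dominate, mirroring their dominance in the")
print("reference databases of known bioactive peptides.")
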