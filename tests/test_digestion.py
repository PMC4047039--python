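"""Cleavage-rule engine: sites, fragments, rule tables and their invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from gutpep.digestion import (
    CleavageRule,
    RuleSchemaError,
    builtin_rulesets,
    cleavage_sites,
    digest,
    load_ruleset,
    resolve_enzymes,
    save_ruleset,
)
from gutpep.registry import SCENARIOS

AA = "ACDEFGHIKLMNPQRSTVWY"

sequences = st.text(alphabet=AA, min_size=0, max_size=60)


class TestCleavageSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAKAA", [3]),          # plain tryptic cut after K
            ("AAKPAA", []),          # proline at P1' vetoes
            ("AWKPAA", [3]),         # W at P2 rescues the K-P bond
            ("AARAA", [3]),
            ("ACKDA", []),           # C-K-D block
            ("ADKDA", []),           # D-K-D block
            ("ARRHA", [2]),          # R-R-H blocks the second R only
            ("ARRRA", [2, 4]),       # R-R-R blocks only the middle bond
            ("AMRPA", [3]),          # M at P2 rescues R-P
        ],
    )
    def test_trypsin_rule_table(self, trypsin, seq, expected):
        assert cleavage_sites(seq, trypsin) == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAFAA", [3]),
            ("AAWMA", []),   # W-M resists chymotryptic cleavage
            ("AAYPA", []),
            ("AAWAA", [3]),
        ],
    )
    def test_chymotrypsin_high_rule_table(self, chymotrypsin_high, seq, expected):
        assert cleavage_sites(seq, chymotrypsin_high) == expected

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AALAA", [3]),   # pepsin cuts after L
            ("AAFAA", [3]),
            ("AALPA", []),    # proline at P1'
            ("APLAA", []),    # proline at P2
            ("AAWAA", []),    # W only at pH > 2
        ],
    )
    def test_pepsin_ph13_rule_table(self, seq, expected):
        pepsin = builtin_rulesets()["pepsin_ph1.3"]
        assert cleavage_sites(seq, pepsin) == expected

    def test_pepsin_ph_gt2_broader_p1(self):
        pepsin2 = builtin_rulesets()["pepsin_ph_gt2"]
        assert cleavage_sites("AAWAA", pepsin2) == [3]
        assert cleavage_sites("AAYAA", pepsin2) == [3]

    def test_empty_sequence_has_no_sites(self, trypsin):
        assert cleavage_sites("", trypsin) == []

    def test_truncated_context_cannot_block(self, trypsin):
        # R-R-R block needs P2=R, absent at the chain start: RR cleaves after R1
        assert cleavage_sites("RRA", trypsin) == [1, 2]


class TestDigest:
    def test_uncut_chain_is_one_fragment(self, trypsin):
        frags = digest("PEPTIDE", [trypsin])
        assert [(f.sequence, f.start, f.end) for f in frags] == [("PEPTIDE", 1, 7)]

    def test_multi_enzyme_union(self):
        frags = digest("AAKAAFAA", SCENARIOS["gastric_plus_small_intestinal"])
        assert [f.sequence for f in frags] == ["AAK", "AAF", "AA"]

    def test_fragments_tile_without_gaps(self, trypsin, chymotrypsin_high):
        seq = "MKWVTFISLLLLFSSAYSRGVFRRDTHK"
        frags = digest(seq, [trypsin, chymotrypsin_high])
        assert "".join(f.sequence for f in frags) == seq
        starts = [f.start for f in frags]
        ends = [f.end for f in frags]
        assert starts[0] == 1 and ends[-1] == len(seq)
        assert all(s == e_prev + 1 for s, e_prev in zip(starts[1:], ends))

    @settings(max_examples=300, derandomize=True)
    @given(sequences)
    def test_conservation_property(self, seq):
        for label in SCENARIOS:
            frags = digest(seq, SCENARIOS[label])
            assert "".join(f.sequence for f in frags) == seq

    @settings(max_examples=300, derandomize=True)
    @given(sequences.filter(bool))
    def test_gastric_cuts_subset_of_full_scenario(self, seq):
        cuts = lambda label: {
            f.end for f in digest(seq, SCENARIOS[label])[:-1]
        }
        assert cuts("gastric") <= cuts("gastric_plus_small_intestinal")
        assert cuts("small_intestinal_only") <= cuts("gastric_plus_small_intestinal")

    @settings(max_examples=200, derandomize=True)
    @given(sequences.filter(lambda s: len(s) > 1))
    def test_idempotence_no_new_cuts_inside_fragments(self, seq):
        # sites are computed on the intact chain: each fragment, re-examined
        # with its intact-chain context, contains no internal cut
        scenario = SCENARIOS["gastric_plus_small_intestinal"]
        enzymes = resolve_enzymes(scenario.enzymes)
        cuts = set()
        for enz in enzymes:
            cuts.update(cleavage_sites(seq, enz))
        for frag in digest(seq, scenario):
            internal = set(range(frag.start, frag.end))
            assert not (cuts & internal)


class TestRuleTables:
    def test_exactly_five_builtin_sets(self):
        assert sorted(builtin_rulesets()) == [
            "chymotrypsin_high", "chymotrypsin_low",
            "pepsin_ph1.3", "pepsin_ph_gt2", "trypsin",
        ]

    def test_trypsin_rule_counts(self, trypsin):
        assert trypsin.counts() == {
            "permit": 1, "exception_permit": 2, "exception_block": 7,
        }

    def test_alias_resolution(self):
        enzymes = resolve_enzymes(["pepsin", "chymotrypsin"])
        assert [e.name for e in enzymes] == ["pepsin_ph1.3", "chymotrypsin_high"]
        low = resolve_enzymes(["chymotrypsin"], chymotrypsin_variant="chymotrypsin_low")
        assert low[0].name == "chymotrypsin_low"

    def test_rule_validation(self):
        with pytest.raises(RuleSchemaError):
            CleavageRule("permit", ((0, frozenset("K")),))
        with pytest.raises(RuleSchemaError):
            CleavageRule("permit", ((5, frozenset("K")),))
        with pytest.raises(RuleSchemaError):
            CleavageRule("permit", ((-1, frozenset("K1")),))
        with pytest.raises(RuleSchemaError):
            CleavageRule("maybe", ((-1, frozenset("K")),))

    def test_malformed_file_names_rule_index(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "name: bad\nrules:\n"
            "  - {kind: permit, conditions: {-1: K}}\n"
            "  - {kind: permit, conditions: {0: K}}\n"
        )
        with pytest.raises(RuleSchemaError, match="rule 1"):
            load_ruleset(path)

    def test_ruleset_without_permit_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("name: bad\nrules:\n  - {kind: exception_block, conditions: {-1: K}}\n")
        with pytest.raises(RuleSchemaError, match="no permit"):
            load_ruleset(path)

    @pytest.mark.parametrize("name", sorted(["trypsin", "chymotrypsin_low", "pepsin_ph1.3"]))
    def test_save_load_round_trip_behavior(self, tmp_path, name):
        original = builtin_rulesets()[name]
        path = tmp_path / f"{name}.yaml"
        save_ruleset(original, path)
        reloaded = load_ruleset(path)
        rng = random.Random(0)
        for _ in range(300):
            decamer = "".join(rng.choice(AA) for _ in range(10))
            assert cleavage_sites(decamer, original) == cleavage_sites(decamer, reloaded)


def oracle_trypsin_sites(seq):
    """Brute-force per-bond trypsin evaluator, independent of the engine."""
    out = []
    for i in range(1, len(seq)):
        p1, p1p = seq[i - 1], seq[i]
        p2 = seq[i - 2] if i >= 2 else None
        permit = p1 in "KR" and p1p != "P"
        rescue = (p2 == "W" and p1 == "K" and p1p == "P") or (
            p2 == "M" and p1 == "R" and p1p == "P"
        )
        block = (
            (p2 in ("C", "D") and p1 == "K" and p1p == "D")
            or (p2 == "C" and p1 == "K" and p1p in ("H", "Y"))
            or (p2 == "C" and p1 == "R" and p1p == "K")
            or (p2 == "R" and p1 == "R" and p1p in ("H", "R"))
        )
        if (permit or rescue) and not block:
            out.append(i)
    return out


def test_engine_matches_bruteforce_oracle_on_all_tripeptides(trypsin):
    for a in AA:
        for b in AA:
            for c in AA:
                seq = a + b + c
                assert cleavage_sites(seq, trypsin) == oracle_trypsin_sites(seq), seq
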