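"""Protein records, the bundled registry and scenario assignment."""

import pytest

from gutpep.registry import (
    ProteinRecord,
    SCENARIOS,
    UnknownAccessionError,
    bundled_registry,
    beta_casein_record,
    read_fasta,
    scenarios_for,
)
from gutpep.residues import SequenceAlphabetError, validate_sequence


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = write_fasta(tmp_path / "a.fasta", [("X", "PEPTIDE")])
        records = read_fasta(path)
        assert len(records) == 1
        assert records[0].sequence == "PEPTIDE"
        assert records[0].chain_length == 7

    def test_two_records_preserve_order(self, tmp_path):
        path = write_fasta(tmp_path / "a.fasta", [("X", "PEPTIDE"), ("Y2", "ACDEF")])
        assert [r.accession for r in read_fasta(path)] == ["X", "Y2"]

    def test_lowercase_is_uppercased_and_wrapped_lines_join(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">X\npep\ntide\n")
        assert read_fasta(path)[0].sequence == "PEPTIDE"

    @pytest.mark.parametrize("bad", ["PEP1IDE", "PEP*IDE"])
    def test_invalid_residue_names_record_and_position(self, tmp_path, bad):
        path = write_fasta(tmp_path / "a.fasta", [("X", bad)])
        with pytest.raises(SequenceAlphabetError, match=r"'X'.*position 4"):
            read_fasta(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_known_accession_resolves_metadata(self, tmp_path):
        path = write_fasta(tmp_path / "a.fasta", [("P02666", "A" * 209)])
        rec = read_fasta(path)[0]
        assert rec.origin == "dietary"
        assert rec.secretion_sites == frozenset()

    def test_length_mismatch_warns_not_truncates(self, tmp_path):
        path = write_fasta(tmp_path / "a.fasta", [("P02666", "ACDEF")])
        with pytest.warns(UserWarning, match="mature chain length"):
            rec = read_fasta(path)[0]
        assert rec.chain_length == 5

    def test_ambiguity_codes_rejected_by_default_accepted_on_opt_in(self, tmp_path):
        path = write_fasta(tmp_path / "a.fasta", [("X", "PEPTIDEX")])
        with pytest.raises(SequenceAlphabetError):
            read_fasta(path)
        assert read_fasta(path, allow_ambiguous=True)[0].sequence == "PEPTIDEX"


class TestBundledRegistry:
    def test_has_all_33_proteins(self):
        assert len(bundled_registry()) == 33

    def test_serum_albumin(self):
        entry = bundled_registry()["P02768"]
        assert entry.origin == "endogenous"
        assert entry.secretion_sites == {"stomach", "small_intestine"}
        assert entry.chain_length == 591
        assert "albumin" in entry.name.lower()

    def test_mucin2_and_beta_casein(self):
        reg = bundled_registry()
        assert reg["Q02817"].chain_length == 5159
        assert reg["P02666"].origin == "dietary"
        assert reg["P02666"].chain_length == 209

    def test_unknown_accession_is_loud(self):
        with pytest.raises(UnknownAccessionError, match="P99999"):
            bundled_registry()["P99999"]

    def test_dietary_rows_have_no_sites_endogenous_have_some(self):
        for entry in bundled_registry().values():
            if entry.origin == "dietary":
                assert not entry.secretion_sites
            else:
                assert entry.secretion_sites


class TestScenarios:
    def test_scenario_enzyme_sets_are_fixed(self):
        assert SCENARIOS["gastric"].enzymes == ("pepsin",)
        assert SCENARIOS["gastric_plus_small_intestinal"].enzymes == (
            "pepsin", "trypsin", "chymotrypsin",
        )
        assert SCENARIOS["small_intestinal_only"].enzymes == ("trypsin", "chymotrypsin")

    def _record(self, origin, sites=(), override=None):
        return ProteinRecord(
            accession="X", name="x", sequence="ACDEF", origin=origin,
            secretion_sites=frozenset(sites), scenario_override=override,
        )

    def test_pancreatic_protein_gets_small_intestinal_only(self):
        labels = [s.label for s in scenarios_for(self._record("endogenous", {"pancreas"}))]
        assert labels == ["small_intestinal_only"]

    def test_dietary_gets_gastric_then_full(self):
        labels = [s.label for s in scenarios_for(self._record("dietary"))]
        assert labels == ["gastric", "gastric_plus_small_intestinal"]

    def test_dual_level_secretion_gets_all_three(self):
        rec = self._record("endogenous", {"stomach", "small_intestine"})
        assert [s.label for s in scenarios_for(rec)] == [
            "gastric", "gastric_plus_small_intestinal", "small_intestinal_only",
        ]

    def test_mouth_secretion_treated_like_stomach(self):
        labels = [s.label for s in scenarios_for(self._record("endogenous", {"mouth"}))]
        assert labels == ["gastric", "gastric_plus_small_intestinal"]

    def test_endogenous_without_sites_errors(self):
        with pytest.raises(ValueError, match="secretion sites"):
            scenarios_for(self._record("endogenous"))

    def test_pure_in_origin_and_sites(self):
        a = self._record("endogenous", {"stomach", "colon"})
        b = self._record("endogenous", {"stomach", "colon"})
        assert [s.label for s in scenarios_for(a)] == [s.label for s in scenarios_for(b)]

    def test_registry_override_wins(self):
        rec = self._record("endogenous", {"duodenum"}, override=("gastric",))
        assert [s.label for s in scenarios_for(rec)] == ["gastric"]

    def test_registry_hormone_overrides_follow_study_tables(self):
        reg = bundled_registry()
        # secretin and promotilin underwent all three digestions in the study
        for acc in ("P09683", "P12872"):
            assert reg[acc].scenario_override == (
                "gastric", "gastric_plus_small_intestinal", "small_intestinal_only",
            )


def test_record_invariants():
    with pytest.raises(ValueError):
        ProteinRecord("X", "x", "ACDEF", origin="dietary",
                      secretion_sites=frozenset({"stomach"}))
    with pytest.raises(ValueError):
        ProteinRecord("X", "x", "ACDEF", origin="endogenous",
                      secretion_sites=frozenset({"liver"}))


def test_bundled_beta_casein_matches_registered_length():
    rec = beta_casein_record()
    assert rec.chain_length == bundled_registry()["P02666"].chain_length == 209
    assert validate_sequence(rec.sequence) == rec.sequence
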