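"""Synthetic proteins with planted reference peptides and known ground truth.

The generator emulates the pipeline's two real inputs — protein chains
and a bioactive-peptide reference table — in a way that makes the correct
answer knowable by construction:

* a *releasable* plant is embedded between flanking residues that force a
  cleavage at both of its boundaries under the stated digestion scenario
  (e.g. a preceding arginine for tryptic release) while the peptide
  itself contains no internal cleavage site for that scenario, so
  exhaustive digestion liberates it exactly;
* a *non-releasable* plant is embedded behind a residue no scenario
  enzyme can cut after, so the peptide stays buried inside a longer
  fragment;
* background residues are drawn from an alphabet containing no cleavage
  P1 residues, so digestion cuts only at planted boundaries, and
  generated reference peptides end in a lysine that the background never
  contains, so no reference peptide can occur outside a planted site.

Every generated protein is verified post hoc by running the real
digestion and matching code; a collision (an accidental match outside the
manifest) triggers regeneration from a derived sub-seed. All randomness
flows from one integer master seed through numpy ``SeedSequence``
spawning, so regeneration from (seed, parameters) is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .biodb import BioactivePeptide, PeptideDatabase
from .digestion import digest
from .profiling import count_occurrences, match_digest
from .registry import SCENARIOS, DigestionScenario, ProteinRecord

__all__ = [
    "GenerationError",
    "PlantedPeptide",
    "SyntheticStudy",
    "generate_protein",
    "generate_study",
]

log = logging.getLogger(__name__)


class GenerationError(ValueError):
    """A requested plant is infeasible or generation failed to converge."""


#: background alphabet: no residue is a cleavage P1 for any builtin enzyme
SAFE_BACKGROUND = "GASTNQEVID"

#: residues whose C-terminal bond each scenario's enzymes can cut
_CLEAVABLE_TAILS = {
    "gastric": set("FL"),
    "small_intestinal_only": set("KRFYW"),
    "gastric_plus_small_intestinal": set("KRFYWL"),
}

#: left flank forcing a cut immediately before the planted peptide
_RELEASE_FLANK = {
    "gastric": "GL",
    "small_intestinal_only": "GR",
    "gastric_plus_small_intestinal": "GR",
}


@dataclass(frozen=True)
class PlantedPeptide:
    peptide: str
    start: int  # 1-based position on the host chain
    releasable: bool


@dataclass(frozen=True)
class SyntheticStudy:
    proteins: tuple[ProteinRecord, ...]
    db: PeptideDatabase
    manifest: Mapping
    seed: int
    params: Mapping

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA, reference TSV and JSON manifest; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "proteins.fasta"
        with open(fasta, "w") as fh:
            for rec in self.proteins:
                fh.write(f">{rec.accession} {rec.name}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        db_path = out / "peptides.tsv"
        self.db.save(db_path)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return {"fasta": fasta, "db": db_path, "manifest": manifest_path}


def _check_releasable(peptide: str, scenario: DigestionScenario) -> None:
    if peptide[0] == "P":
        raise GenerationError(
            f"{peptide!r}: a peptide starting with proline cannot be released "
            f"(proline at P1' vetoes the upstream cut)"
        )
    if peptide[-1] not in _CLEAVABLE_TAILS[scenario.label]:
        raise GenerationError(
            f"{peptide!r}: C-terminal {peptide[-1]!r} is not cleavable under "
            f"{scenario.label}; a releasable plant must end in one of "
            f"{sorted(_CLEAVABLE_TAILS[scenario.label])}"
        )


def generate_protein(
    planted: Sequence[tuple[str, bool]],
    length: int,
    seed: int | np.random.Generator,
    scenario: DigestionScenario | str = "small_intestinal_only",
    *,
    accession: str = "SYN001",
) -> tuple[ProteinRecord, list[PlantedPeptide]]:
    """Embed peptides in a background chain with known release status.

    Parameters
    ----------
    planted:
        (peptide, releasable) pairs, placed in the given order.
    length:
        Target chain length; must accommodate all plants and flanks.
    seed:
        Integer seed or a numpy Generator.
    scenario:
        Digestion scenario (label or object) the release flags refer to.

    Returns the protein record and its manifest entries. Raises
    :class:`GenerationError` when a peptide flagged releasable inherently
    cannot be released under the scenario (wrong C-terminal residue,
    leading proline, or an internal cleavage site).
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    blocks: list[tuple[str, str, bool]] = []  # (flank, peptide+pad, releasable)
    for peptide, releasable in planted:
        peptide = peptide.upper()
        if releasable:
            _check_releasable(peptide, scenario)
            blocks.append((_RELEASE_FLANK[scenario.label], peptide + "G", True))
        else:
            blocks.append(("G", peptide + "G", False))

    blocks_len = sum(len(f) + len(p) for f, p, _ in blocks)
    if length < blocks_len:
        raise GenerationError(
            f"length {length} cannot hold {blocks_len} residues of plants and flanks"
        )
    extra = length - blocks_len
    gaps = rng.multinomial(extra, np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))

    parts: list[str] = []
    manifest: list[PlantedPeptide] = []
    pos = 0
    bg = lambda n: "".join(rng.choice(list(SAFE_BACKGROUND), size=n)) if n else ""
    for (flank, pep_pad, releasable), gap in zip(blocks, gaps[:-1]):
        parts.append(bg(int(gap)))
        pos += int(gap)
        parts.append(flank)
        pos += len(flank)
        peptide = pep_pad[:-1]
        manifest.append(PlantedPeptide(peptide, pos + 1, releasable))
        parts.append(pep_pad)
        pos += len(pep_pad)
    parts.append(bg(int(gaps[-1])))
    sequence = "".join(parts)

    # authoritative feasibility check: the real engine must release every
    # releasable plant as an exact fragment
    fragments = digest(sequence, scenario)
    released = {(f.sequence, f.start) for f in fragments}
    for entry in manifest:
        if entry.releasable and (entry.peptide, entry.start) not in released:
            raise GenerationError(
                f"{entry.peptide!r} flagged releasable but not released under "
                f"{scenario.label} (internal cleavage site or blocked boundary)"
            )
    record = ProteinRecord(
        accession=accession,
        name=f"synthetic protein {accession}",
        sequence=sequence,
        origin="endogenous",
        secretion_sites=frozenset({"small_intestine"}),
        scenario_override=(scenario.label,),
    )
    return record, manifest


def _generate_db(rng: np.random.Generator, db_size: int) -> PeptideDatabase:
    """Reference peptides: safe-alphabet body + terminal K, none a suffix of another."""
    db = PeptideDatabase()
    seqs: list[str] = []
    activities_pool = [2, 4, 6, 8, 9]
    while len(seqs) < db_size:
        ell = int(rng.integers(2, 10))
        body = "".join(rng.choice(list(SAFE_BACKGROUND), size=ell - 1))
        pep = body + "K"
        if any(a.endswith(b) or b.endswith(a) for a in [pep] for b in seqs):
            continue
        k = int(rng.integers(1, 3))
        acts = frozenset(int(a) for a in rng.choice(activities_pool, size=k, replace=False))
        db.add(BioactivePeptide(pep, acts, source_id="synthetic"))
        seqs.append(pep)
    return db


def generate_study(
    n_proteins: int,
    db_size: int,
    plant_rate: float,
    seed: int,
    *,
    protein_length: int = 120,
    scenario: str = "small_intestinal_only",
    max_attempts: int = 20,
) -> SyntheticStudy:
    """Generate a full synthetic study with a ground-truth manifest.

    Each reference peptide is planted into one uniformly chosen protein
    with probability ``plant_rate`` (releasable with probability 0.75).
    Every protein is verified post hoc with the real digestion and
    matching code: the released matches must be exactly the releasable
    plants and every reference peptide must occur only at its manifest
    positions; a collision triggers regeneration from a spawned sub-seed.
    """
    if n_proteins < 1 or db_size < 1:
        raise ValueError("n_proteins and db_size must be positive")
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    db_ss, plan_ss, protein_ss = ss.spawn(3)
    db = _generate_db(np.random.default_rng(db_ss), db_size)

    plan_rng = np.random.default_rng(plan_ss)
    plants_per_protein: list[list[tuple[str, bool]]] = [[] for _ in range(n_proteins)]
    for pep in sorted(db.entries):
        if plan_rng.random() < plant_rate:
            host = int(plan_rng.integers(n_proteins))
            releasable = bool(plan_rng.random() < 0.75)
            plants_per_protein[host].append((pep, releasable))

    scn = SCENARIOS[scenario]
    proteins: list[ProteinRecord] = []
    manifest_proteins: dict[str, dict] = {}
    for i, plants in enumerate(plants_per_protein):
        accession = f"SYN{i + 1:03d}"
        needed = sum(len(p) + 3 for p, _ in plants)
        length = max(protein_length, needed + 10)
        attempts_ss = np.random.SeedSequence(
            entropy=protein_ss.entropy, spawn_key=protein_ss.spawn_key + (i,)
        )
        record = None
        entries: list[PlantedPeptide] = []
        for attempt, sub in enumerate(attempts_ss.spawn(max_attempts)):
            rng = np.random.default_rng(sub)
            record, entries = generate_protein(
                plants, length, rng, scn, accession=accession
            )
            if _verify(record, entries, db, scn):
                break
            log.info("%s: collision on attempt %d, regenerating", accession, attempt)
            record = None
        if record is None:
            raise GenerationError(
                f"{accession}: could not generate a collision-free chain "
                f"in {max_attempts} attempts"
            )
        proteins.append(record)
        manifest_proteins[accession] = {
            "length": record.chain_length,
            "plants": [
                {"peptide": e.peptide, "start": e.start, "releasable": e.releasable}
                for e in entries
            ],
        }

    manifest = {
        "seed": seed,
        "params": {
            "n_proteins": n_proteins,
            "db_size": db_size,
            "plant_rate": plant_rate,
            "protein_length": protein_length,
            "scenario": scenario,
        },
        "proteins": manifest_proteins,
    }
    return SyntheticStudy(
        proteins=tuple(proteins),
        db=db,
        manifest=manifest,
        seed=seed,
        params=manifest["params"],
    )


def _verify(
    record: ProteinRecord,
    entries: Sequence[PlantedPeptide],
    db: PeptideDatabase,
    scenario: DigestionScenario,
) -> bool:
    """True iff digestion releases exactly the releasable plants and every
    reference peptide occurs only at its manifest positions."""
    profile = match_digest(digest(record.sequence, scenario), db, accession=record.accession)
    expected = {e.peptide for e in entries if e.releasable}
    if set(profile.released_sequences) != expected:
        return False
    planted_positions: dict[str, set[int]] = {}
    for e in entries:
        planted_positions.setdefault(e.peptide, set()).add(e.start)
    for pep in db.entries:
        observed = set(count_occurrences(record.sequence, pep))
        if observed != planted_positions.get(pep, set()):
            return False
    return True
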