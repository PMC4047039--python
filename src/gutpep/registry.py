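"""Protein records, the bundled study registry, and digestion-scenario logic.

A :class:`ProteinRecord` is a mature chain (signal peptide already removed)
plus the metadata that decides how it is digested: its origin (dietary vs
gut endogenous) and, for endogenous proteins, the gastrointestinal sites
into which it is secreted. Dietary proteins and endogenous proteins that
reach the stomach are digested gastrically (pepsin) and then gastro-
intestinally (pepsin + trypsin + chymotrypsin); endogenous proteins
secreted into the small intestine or from the pancreas/duodenum see only
small-intestinal digestion (trypsin + chymotrypsin).

The bundled registry covers the 33 proteins of the underlying study, keyed
by UniProt accession, with their secretion sites and expected mature chain
lengths. A handful of multi-site hormones carry an explicit scenario
override where the descriptive secretion site alone under-determines the
scenario set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .residues import validate_sequence

__all__ = [
    "ProteinRecord",
    "DigestionScenario",
    "RegistryEntry",
    "SCENARIOS",
    "SECRETION_SITES",
    "UnknownAccessionError",
    "bundled_registry",
    "read_fasta",
    "scenarios_for",
    "beta_casein_record",
]

SECRETION_SITES = frozenset(
    {"mouth", "stomach", "small_intestine", "pancreas", "duodenum", "colon", "plasma"}
)

#: sites implying exposure to gastric (peptic) digestion
_GASTRIC_SITES = frozenset({"mouth", "stomach"})
#: sites implying direct entry into the small intestine
_INTESTINAL_SITES = frozenset({"small_intestine", "pancreas", "duodenum", "colon"})


@dataclass(frozen=True)
class DigestionScenario:
    """A named enzyme set applied to a protein.

    ``enzymes`` holds canonical enzyme names; ``pepsin`` and
    ``chymotrypsin`` are aliases resolved to a concrete specificity
    variant by the digestion engine.
    """

    label: str
    enzymes: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = _SCENARIO_ENZYMES.get(self.label)
        if expected is None:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if tuple(self.enzymes) != expected:
            raise ValueError(
                f"scenario {self.label!r} must use enzymes {expected}, got {self.enzymes}"
            )


_SCENARIO_ENZYMES: dict[str, tuple[str, ...]] = {
    "gastric": ("pepsin",),
    "gastric_plus_small_intestinal": ("pepsin", "trypsin", "chymotrypsin"),
    "small_intestinal_only": ("trypsin", "chymotrypsin"),
}

#: The three digestion scenarios, by label.
SCENARIOS: Mapping[str, DigestionScenario] = {
    label: DigestionScenario(label, enzymes) for label, enzymes in _SCENARIO_ENZYMES.items()
}


@dataclass(frozen=True)
class ProteinRecord:
    """A mature protein chain with digestion metadata.

    ``origin`` may be ``None`` for records read from FASTA whose accession
    is not in the registry; such records must be completed from user
    configuration before scenarios can be assigned.
    """

    accession: str
    name: str
    sequence: str
    origin: str | None = None
    secretion_sites: frozenset[str] = frozenset()
    scenario_override: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.origin not in (None, "dietary", "endogenous"):
            raise ValueError(f"origin must be dietary/endogenous, got {self.origin!r}")
        unknown = set(self.secretion_sites) - SECRETION_SITES
        if unknown:
            raise ValueError(f"unknown secretion sites {sorted(unknown)}")
        if self.origin == "dietary" and self.secretion_sites:
            raise ValueError("dietary records must have empty secretion_sites")

    @property
    def chain_length(self) -> int:
        return len(self.sequence)


class UnknownAccessionError(KeyError):
    """Lookup of an accession absent from the registry."""


@dataclass(frozen=True)
class RegistryEntry:
    accession: str
    name: str
    origin: str
    secretion_sites: frozenset[str]
    chain_length: int
    scenario_override: tuple[str, ...] | None = None


class _Registry(dict):
    """Mapping accession -> RegistryEntry with an explicit not-found error."""

    def __missing__(self, accession: str) -> RegistryEntry:
        raise UnknownAccessionError(
            f"accession {accession!r} is not in the protein registry"
        )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gutpep").joinpath("data", name)))


def _parse_registry(path: Path) -> _Registry:
    reg = _Registry()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        required = {"accession", "name", "origin", "secretion_sites", "chain_length"}
        missing = required - idx.keys()
        if missing:
            raise ValueError(f"registry {path}: missing columns {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            get = lambda col: cells[idx[col]] if idx[col] < len(cells) else ""
            sites = frozenset(s for s in get("secretion_sites").split(";") if s)
            override_raw = get("scenarios") if "scenarios" in idx else ""
            override = tuple(s for s in override_raw.split(";") if s) or None
            entry = RegistryEntry(
                accession=get("accession"),
                name=get("name"),
                origin=get("origin"),
                secretion_sites=sites,
                chain_length=int(get("chain_length")),
                scenario_override=override,
            )
            reg[entry.accession] = entry
    return reg


_BUNDLED: _Registry | None = None


def bundled_registry(path: str | Path | None = None) -> Mapping[str, RegistryEntry]:
    """The per-protein metadata table of the study, keyed by accession.

    Pass ``path`` to load a user-supplied registry TSV instead (columns:
    accession, name, origin, secretion_sites ``;``-separated,
    chain_length, optional scenarios override ``;``-separated).
    """
    global _BUNDLED
    if path is not None:
        return _parse_registry(Path(path))
    if _BUNDLED is None:
        _BUNDLED = _parse_registry(_data_path("registry.tsv"))
    return _BUNDLED


def read_fasta(
    path: str | Path,
    *,
    registry: Mapping[str, RegistryEntry] | None = None,
    allow_ambiguous: bool = False,
) -> list[ProteinRecord]:
    """Read mature protein chains from a FASTA file.

    The first whitespace-separated token of each header is taken as the
    accession. When the accession is known to the registry (the bundled
    one by default) the record's origin and secretion sites are filled in,
    and a mismatch between the sequence length and the registered mature
    chain length triggers a warning (never silent truncation).
    """
    path = Path(path)
    if registry is None:
        registry = bundled_registry()
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        seq = validate_sequence(str(rec.seq), name=accession, allow_ambiguous=allow_ambiguous)
        if not seq:
            raise ValueError(f"record {accession!r}: empty sequence")
        origin = None
        sites: frozenset[str] = frozenset()
        override = None
        name = rec.description
        try:
            entry = registry[accession]
        except KeyError:
            pass
        else:
            origin = entry.origin
            sites = entry.secretion_sites
            override = entry.scenario_override
            name = entry.name
            if len(seq) != entry.chain_length:
                warnings.warn(
                    f"{accession}: sequence length {len(seq)} differs from the "
                    f"registered mature chain length {entry.chain_length}; "
                    "check that the signal peptide was removed",
                    stacklevel=2,
                )
        records.append(
            ProteinRecord(
                accession=accession,
                name=name,
                sequence=seq,
                origin=origin,
                secretion_sites=sites,
                scenario_override=override,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def scenarios_for(record: ProteinRecord) -> list[DigestionScenario]:
    """Digestion scenarios applicable to a protein.

    Pure function of (origin, secretion_sites): dietary proteins and
    endogenous proteins reaching the mouth/stomach undergo gastric and
    then gastric+small-intestinal digestion; endogenous proteins entering
    at the small-intestinal level (small intestine, pancreas, duodenum,
    colon) undergo small-intestinal digestion only; proteins secreted at
    both levels (e.g. serum albumin) get all three. Registry rows may
    carry an explicit override for hormones whose descriptive secretion
    site under-determines the applicable set.
    """
    if record.scenario_override is not None:
        return [SCENARIOS[label] for label in record.scenario_override]
    if record.origin == "dietary":
        return [SCENARIOS["gastric"], SCENARIOS["gastric_plus_small_intestinal"]]
    if record.origin != "endogenous":
        raise ValueError(
            f"record {record.accession!r} has no origin; supply registry metadata"
        )
    if not record.secretion_sites:
        raise ValueError(
            f"endogenous record {record.accession!r} has no secretion sites"
        )
    out: list[DigestionScenario] = []
    if record.secretion_sites & _GASTRIC_SITES:
        out.append(SCENARIOS["gastric"])
        out.append(SCENARIOS["gastric_plus_small_intestinal"])
    if record.secretion_sites & _INTESTINAL_SITES:
        out.append(SCENARIOS["small_intestinal_only"])
    return out


def beta_casein_record() -> ProteinRecord:
    """The bundled mature bovine beta-casein chain (P02666, 209 aa)."""
    return read_fasta(_data_path("p02666_beta_casein.fasta"))[0]


def with_metadata(
    record: ProteinRecord, *, origin: str, secretion_sites: Iterable[str] = ()
) -> ProteinRecord:
    """Return a copy of ``record`` with origin/site metadata filled in."""
    return replace(
        record, origin=origin, secretion_sites=frozenset(secretion_sites)
    )
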