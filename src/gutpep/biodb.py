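"""Reference database of known bioactive peptides.

Activities are represented by the ten tabulated category codes plus an
open-ended ``OTHER`` tier: a category is either an ``int`` in 1..10 or a
free-text lowercase label (e.g. ``"opioid"``). The bundled label map
translates the common free-text activity names found in exported
reference tables into codes; anything it does not recognise becomes an
OTHER label rather than an error, because real reference snapshots carry
far more activities than the ten tabulated ones.

The bundled :func:`fixture_db` is a small curated fixture of released
bioactive peptides (mostly ACE-inhibitory di-/tripeptides); it is
explicitly NOT a snapshot of the full reference database, so per-protein
counts computed against it are not comparable with counts computed
against a full export, which the user must supply.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "CATEGORY_DESCRIPTIONS",
    "Activity",
    "BioactivePeptide",
    "PeptideDatabase",
    "canonical_activity",
    "activity_name",
    "load_db",
    "fixture_db",
]

log = logging.getLogger(__name__)

Activity = Union[int, str]

CATEGORY_DESCRIPTIONS: dict[int, str] = {
    1: "antiamnestic",
    2: "ACE inhibitor",
    3: "antithrombotic",
    4: "stimulating",
    5: "regulating",
    6: "antioxidative",
    7: "bacterial permease ligand",
    8: "inhibitor",
    9: "hypotensive",
    10: "activating ubiquitin mediated proteolysis",
}


def _normalize_label(label: str) -> str:
    return re.sub(r"[\s_\-]+", " ", label.strip()).lower()


_LABEL_MAP: dict[str, int] | None = None


def _label_map() -> dict[str, int]:
    global _LABEL_MAP
    if _LABEL_MAP is None:
        path = Path(str(resources.files("gutpep").joinpath("data", "activity_labels.tsv")))
        df = pd.read_csv(path, sep="\t")
        _LABEL_MAP = {
            _normalize_label(row.label): int(row.code) for row in df.itertuples()
        }
    return _LABEL_MAP


def canonical_activity(label: str | int) -> Activity:
    """Map a free-text activity label to a category code, or keep it as OTHER.

    Integer codes (1..10) pass through unchanged.
    """
    if isinstance(label, int):
        if label not in CATEGORY_DESCRIPTIONS:
            raise ValueError(f"unknown activity code {label}")
        return label
    return _label_map().get(_normalize_label(label), _normalize_label(label))


def activity_name(activity: Activity) -> str:
    if isinstance(activity, int):
        return CATEGORY_DESCRIPTIONS[activity]
    return activity


@dataclass(frozen=True)
class BioactivePeptide:
    sequence: str
    activities: frozenset[Activity]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(
                f"bioactive peptide {self.sequence!r}: length must be >= 2"
            )
        if not self.activities:
            raise ValueError(f"peptide {self.sequence!r}: empty activity set")


@dataclass
class PeptideDatabase:
    """Reference peptides keyed by (uppercased) sequence, indexed by activity."""

    entries: dict[str, BioactivePeptide] = field(default_factory=dict)

    def add(self, peptide: BioactivePeptide) -> None:
        key = peptide.sequence.upper()
        existing = self.entries.get(key)
        if existing is None:
            self.entries[key] = BioactivePeptide(key, peptide.activities, peptide.source_id)
        else:
            self.entries[key] = BioactivePeptide(
                key,
                existing.activities | peptide.activities,
                existing.source_id or peptide.source_id,
            )

    def get(self, sequence: str) -> BioactivePeptide | None:
        return self.entries.get(sequence.upper())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sequence: str) -> bool:
        return sequence.upper() in self.entries

    def activities_of(self, sequence: str) -> frozenset[Activity]:
        entry = self.get(sequence)
        return entry.activities if entry else frozenset()

    def by_activity(self) -> dict[Activity, set[str]]:
        """Index: activity category -> set of peptide sequences."""
        index: dict[Activity, set[str]] = {}
        for seq, pep in self.entries.items():
            for act in pep.activities:
                index.setdefault(act, set()).add(seq)
        return index

    def peptides_with(self, activity: Activity) -> set[str]:
        return self.by_activity().get(activity, set())

    @property
    def categories(self) -> set[Activity]:
        return set(self.by_activity())

    def save(self, path: str | Path) -> None:
        rows = []
        for seq in sorted(self.entries):
            pep = self.entries[seq]
            labels = sorted(
                (activity_name(a) for a in pep.activities), key=str
            )
            rows.append(
                {"sequence": seq, "activities": ";".join(labels), "source_id": pep.source_id}
            )
        pd.DataFrame(rows, columns=["sequence", "activities", "source_id"]).to_csv(
            path, sep="\t", index=False
        )


def load_db(path: str | Path) -> PeptideDatabase:
    """Load a peptide reference table from TSV.

    Columns: ``sequence``, ``activities`` (``;``-separated labels),
    optional ``source_id``. Duplicate sequences are merged with the union
    of their activities.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sequence", "activities"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    db = PeptideDatabase()
    for row in df.itertuples():
        activities = frozenset(
            canonical_activity(lab) for lab in str(row.activities).split(";") if lab
        )
        source = getattr(row, "source_id", "") or ""
        db.add(BioactivePeptide(str(row.sequence).upper(), activities, source))
    log.info(
        "loaded peptide db %s: %d entries, %d activity categories",
        path,
        len(db),
        len(db.categories),
    )
    return db


_FIXTURE: PeptideDatabase | None = None


def fixture_db() -> PeptideDatabase:
    """The bundled curated fixture of released bioactive peptides."""
    global _FIXTURE
    if _FIXTURE is None:
        path = Path(str(resources.files("gutpep").joinpath("data", "fixture_peptides.tsv")))
        _FIXTURE = load_db(path)
    return _FIXTURE


def database_from_peptides(
    peptides: Iterable[tuple[str, Iterable[Activity]]]
) -> PeptideDatabase:
    """Build a database from (sequence, activities) pairs (mainly for tests)."""
    db = PeptideDatabase()
    for seq, acts in peptides:
        db.add(BioactivePeptide(seq.upper(), frozenset(acts)))
    return db
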