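"""Occurrence and release statistics for bioactive peptides.

Three statistics describe a protein as a source of bioactive peptides:

* ``A_O`` — frequency of bioactive-fragment occurrences within the intact
  chain, scaled per residue: ``A_O = round(1000 * a_O / N)`` where ``a_O``
  counts every (possibly overlapping) occurrence of every reference
  peptide, a peptide with k activities contributing its occurrences to
  all k per-category counts, and ``N`` is the mature chain length.
* ``Y_j`` — relative frequency (%) of activity category j among all
  occurrences: ``Y_j = round(100 * a_Oj / a_O)``.
* ``A_D`` — frequency of bioactive peptides among the digest products:
  ``A_D = round(1000 * a_D / N)`` where ``a_D`` counts the distinct
  fragment sequences that exactly equal a reference peptide (release
  semantics: after digestion a substring match does not count).

Rounding is to the nearest integer, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .biodb import Activity, PeptideDatabase
from .digestion import PeptideFragment
from .registry import ProteinRecord

__all__ = [
    "IntactProfile",
    "DigestProfile",
    "round_half_away",
    "freq_AO",
    "freq_AD",
    "rel_Y",
    "scan_intact",
    "match_digest",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def freq_AO(count: int, chain_length: int) -> int:
    """Per-residue occurrence frequency, scaled by 1000."""
    if chain_length < 1:
        raise ValueError("chain length must be >= 1")
    if count < 0:
        raise ValueError("count must be >= 0")
    return round_half_away(1000 * count / chain_length)


#: The post-digestion frequency has the identical contract.
freq_AD = freq_AO


def rel_Y(count_j: int, total: int) -> int:
    """Relative frequency (%) of one activity category among all occurrences."""
    if total < 1:
        raise ValueError("total occurrence count must be >= 1")
    return round_half_away(100 * count_j / total)


def count_occurrences(sequence: str, peptide: str) -> list[int]:
    """1-based start positions of every (overlapping) occurrence."""
    positions = []
    start = sequence.find(peptide)
    while start != -1:
        positions.append(start + 1)
        start = sequence.find(peptide, start + 1)
    return positions


@dataclass(frozen=True)
class IntactProfile:
    """Bioactive-fragment occurrence profile of one intact protein."""

    accession: str
    chain_length: int
    occurrences: Mapping[str, tuple[int, ...]]  # peptide -> 1-based starts
    category_counts: Mapping[Activity, int]  # a_Oj
    total_count: int  # a_O, summed over ALL categories

    @property
    def overall_AO(self) -> int:
        return freq_AO(self.total_count, self.chain_length)

    def category_AO(self, activity: Activity) -> int:
        return freq_AO(self.category_counts.get(activity, 0), self.chain_length)

    def category_Y(self, activity: Activity) -> int:
        return rel_Y(self.category_counts.get(activity, 0), self.total_count)


@dataclass(frozen=True)
class DigestMatch:
    fragment: PeptideFragment
    activities: frozenset[Activity]


@dataclass(frozen=True)
class DigestProfile:
    """Release profile of one digested protein.

    ``unique_counts`` counts distinct matched fragment sequences per
    category; ``occurrence_counts`` counts fragment instances. The total
    ``a_D`` counts each distinct matched sequence once, whatever its
    multiplicity or number of activities, mirroring the convention that a
    released peptide is one peptide even when it is multifunctional.
    """

    accession: str
    chain_length: int
    matches: tuple[DigestMatch, ...]
    unique_counts: Mapping[Activity, int]
    occurrence_counts: Mapping[Activity, int]
    total_released: int  # a_D: distinct matched sequences

    @property
    def AD(self) -> int:
        return freq_AD(self.total_released, self.chain_length)

    def category_count(self, activity: Activity, mode: str = "unique") -> int:
        counts = self.unique_counts if mode == "unique" else self.occurrence_counts
        return counts.get(activity, 0)

    @property
    def released_sequences(self) -> tuple[str, ...]:
        return tuple(sorted({m.fragment.sequence for m in self.matches}))


def scan_intact(
    record: ProteinRecord | str, db: PeptideDatabase, *, accession: str = ""
) -> IntactProfile:
    """Count every occurrence of every reference peptide in the intact chain.

    Overlapping occurrences at distinct start positions count separately;
    a peptide carrying k activities contributes its occurrences to all k
    per-category counts, and the total ``a_O`` is the sum over all
    categories.
    """
    if isinstance(record, ProteinRecord):
        sequence = record.sequence
        accession = record.accession
    else:
        sequence = record
    occurrences: dict[str, tuple[int, ...]] = {}
    category_counts: dict[Activity, int] = {}
    total = 0
    for peptide, entry in db.entries.items():
        positions = count_occurrences(sequence, peptide)
        if not positions:
            continue
        occurrences[peptide] = tuple(positions)
        for activity in entry.activities:
            category_counts[activity] = category_counts.get(activity, 0) + len(positions)
            total += len(positions)
    return IntactProfile(
        accession=accession,
        chain_length=len(sequence),
        occurrences=occurrences,
        category_counts=category_counts,
        total_count=total,
    )


def match_digest(
    fragments: Sequence[PeptideFragment],
    db: PeptideDatabase,
    *,
    accession: str = "",
) -> DigestProfile:
    """Match digest fragments against the reference database.

    A fragment matches iff its full sequence equals a reference peptide
    exactly; peptides still buried inside a longer fragment are not
    counted as released.
    """
    matches: list[DigestMatch] = []
    occurrence_counts: dict[Activity, int] = {}
    unique_seqs_per_cat: dict[Activity, set[str]] = {}
    matched_seqs: set[str] = set()
    for frag in fragments:
        entry = db.get(frag.sequence)
        if entry is None:
            continue
        matches.append(DigestMatch(frag, entry.activities))
        matched_seqs.add(entry.sequence)
        for activity in entry.activities:
            occurrence_counts[activity] = occurrence_counts.get(activity, 0) + 1
            unique_seqs_per_cat.setdefault(activity, set()).add(entry.sequence)
    chain_length = sum(len(f.sequence) for f in fragments)
    return DigestProfile(
        accession=accession,
        chain_length=chain_length,
        matches=tuple(matches),
        unique_counts={a: len(s) for a, s in unique_seqs_per_cat.items()},
        occurrence_counts=occurrence_counts,
        total_released=len(matched_seqs),
    )
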