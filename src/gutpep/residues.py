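"""The amino-acid alphabet shared by every module.

All sequences handled by the package are mature protein chains written in
one-letter code. The 20 standard residues are always accepted; the
ambiguity/rare codes (B, Z, X, U) are rejected by default because curated
mature chains should not contain them, but callers may opt in, in which
case such residues are carried along while never satisfying a cleavage
rule and never matching a reference peptide.
"""

from __future__ import annotations

STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA: frozenset[str] = frozenset("BZXU")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the accepted alphabet."""


def validate_sequence(
    sequence: str,
    *,
    name: str = "<sequence>",
    allow_ambiguous: bool = False,
) -> str:
    """Uppercase and validate a residue string.

    Parameters
    ----------
    sequence:
        Raw residue string (whitespace is not tolerated).
    name:
        Identifier used in error messages (record id, accession, ...).
    allow_ambiguous:
        Accept B/Z/X/U as inert residues instead of raising.

    Returns
    -------
    The uppercased sequence.

    Raises
    ------
    SequenceAlphabetError
        Naming the record and the 1-based position of the first offending
        character.
    """
    seq = sequence.upper()
    allowed = STANDARD_AA | AMBIGUOUS_AA if allow_ambiguous else STANDARD_AA
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceAlphabetError(
                f"record {name!r}: invalid residue {ch!r} at position {pos}"
            )
    return seq
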