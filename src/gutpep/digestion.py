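"""Rule-based enzymatic digestion of protein chains.

Cleavage specificity is declarative: an enzyme is an ordered list of
rules, each a conjunction of conditions over a local window of residues
around a candidate peptide bond. Window offsets follow protease
nomenclature: -1 is P1 (the residue N-terminal of the bond), +1 is P1'
(C-terminal), -2 is P2, and so on out to +/-4. A bond is cleaved iff

    (any permit rule fires OR any exception_permit rule fires)
    AND no exception_block rule fires.

A condition whose offset falls outside the chain makes its rule fail,
whatever the rule kind: truncated context can neither license nor veto a
cut through residues that do not exist.

Digestion is exhaustive and without kinetics: a multi-enzyme scenario
cuts at the union of the per-enzyme cleavage sites computed on the intact
chain, so the result is independent of enzyme order and a smaller enzyme
set always yields a coarser fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .registry import DigestionScenario
from .residues import STANDARD_AA

__all__ = [
    "CleavageRule",
    "EnzymeRuleSet",
    "PeptideFragment",
    "RuleSchemaError",
    "builtin_rulesets",
    "resolve_enzymes",
    "cleavage_sites",
    "digest",
    "load_ruleset",
    "save_ruleset",
    "ENZYME_ALIASES",
]

_KINDS = ("permit", "exception_permit", "exception_block")

#: scenario enzyme names -> default concrete specificity variant
ENZYME_ALIASES: dict[str, str] = {
    "pepsin": "pepsin_ph1.3",
    "chymotrypsin": "chymotrypsin_high",
}


class RuleSchemaError(ValueError):
    """A rule table violates the declarative-rule schema."""


@dataclass(frozen=True)
class CleavageRule:
    kind: str
    conditions: tuple[tuple[int, frozenset[str]], ...]  # sorted by offset

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise RuleSchemaError(f"rule kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.conditions:
            raise RuleSchemaError("rule has no conditions")
        for offset, residues in self.conditions:
            if offset == 0 or not -4 <= offset <= 4:
                raise RuleSchemaError(f"offset {offset} outside -4..+4 (0 forbidden)")
            if not residues or not residues <= STANDARD_AA:
                raise RuleSchemaError(
                    f"residue set at offset {offset} must be a non-empty subset "
                    f"of the standard alphabet, got {sorted(residues)}"
                )

    def fires(self, sequence: str, bond: int) -> bool:
        """True iff every condition holds around the bond after residue ``bond`` (1-based)."""
        n = len(sequence)
        for offset, residues in self.conditions:
            idx = bond + offset if offset < 0 else bond + offset - 1  # 0-based
            if idx < 0 or idx >= n:
                return False
            if sequence[idx] not in residues:
                return False
        return True


@dataclass(frozen=True)
class EnzymeRuleSet:
    name: str
    rules: tuple[CleavageRule, ...]

    def cleaves(self, sequence: str, bond: int) -> bool:
        permitted = False
        for rule in self.rules:
            if rule.kind == "exception_block":
                if rule.fires(sequence, bond):
                    return False
            elif not permitted and rule.fires(sequence, bond):
                permitted = True
        return permitted

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in _KINDS}
        for rule in self.rules:
            out[rule.kind] += 1
        return out


@dataclass(frozen=True)
class PeptideFragment:
    """A digest product with 1-based inclusive coordinates on the mature chain."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")


def _parse_residue_set(spec: str) -> frozenset[str]:
    if not isinstance(spec, str) or not spec:
        raise RuleSchemaError(f"residue set must be a non-empty string, got {spec!r}")
    if spec.startswith("^"):
        return frozenset(STANDARD_AA - set(spec[1:].upper()))
    return frozenset(spec.upper())


def _rule_from_mapping(raw: Mapping, index: int) -> CleavageRule:
    try:
        kind = raw["kind"]
        conditions = raw["conditions"]
    except (TypeError, KeyError) as exc:
        raise RuleSchemaError(f"rule {index}: missing field {exc}") from exc
    if not isinstance(conditions, Mapping) or not conditions:
        raise RuleSchemaError(f"rule {index}: conditions must be a non-empty mapping")
    try:
        parsed = tuple(
            sorted((int(off), _parse_residue_set(res)) for off, res in conditions.items())
        )
        return CleavageRule(kind=kind, conditions=parsed)
    except RuleSchemaError as exc:
        raise RuleSchemaError(f"rule {index}: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise RuleSchemaError(f"rule {index}: {exc}") from exc


def _residue_set_to_spec(residues: frozenset[str]) -> str:
    # prefer the complement notation when it is shorter
    if len(residues) > 10:
        return "^" + "".join(sorted(STANDARD_AA - residues))
    return "".join(sorted(residues))


def load_ruleset(path: str | Path) -> EnzymeRuleSet:
    """Load one enzyme rule table from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "name" not in doc or "rules" not in doc:
        raise RuleSchemaError(f"{path}: expected a mapping with 'name' and 'rules'")
    rules = tuple(_rule_from_mapping(raw, i) for i, raw in enumerate(doc["rules"]))
    if not any(r.kind == "permit" for r in rules):
        raise RuleSchemaError(f"{path}: rule set has no permit rule")
    return EnzymeRuleSet(name=str(doc["name"]), rules=rules)


def save_ruleset(ruleset: EnzymeRuleSet, path: str | Path) -> None:
    """Serialize a rule set back to its YAML file format."""
    doc = {
        "name": ruleset.name,
        "rules": [
            {
                "kind": rule.kind,
                "conditions": {off: _residue_set_to_spec(res) for off, res in rule.conditions},
            }
            for rule in ruleset.rules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_BUILTIN_NAMES = (
    "trypsin",
    "chymotrypsin_high",
    "chymotrypsin_low",
    "pepsin_ph1.3",
    "pepsin_ph_gt2",
)
_BUILTIN: dict[str, EnzymeRuleSet] | None = None


def builtin_rulesets() -> Mapping[str, EnzymeRuleSet]:
    """The five bundled enzyme rule tables, loaded from package data."""
    global _BUILTIN
    if _BUILTIN is None:
        base = resources.files("gutpep").joinpath("data", "enzymes")
        _BUILTIN = {
            name: load_ruleset(Path(str(base.joinpath(f"{name}.yaml"))))
            for name in _BUILTIN_NAMES
        }
    return _BUILTIN


def resolve_enzymes(
    names: Iterable[str],
    *,
    rulesets: Mapping[str, EnzymeRuleSet] | None = None,
    pepsin_variant: str = "pepsin_ph1.3",
    chymotrypsin_variant: str = "chymotrypsin_high",
) -> list[EnzymeRuleSet]:
    """Map scenario enzyme names (possibly aliases) to concrete rule sets."""
    if rulesets is None:
        rulesets = builtin_rulesets()
    variants = dict(ENZYME_ALIASES)
    variants["pepsin"] = pepsin_variant
    variants["chymotrypsin"] = chymotrypsin_variant
    out = []
    for name in names:
        key = variants.get(name, name)
        if key not in rulesets:
            raise KeyError(f"no rule set named {key!r}")
        out.append(rulesets[key])
    return out


def cleavage_sites(sequence: str, enzyme: EnzymeRuleSet) -> list[int]:
    """Bond indices cut by one enzyme: cut after residue ``i`` (1 <= i < N)."""
    return [i for i in range(1, len(sequence)) if enzyme.cleaves(sequence, i)]


def digest(
    sequence: str,
    scenario: DigestionScenario | Iterable[EnzymeRuleSet],
    **variant_kwargs,
) -> list[PeptideFragment]:
    """Fragments produced by exhaustive digestion under a scenario.

    The cut set is the union over the scenario's enzymes of the cleavage
    sites computed on the intact chain; fragments are the maximal runs
    between consecutive cuts, N- to C-terminal. Concatenating the
    fragment sequences reproduces the input exactly.
    """
    if isinstance(scenario, DigestionScenario):
        enzymes = resolve_enzymes(scenario.enzymes, **variant_kwargs)
    else:
        enzymes = list(scenario)
    cuts: set[int] = set()
    for enzyme in enzymes:
        cuts.update(cleavage_sites(sequence, enzyme))
    fragments: list[PeptideFragment] = []
    start = 1
    for cut in sorted(cuts) + [len(sequence)]:
        fragments.append(PeptideFragment(sequence[start - 1 : cut], start, cut))
        start = cut + 1
    if not sequence:
        return []
    return fragments
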