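"""Daily-quantity model: from released peptides per molecule to mg/day.

The conversion treats every released bioactive peptide as a reference
peptide of fixed small size (a dipeptide by default, since the large
majority of released bioactive peptides are dipeptides). For a protein of
molar mass ``M`` (Da) releasing ``n`` peptides per molecule,

    mg bioactive peptide per g protein = n * m_ref / M * 1000

where ``m_ref`` is the reference peptide mass: for a dipeptide, twice the
mean of the 20 free amino-acid average masses minus one water
(~255.8 Da). Scaling by grams of protein eaten (or secreted) per day
gives mg/day per diet item; multi-protein food items use the unweighted
mean of their member proteins' mg/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "AVERAGE_RESIDUE_MASSES",
    "WATER_MASS",
    "MassModel",
    "DEFAULT_MASS_MODEL",
    "DietItem",
    "EndogenousSupply",
    "QuantityEstimate",
    "protein_molar_mass",
    "mg_per_g",
    "daily_total",
    "load_diet_config",
]

#: Average (isotope-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

WATER_MASS = 18.02


@dataclass(frozen=True)
class MassModel:
    """Masses used by the quantity conversion."""

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES)
    )
    water: float = WATER_MASS
    reference_length: int = 2

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_masses.values()) or self.water <= 0:
            raise ValueError("all masses must be positive")
        if self.reference_length < 1:
            raise ValueError("reference peptide length must be >= 1")

    @property
    def reference_peptide_mass(self) -> float:
        """Mass (Da) of the reference released peptide.

        An L-mer of mean composition: L free amino acids condensed with
        loss of L-1 waters, i.e. ``L * mean(free aa mass) - (L-1) * water``.
        """
        mean_free = sum(self.residue_masses.values()) / len(self.residue_masses) + self.water
        return self.reference_length * mean_free - (self.reference_length - 1) * self.water


DEFAULT_MASS_MODEL = MassModel()


def protein_molar_mass(sequence: str, model: MassModel = DEFAULT_MASS_MODEL) -> float:
    """Average molar mass (Da) of a protein chain: residue masses + one water."""
    if not sequence:
        raise ValueError("empty sequence has no molar mass")
    try:
        return sum(model.residue_masses[aa] for aa in sequence.upper()) + model.water
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from exc


def mg_per_g(
    n_released: float, molar_mass: float, model: MassModel = DEFAULT_MASS_MODEL
) -> float:
    """mg of released bioactive peptide per g of protein.

    ``n_released`` peptides (of reference mass) per protein molecule of
    ``molar_mass`` Da. Unrounded; reports round to integer.
    """
    if n_released < 0:
        raise ValueError("released-peptide count must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return n_released * model.reference_peptide_mass / molar_mass * 1000.0


@dataclass(frozen=True)
class DietItem:
    """One protein-contributing food group of the model diet."""

    name: str
    grams_protein_per_day: float
    mg_per_g: float
    member_proteins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.grams_protein_per_day < 0:
            raise ValueError(f"{self.name}: grams of protein must be >= 0")

    @property
    def mg_per_day(self) -> float:
        return self.grams_protein_per_day * self.mg_per_g


@dataclass(frozen=True)
class EndogenousSupply:
    """Daily gut endogenous protein secretion and its mean release yield."""

    grams_protein_per_day: float
    mg_per_g: float

    @property
    def mg_per_day(self) -> float:
        return self.grams_protein_per_day * self.mg_per_g


@dataclass(frozen=True)
class QuantityEstimate:
    per_item_mg_per_day: Mapping[str, float]
    dietary_total_mg_per_day: float
    endogenous_total_mg_per_day: float | None = None


def daily_total(
    items: Sequence[DietItem], endogenous: EndogenousSupply | None = None
) -> QuantityEstimate:
    """Total predicted mg of bioactive peptides released per day."""
    per_item = {item.name: item.mg_per_day for item in items}
    return QuantityEstimate(
        per_item_mg_per_day=per_item,
        dietary_total_mg_per_day=sum(per_item.values()),
        endogenous_total_mg_per_day=endogenous.mg_per_day if endogenous else None,
    )


def load_diet_config(path: str | Path | None = None) -> dict:
    """Load the diet configuration (the bundled model diet by default)."""
    if path is None:
        path = Path(str(resources.files("gutpep").joinpath("data", "diet.yaml")))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "items" not in doc:
        raise ValueError(f"{path}: diet config must be a mapping with 'items'")
    return doc
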