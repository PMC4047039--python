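"""End-to-end orchestration: FASTA + peptide table -> profiles and quantities.

``run_profile`` computes, for every input protein, the intact occurrence
profile and — per applicable digestion scenario — the digest release
profile plus the listing of released peptides, and writes them as TSV
(primary) with a JSON machine twin. ``run_quantity`` converts a profile
bundle plus a diet configuration into the mg/g and mg/day table.
Reports contain integers (counts and rounded frequencies); the ``raw``
switch adds unrounded frequencies for auditing the rounding rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .biodb import PeptideDatabase, activity_name, fixture_db, load_db
from .digestion import digest
from .profiling import (
    DigestProfile,
    IntactProfile,
    freq_AD,
    match_digest,
    round_half_away,
    scan_intact,
)
from .quantity import (
    DEFAULT_MASS_MODEL,
    DietItem,
    EndogenousSupply,
    MassModel,
    QuantityEstimate,
    daily_total,
    load_diet_config,
    mg_per_g,
    protein_molar_mass,
)
from .registry import ProteinRecord, SCENARIOS, bundled_registry, read_fasta, scenarios_for

__all__ = ["RunConfig", "ProfileBundle", "run_profile", "run_quantity"]

log = logging.getLogger(__name__)

_TABULATED = list(range(1, 11))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    fasta: Path
    peptide_db: Path | None = None  # None -> bundled fixture
    registry: Path | None = None
    diet: Path | None = None
    out_dir: Path | None = None
    scenarios: tuple[str, ...] | None = None  # None -> per-protein assignment
    pepsin_variant: str = "pepsin_ph1.3"
    chymotrypsin_variant: str = "chymotrypsin_high"
    counting_mode: str = "unique"
    raw: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        if not self.fasta.exists():
            raise FileNotFoundError(f"FASTA not found: {self.fasta}")
        for attr in ("peptide_db", "registry", "diet"):
            value = getattr(self, attr)
            if value is not None:
                value = Path(value)
                if not value.exists():
                    raise FileNotFoundError(f"{attr} not found: {value}")
                setattr(self, attr, value)
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
        if self.counting_mode not in ("unique", "occurrence"):
            raise ValueError("counting_mode must be 'unique' or 'occurrence'")
        if self.scenarios is not None:
            self.scenarios = tuple(self.scenarios)
            unknown = set(self.scenarios) - set(SCENARIOS)
            if unknown:
                raise ValueError(f"unknown scenarios {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
            if v is not None
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (not output/log paths)."""
        relevant = {
            k: str(v)
            for k, v in asdict(self).items()
            if k not in ("out_dir", "log_level")
        }
        payload = json.dumps(relevant, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ProfileBundle:
    """All per-protein results of one profiling run."""

    records: tuple[ProteinRecord, ...]
    intact: Mapping[str, IntactProfile]  # accession -> profile
    digests: Mapping[tuple[str, str], DigestProfile]  # (accession, scenario) -> profile
    db_size: int
    counting_mode: str = "unique"

    def released(self, accession: str, scenario: str) -> tuple[str, ...]:
        return self.digests[(accession, scenario)].released_sequences


def _load_inputs(config: RunConfig):
    registry = bundled_registry(config.registry) if config.registry else bundled_registry()
    records = read_fasta(config.fasta, registry=registry)
    db = load_db(config.peptide_db) if config.peptide_db else fixture_db()
    return records, db


def run_profile(config: RunConfig) -> ProfileBundle:
    """Run the full intact-scan + digestion + matching analysis."""
    logging.getLogger("gutpep").setLevel(config.log_level)
    records, db = _load_inputs(config)
    log.info(
        "gutpep %s | config %s | %d proteins | %d reference peptides",
        __version__,
        config.config_hash(),
        len(records),
        len(db),
    )
    intact: dict[str, IntactProfile] = {}
    digests: dict[tuple[str, str], DigestProfile] = {}
    for record in records:
        intact[record.accession] = scan_intact(record, db)
        if config.scenarios is not None:
            applicable = [SCENARIOS[s] for s in config.scenarios]
        else:
            applicable = scenarios_for(record)
        for scenario in applicable:
            fragments = digest(
                record.sequence,
                scenario,
                pepsin_variant=config.pepsin_variant,
                chymotrypsin_variant=config.chymotrypsin_variant,
            )
            digests[(record.accession, scenario.label)] = match_digest(
                fragments, db, accession=record.accession
            )
    bundle = ProfileBundle(
        records=tuple(records),
        intact=intact,
        digests=digests,
        db_size=len(db),
        counting_mode=config.counting_mode,
    )
    if config.out_dir is not None:
        write_reports(bundle, config)
    return bundle


def _intact_frame(bundle: ProfileBundle, raw: bool) -> pd.DataFrame:
    rows = []
    for rec in bundle.records:
        prof = bundle.intact[rec.accession]
        row: dict = {"accession": rec.accession, "name": rec.name, "N": prof.chain_length}
        for cat in _TABULATED:
            row[f"count_{cat}"] = prof.category_counts.get(cat, 0)
            row[f"AO_{cat}"] = prof.category_AO(cat)
            row[f"Y_{cat}"] = (
                prof.category_Y(cat) if prof.total_count else 0
            )
        row["total_count"] = prof.total_count
        row["overall_AO"] = prof.overall_AO
        if raw:
            row["overall_AO_raw"] = 1000 * prof.total_count / prof.chain_length
        rows.append(row)
    return pd.DataFrame(rows)


def _digest_frame(bundle: ProfileBundle, raw: bool) -> pd.DataFrame:
    rows = []
    for (accession, scenario), prof in bundle.digests.items():
        row: dict = {
            "accession": accession,
            "scenario": scenario,
            "N": prof.chain_length,
        }
        for cat in _TABULATED:
            row[f"count_{cat}"] = prof.category_count(cat, bundle.counting_mode)
        row["total_released"] = prof.total_released
        row["AD"] = prof.AD
        if raw:
            row["AD_raw"] = 1000 * prof.total_released / prof.chain_length
        rows.append(row)
    return pd.DataFrame(rows)


def _released_frame(bundle: ProfileBundle) -> pd.DataFrame:
    rows = []
    for (accession, scenario), prof in sorted(bundle.digests.items()):
        for match in prof.matches:
            rows.append(
                {
                    "accession": accession,
                    "scenario": scenario,
                    "peptide": match.fragment.sequence,
                    "start": match.fragment.start,
                    "end": match.fragment.end,
                    "activities": ";".join(
                        sorted((activity_name(a) for a in match.activities), key=str)
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["accession", "scenario", "peptide", "start", "end", "activities"]
    )


def write_reports(bundle: ProfileBundle, config: RunConfig) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    frames = {
        "intact_profile": _intact_frame(bundle, config.raw),
        "digest_profile": _digest_frame(bundle, config.raw),
        "released_peptides": _released_frame(bundle),
    }
    twin: dict = {}
    for name, frame in frames.items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
        twin[name] = frame.to_dict(orient="records")
    json_path = out / "profile.json"
    with open(json_path, "w") as fh:
        json.dump(
            {"version": __version__, "config": config.config_hash(), "tables": twin},
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["json"] = json_path
    return paths


def run_quantity(
    config: RunConfig,
    bundle: ProfileBundle,
    *,
    mass_model: MassModel = DEFAULT_MASS_MODEL,
) -> pd.DataFrame:
    """Diet-model quantity report (mg/g and mg/day per food item).

    Each diet item's mg/g is the unweighted mean over its member proteins
    of ``n_released × reference-peptide mass / molar mass × 1000``, with
    ``n_released`` taken from the gastric+small-intestinal digest profile
    in ``bundle``. The endogenous pool uses the mean mg/g of its member
    proteins present in the bundle.
    """
    diet = load_diet_config(config.diet)
    by_accession = {rec.accession: rec for rec in bundle.records}

    def _protein_mg_per_g(accession: str) -> float:
        if accession not in by_accession:
            raise KeyError(
                f"diet references protein {accession!r} absent from the profile bundle"
            )
        key = (accession, "gastric_plus_small_intestinal")
        if key not in bundle.digests:
            raise KeyError(
                f"no gastric+small-intestinal digest profile for {accession!r}"
            )
        record = by_accession[accession]
        n = bundle.digests[key].total_released
        return mg_per_g(n, protein_molar_mass(record.sequence, mass_model), mass_model)

    items: list[DietItem] = []
    rows = []
    for spec in diet["items"]:
        members = tuple(spec["proteins"])
        values = [_protein_mg_per_g(acc) for acc in members]
        item_mg_g = sum(values) / len(values)
        item = DietItem(
            name=spec["name"],
            grams_protein_per_day=float(spec["grams_protein_per_day"]),
            mg_per_g=item_mg_g,
            member_proteins=members,
        )
        items.append(item)
        rows.append(
            {
                "item": item.name,
                "grams_protein_per_day": item.grams_protein_per_day,
                "mg_per_g": round_half_away(item.mg_per_g),
                "mg_per_day": round_half_away(item.mg_per_day),
            }
        )
    endo = None
    endo_spec = diet.get("endogenous")
    if endo_spec:
        members = [acc for acc in endo_spec["proteins"] if acc in by_accession]
        if members:
            values = [_protein_mg_per_g(acc) for acc in members]
            endo = EndogenousSupply(
                grams_protein_per_day=float(endo_spec["grams_protein_per_day"]),
                mg_per_g=sum(values) / len(values),
            )
    estimate = daily_total(items, endo)
    rows.append(
        {
            "item": "Dietary total",
            "grams_protein_per_day": sum(i.grams_protein_per_day for i in items),
            "mg_per_g": "",
            "mg_per_day": round_half_away(estimate.dietary_total_mg_per_day),
        }
    )
    if estimate.endogenous_total_mg_per_day is not None:
        rows.append(
            {
                "item": "Endogenous total",
                "grams_protein_per_day": endo.grams_protein_per_day,
                "mg_per_g": round_half_away(endo.mg_per_g),
                "mg_per_day": round_half_away(estimate.endogenous_total_mg_per_day),
            }
        )
    frame = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "quantity.tsv", sep="\t", index=False)
    return frame
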