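"""Readers/writers for the tabular schemas and the run configuration.

Input schemas (CSV, UTF-8, '.' decimal separator):

``animals.csv`` — one row per animal x gut location:
    animal_id, species, body_weight_kg, location, digesta_dm_g,
    tio2_pct_dm, aa_<KEY>_pct_dm ... (blank cell = not assayed)

``meals.csv`` — one row per species:
    species, fresh_milk_g_per_kg_bw, protein_g_per_kg_bw, dm_g_per_kg_bw,
    tio2_mg_per_g_dm, aa_<KEY>_mg_per_g_protein ...

Amino-acid column headers are resolved through the synonym map, so
``aa_Asp_pct_dm`` and ``aa_asparagine_pct_dm`` both land on the ASX pool.
Outputs are TSV; every output file starts with a comment line carrying the
package version, the configuration hash and the seed, so a run is fully
reconstructible from its artefacts.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .aminoacids import (
    AAGroupDef,
    AAProfile,
    Basis,
    canonicalize_aa_name,
    default_groups,
)
from .records import (
    AnimalRecord,
    CompartmentSample,
    GutLocation,
    MilkMeal,
    location_label,
    parse_location,
    validate_record,
)

_AA_ANIMAL_RE = re.compile(r"^aa_(.+)_pct_dm$", re.IGNORECASE)
_AA_MEAL_RE = re.compile(r"^aa_(.+)_mg_per_g_protein$", re.IGNORECASE)


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


def _aa_columns(columns: Sequence[str], pattern: re.Pattern) -> dict[str, str]:
    """Map canonical AA key -> column name for matching columns."""
    out: dict[str, str] = {}
    for col in columns:
        m = pattern.match(col)
        if m:
            key = canonicalize_aa_name(m.group(1)).value
            if key in out:
                raise SchemaError(f"duplicate amino-acid column for {key}: {col!r}")
            out[key] = col
    return out


def read_meals(path) -> dict[str, dict]:
    """Parse meals.csv into per-species meal templates."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {
        "species",
        "fresh_milk_g_per_kg_bw",
        "protein_g_per_kg_bw",
        "dm_g_per_kg_bw",
        "tio2_mg_per_g_dm",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"meals file missing columns {sorted(missing)}")
    aa_cols = _aa_columns(df.columns, _AA_MEAL_RE)
    if not aa_cols:
        raise SchemaError("meals file has no aa_<KEY>_mg_per_g_protein columns")
    meals: dict[str, dict] = {}
    for i, row in df.iterrows():
        sp = str(row["species"])
        if sp in meals:
            raise SchemaError(f"duplicate species {sp!r} in meals file (row {i})")
        comp = {}
        for key, col in aa_cols.items():
            v = row[col]
            if pd.notna(v):
                comp[key] = float(v)
        meals[sp] = {
            "protein_g_per_kg_bw": float(row["protein_g_per_kg_bw"]),
            "dm_g_per_kg_bw": float(row["dm_g_per_kg_bw"]),
            "tio2_mg_per_g_dm": float(row["tio2_mg_per_g_dm"]),
            "composition": AAProfile(comp, Basis.MG_PER_G_PROTEIN),
        }
    return meals


def read_cohort(animals_path, meals_path) -> list[AnimalRecord]:
    """Read and validate a cohort from animals.csv + meals.csv."""
    meals = read_meals(meals_path)
    df = pd.read_csv(animals_path, float_precision="round_trip")
    required = {
        "animal_id",
        "species",
        "body_weight_kg",
        "location",
        "digesta_dm_g",
        "tio2_pct_dm",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"animals file missing columns {sorted(missing)}")
    aa_cols = _aa_columns(df.columns, _AA_ANIMAL_RE)

    seen: set[tuple[str, GutLocation]] = set()
    by_animal: dict[str, dict] = {}
    for i, row in df.iterrows():
        aid = str(row["animal_id"])
        try:
            loc = parse_location(str(row["location"]))
        except ValueError as e:
            raise SchemaError(f"row {i}, column 'location': {e}") from None
        if (aid, loc) in seen:
            raise SchemaError(
                f"row {i}: duplicate sample for animal {aid!r} at {location_label(loc)}"
            )
        seen.add((aid, loc))
        dm = row["digesta_dm_g"]
        if pd.isna(dm) or float(dm) < 0:
            raise SchemaError(
                f"row {i}, column 'digesta_dm_g': must be a number >= 0, got {dm!r}"
            )
        marker = row["tio2_pct_dm"]
        marker_conc = None if pd.isna(marker) else float(marker)
        if marker_conc is not None and not 0 <= marker_conc <= 100:
            raise SchemaError(
                f"row {i}, column 'tio2_pct_dm': must lie in [0, 100], got {marker_conc}"
            )
        conc = {}
        for key, col in aa_cols.items():
            v = row[col]
            if pd.notna(v):
                conc[key] = float(v)
        sample = CompartmentSample(
            location=loc,
            digesta_dm=float(dm),
            marker_conc=marker_conc,
            aa_conc=AAProfile(conc, Basis.PCT_DM) if conc else None,
        )
        entry = by_animal.setdefault(
            aid, {"species": str(row["species"]), "bw": float(row["body_weight_kg"]), "samples": {}}
        )
        if entry["species"] != str(row["species"]):
            raise SchemaError(f"row {i}: species of animal {aid!r} is inconsistent")
        entry["samples"][loc] = sample

    records: list[AnimalRecord] = []
    for aid, entry in by_animal.items():
        sp = entry["species"]
        if sp not in meals:
            raise SchemaError(f"animal {aid!r}: species {sp!r} not in meals file")
        m = meals[sp]
        meal = MilkMeal(
            species=sp,
            body_weight=entry["bw"],
            protein_dose=m["protein_g_per_kg_bw"],
            marker_dose=m["tio2_mg_per_g_dm"],
            meal_dm=m["dm_g_per_kg_bw"] * entry["bw"],
            composition=m["composition"],
        )
        records.append(AnimalRecord(animal_id=aid, meal=meal, samples=entry["samples"]))
    return records


def write_cohort(records: Sequence[AnimalRecord], animals_path, meals_path) -> None:
    """Write a cohort back to the animals.csv / meals.csv schemas."""
    aa_keys = sorted({k for r in records for k in r.meal.composition.keys()})
    rows = []
    for r in records:
        for loc in sorted(r.samples, key=lambda l: l.value):
            s = r.samples[loc]
            row = {
                "animal_id": r.animal_id,
                "species": r.meal.species,
                "body_weight_kg": r.meal.body_weight,
                "location": location_label(loc),
                "digesta_dm_g": s.digesta_dm,
                "tio2_pct_dm": s.marker_conc,
            }
            for k in aa_keys:
                row[f"aa_{k}_pct_dm"] = s.aa_conc.get(k) if s.aa_conc else None
            rows.append(row)
    pd.DataFrame(rows).to_csv(animals_path, index=False)

    meal_rows = {}
    for r in records:
        m = r.meal
        row = {
            "species": m.species,
            "fresh_milk_g_per_kg_bw": float("nan"),
            "protein_g_per_kg_bw": m.protein_dose,
            "dm_g_per_kg_bw": m.meal_dm / m.body_weight,
            "tio2_mg_per_g_dm": m.marker_dose,
        }
        for k in aa_keys:
            row[f"aa_{k}_mg_per_g_protein"] = m.composition.get(k)
        meal_rows.setdefault(m.species, row)
    pd.DataFrame(list(meal_rows.values())).to_csv(meals_path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Serializable run settings; config + inputs determine all outputs."""

    groups: Optional[Mapping[str, Sequence[str]]] = None
    include_proline_in_neaa: bool = False
    group_policy: str = "strict"
    imputation_policy: str = "species_mean"
    alpha: float = 0.05
    seed: int = 0
    pct_decimals: int = 1
    ratio_decimals: int = 2
    log_level: str = "INFO"

    def group_defs(self) -> dict[str, AAGroupDef]:
        if self.groups is None:
            return default_groups(self.include_proline_in_neaa)
        return {
            name: AAGroupDef(name, frozenset(canonicalize_aa_name(m) for m in members))
            for name, members in self.groups.items()
        }

    def to_dict(self) -> dict:
        return {
            "groups": {k: sorted(v) for k, v in self.groups.items()} if self.groups else None,
            "include_proline_in_neaa": self.include_proline_in_neaa,
            "group_policy": self.group_policy,
            "imputation_policy": self.imputation_policy,
            "alpha": self.alpha,
            "seed": self.seed,
            "pct_decimals": self.pct_decimals,
            "ratio_decimals": self.ratio_decimals,
            "log_level": self.log_level,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys {sorted(unknown)}; accepted: {sorted(known)}")
    return RunConfig(**raw)


def write_tsv(df: pd.DataFrame, path, config: Optional[RunConfig] = None, seed=None) -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    import markerdigest

    cfg_hash = config.hash() if config is not None else "-"
    seed_str = str(seed) if seed is not None else (str(config.seed) if config else "-")
    with open(path, "w") as fh:
        fh.write(
            f"# markerdigest {markerdigest.__version__} config_hash={cfg_hash} seed={seed_str}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
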