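"""Bundled reference tables from a piglet milk-feeding digestibility study.

Three small published summary tables ship with the package and serve two
purposes: they parameterize the synthetic cohort generator's default study
conditions, and they are recomputable inputs for internal-consistency
checks (group aggregation, location contrasts).

- ``milk_composition``: amino-acid composition of raw bovine, caprine and
  ovine milk, mg per g protein (triplicate batch means).
- ``milk_meals``: per-species meal template (fresh milk, protein, dry
  matter per kg body weight; TiO2 dose per g DM).
- ``gastric_retention``: species x amino-acid mean gastric retention ratios
  (mg retained per mg consumed) at 210 min post-feeding, n=4.
- ``si_digestibility``: species means and 25%/75% location means of
  cumulative apparent small-intestinal digestibility (%), n=4.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .aminoacids import AAProfile, Basis


def _read(name: str) -> pd.DataFrame:
    with resources.files("markerdigest.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_milk_meals() -> pd.DataFrame:
    return _read("milk_meals.csv")


def load_milk_composition() -> pd.DataFrame:
    return _read("milk_composition.csv")


def load_gastric_retention() -> pd.DataFrame:
    return _read("gastric_retention.csv")


def load_si_digestibility() -> pd.DataFrame:
    return _read("si_digestibility.csv")


def milk_composition_profile(species: str) -> AAProfile:
    """Composition of one milk type as an AAProfile (mg per g protein)."""
    df = load_milk_composition()
    sub = df[df["species"] == species]
    if sub.empty:
        raise KeyError(f"no bundled composition for species {species!r}")
    return AAProfile(
        dict(zip(sub["aa"], sub["mg_per_g_protein"])), Basis.MG_PER_G_PROTEIN
    )


def gastric_retention_map(species: str) -> dict[str, float]:
    """Per-amino-acid mean gastric retention ratios for one species.

    Tryptophan and cysteine are absent from the bundled digesta retention
    table (not assayed); they default to the printed essential-group and
    non-essential-group totals respectively so that simulated cohorts carry
    a complete analyte set.
    """
    df = load_gastric_retention()
    sub = df[df["species"] == species]
    if sub.empty:
        raise KeyError(f"no bundled gastric retention for species {species!r}")
    out = dict(zip(sub["aa"], sub["retention_ratio"]))
    group_totals = {
        "bovine": {"TRP": 0.72, "CYS": 0.71},
        "caprine": {"TRP": 0.51, "CYS": 0.49},
        "ovine": {"TRP": 0.39, "CYS": 0.40},
    }
    for aa, v in group_totals.get(species, {}).items():
        out.setdefault(aa, v)
    return out
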