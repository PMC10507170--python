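"""TiO2 marker mass ledger.

The indigestible marker is dosed with the meal and recovered compartment by
compartment. For each small-intestinal location the ledger splits the
recovered marker into the amount that has appeared up to and including that
location ("until") and the amount already released past it ("after"); the
after/at ratio is what extrapolates unabsorbed nutrient outflow past a
sampling site. Whole-tract recovery (recovered / dosed) is reported but
never used to rescale masses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    SI_LOCATIONS,
    AnimalRecord,
    CompartmentSample,
    GutLocation,
    location_label,
)


class MissingMarkerError(ValueError):
    """A needed marker concentration is absent (imputation may intercept)."""


def marker_mass(sample: CompartmentSample) -> float:
    """Marker mass in one compartment, mg: DM (g) x conc (%DM) / 100 x 1000."""
    if sample.marker_conc is None:
        raise MissingMarkerError(
            f"{sample.location.name} sample has no marker concentration"
        )
    return sample.digesta_dm * sample.marker_conc / 100.0 * 1000.0


@dataclass(frozen=True)
class MarkerLedger:
    """Per-location marker masses (mg) with cumulative/downstream splits."""

    animal_id: str
    masses: Mapping[GutLocation, float]  # STOMACH, PSI, DSI, TI, LARGE_INTESTINE
    until: Mapping[GutLocation, float]
    after: Mapping[GutLocation, float]
    intake: float
    recovery: float
    ti_imputed: bool = False

    @property
    def total_recovered(self) -> float:
        return float(sum(self.masses.values()))


def _li_marker_mass(record: AnimalRecord) -> float:
    li = record.li_samples()
    if not li or all(s.marker_conc is None for s in li):
        raise MissingMarkerError("no large-intestine marker data")
    return sum(marker_mass(s) for s in li if s.marker_conc is not None)


def build_ledger(
    record: AnimalRecord, ti_marker_mg: Optional[float] = None
) -> MarkerLedger:
    """Build the marker ledger for one animal.

    ``ti_marker_mg`` overrides the terminal-ileum marker mass (the
    imputation pathway donates a mass, not a concentration); without it the
    terminal-ileum concentration must have been assayed.
    """
    masses: dict[GutLocation, float] = {}
    for loc in (GutLocation.STOMACH, GutLocation.PSI, GutLocation.DSI):
        s = record.sample(loc)
        if s is None:
            raise MissingMarkerError(f"no {loc.name} sample for {record.animal_id}")
        masses[loc] = marker_mass(s)
    ti_imputed = False
    if ti_marker_mg is not None:
        if ti_marker_mg < 0:
            raise ValueError("imputed terminal-ileum marker mass must be >= 0")
        masses[GutLocation.TI] = float(ti_marker_mg)
        ti = record.sample(GutLocation.TI)
        ti_imputed = ti is None or ti.marker_conc is None
    else:
        ti = record.sample(GutLocation.TI)
        if ti is None:
            raise MissingMarkerError(f"no terminal-ileum sample for {record.animal_id}")
        masses[GutLocation.TI] = marker_mass(ti)
    masses[GutLocation.LARGE_INTESTINE] = _li_marker_mass(record)

    until: dict[GutLocation, float] = {}
    after: dict[GutLocation, float] = {}
    running = masses[GutLocation.STOMACH]
    total = float(sum(masses.values()))
    for loc in SI_LOCATIONS:
        running += masses[loc]
        until[loc] = running
        after[loc] = total - running
    intake = record.meal.marker_intake_mg
    return MarkerLedger(
        animal_id=record.animal_id,
        masses=masses,
        until=until,
        after=after,
        intake=intake,
        recovery=total / intake,
        ti_imputed=ti_imputed,
    )


@dataclass(frozen=True)
class TIImputation:
    """Terminal-ileum marker mass for one animal, with provenance."""

    marker_mg: float
    imputed: bool
    donors: tuple[str, ...] = ()


class NoDonorError(ValueError):
    """No animal with a measured terminal-ileum marker is available."""


def _measured_ti_mass(record: AnimalRecord) -> Optional[float]:
    ti = record.sample(GutLocation.TI)
    if ti is None or ti.marker_conc is None:
        return None
    return marker_mass(ti)


def impute_terminal_marker(
    cohort: Sequence[AnimalRecord], policy: str = "species_mean"
) -> dict[str, TIImputation]:
    """Fill missing terminal-ileum marker masses from donor animals.

    Policies: ``species_mean`` (donors of the same species, falling back to
    the overall mean when a species has none), ``overall_mean`` (all
    measured animals), ``fail`` (raise on any missing value). Animals with a
    measured value are never changed.
    """
    if policy not in ("species_mean", "overall_mean", "fail"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    measured = {r.animal_id: _measured_ti_mass(r) for r in cohort}
    donors = {aid: m for aid, m in measured.items() if m is not None}
    out: dict[str, TIImputation] = {}
    for r in cohort:
        m = measured[r.animal_id]
        if m is not None:
            out[r.animal_id] = TIImputation(m, imputed=False)
            continue
        if policy == "fail":
            raise NoDonorError(
                f"terminal-ileum marker missing for {r.animal_id} under policy 'fail'"
            )
        pool = donors
        if policy == "species_mean":
            species_pool = {
                aid: v
                for aid, v in donors.items()
                if _species_of(cohort, aid) == r.meal.species
            }
            if species_pool:
                pool = species_pool
        if not pool:
            raise NoDonorError(
                "no animal with a measured terminal-ileum marker mass to donate"
            )
        out[r.animal_id] = TIImputation(
            float(np.mean(list(pool.values()))), imputed=True, donors=tuple(sorted(pool))
        )
    return out


def _species_of(cohort: Sequence[AnimalRecord], animal_id: str) -> str:
    for r in cohort:
        if r.animal_id == animal_id:
            return r.meal.species
    raise KeyError(animal_id)


def build_cohort_ledgers(
    cohort: Sequence[AnimalRecord], policy: str = "species_mean"
) -> dict[str, MarkerLedger]:
    """Impute terminal-ileum marker where needed and build every ledger."""
    imput = impute_terminal_marker(cohort, policy)
    return {
        r.animal_id: build_ledger(r, ti_marker_mg=imput[r.animal_id].marker_mg)
        for r in cohort
    }


def marker_distribution(ledgers: "Mapping[str, MarkerLedger] | Iterable[MarkerLedger]") -> pd.DataFrame:
    """Mean and SEM of the marker share (% of intake) per location."""
    if isinstance(ledgers, Mapping):
        ledgers = list(ledgers.values())
    else:
        ledgers = list(ledgers)
    if not ledgers:
        raise ValueError("no ledgers supplied")
    locs = [
        GutLocation.STOMACH,
        GutLocation.PSI,
        GutLocation.DSI,
        GutLocation.TI,
        GutLocation.LARGE_INTESTINE,
    ]
    rows = []
    for loc in locs:
        shares = np.array([100.0 * l.masses[loc] / l.intake for l in ledgers])
        sem = float(shares.std(ddof=1) / np.sqrt(len(shares))) if len(shares) > 1 else 0.0
        rows.append(
            {
                "location": location_label(loc),
                "mean_pct_of_intake": float(shares.mean()),
                "sem_pct_of_intake": sem,
            }
        )
    return pd.DataFrame(rows)


def ledger_table(ledgers: Mapping[str, MarkerLedger]) -> pd.DataFrame:
    """Long-format ledger export (one row per animal x location)."""
    rows = []
    for aid, l in ledgers.items():
        for loc, mass in l.masses.items():
            rows.append(
                {
                    "animal_id": aid,
                    "location": location_label(loc),
                    "marker_mg": mass,
                    "pct_of_intake": 100.0 * mass / l.intake,
                    "until_mg": l.until.get(loc, np.nan),
                    "after_mg": l.after.get(loc, np.nan),
                    "recovery": l.recovery,
                    "imputed": l.ti_imputed and loc is GutLocation.TI,
                }
            )
    return pd.DataFrame(rows)
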