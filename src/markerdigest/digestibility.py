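"""Regional apparent amino-acid digestibility by the marker-ratio method.

For a small-intestinal location at fractional length x, the unabsorbed
amino-acid mass is the cumulative digesta content up to that location plus
the outflow already released past it, extrapolated by the marker ratio:

    released_after(loc) = AA(loc) * marker_after(loc) / marker(loc)
    unabsorbed(loc)     = AA(stomach) + sum AA(compartments <= loc) + released_after(loc)
    apparent(%)         = (intake - unabsorbed) / intake * 100

Correcting intake for the amino acids still retained in the stomach gives
the digestibility of the material actually available for uptake:

    entering    = intake - AA(stomach)
    available(%) = (entering - (unabsorbed - AA(stomach))) / entering * 100

so that, exactly, apparent = available * (1 - gastric retention). Group
digestibilities are computed on summed member masses, not on averaged
member digestibilities. Apparent values may be negative (stomach contents
exceeding intake, e.g. residual protein from an earlier meal) and are never
clipped; available digestibility is undefined when nothing entered the
small intestine.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aminoacids import AAGroupDef, AminoAcid, canonicalize_aa_name, default_groups
from .marker import MarkerLedger, build_cohort_ledgers
from .records import SI_LOCATIONS, AnimalRecord, CompartmentSample, GutLocation, location_label


class MissingAnalyteError(KeyError):
    """A requested amino acid is absent from a sample's profile."""


class ZeroMarkerError(ZeroDivisionError):
    """Marker mass at the location is zero; the extrapolation is undefined."""


class ZeroIntakeError(ZeroDivisionError):
    """Dietary intake of the analyte is zero."""


def aa_mass(sample: CompartmentSample, aa: "str | AminoAcid") -> float:
    """Amino-acid mass in one compartment, mg: DM (g) x conc (%DM) / 100 x 1000."""
    key = canonicalize_aa_name(str(aa)).value
    if sample.aa_conc is None or key not in sample.aa_conc:
        raise MissingAnalyteError(
            f"{key} not assayed in {sample.location.name} sample"
        )
    return sample.digesta_dm * sample.aa_conc[key] / 100.0 * 1000.0


def _analyte_mass(sample: CompartmentSample, analyte, members: Optional[Sequence[AminoAcid]]) -> float:
    if members is None:
        return aa_mass(sample, analyte)
    return sum(aa_mass(sample, m) for m in members)


def _analyte_intake(record: AnimalRecord, analyte, members) -> float:
    if members is None:
        return record.meal.aa_intake_mg(analyte)
    return sum(record.meal.aa_intake_mg(m) for m in members)


def gastric_retention(record: AnimalRecord, aa, members=None) -> float:
    """Gastric retention ratio: mg retained in the stomach per mg consumed.

    Values above 1 are possible (residual material from an earlier meal)
    and are passed through, not clipped.
    """
    intake = _analyte_intake(record, aa, members)
    if intake <= 0:
        raise ZeroIntakeError(f"zero dietary intake of {aa}")
    stomach = record.sample(GutLocation.STOMACH)
    if stomach is None:
        raise MissingAnalyteError("no stomach sample")
    return _analyte_mass(stomach, aa, members) / intake


def released_after(
    record: AnimalRecord, ledger: MarkerLedger, loc: GutLocation, aa, members=None
) -> float:
    """Analyte mass already released past ``loc``, by the marker ratio."""
    if loc not in SI_LOCATIONS:
        raise ValueError("released_after is defined for small-intestinal locations")
    marker_at = ledger.masses[loc]
    after = ledger.after[loc]
    if after == 0:
        return 0.0
    if marker_at <= 0:
        raise ZeroMarkerError(
            f"zero marker mass at {loc.name} for {record.animal_id}"
        )
    sample = record.sample(loc)
    if sample is None:
        raise MissingAnalyteError(f"no {loc.name} sample")
    return _analyte_mass(sample, aa, members) * after / marker_at


def unabsorbed_mass(
    record: AnimalRecord, ledger: MarkerLedger, loc: GutLocation, aa, members=None
) -> float:
    """Cumulative unabsorbed analyte mass at ``loc`` (stomach included), mg."""
    stomach = record.sample(GutLocation.STOMACH)
    if stomach is None:
        raise MissingAnalyteError("no stomach sample")
    total = _analyte_mass(stomach, aa, members)
    for l in SI_LOCATIONS:
        s = record.sample(l)
        if s is None:
            raise MissingAnalyteError(f"no {l.name} sample")
        total += _analyte_mass(s, aa, members)
        if l is loc:
            break
    total += released_after(record, ledger, loc, aa, members)
    return total


def apparent_digestibility(
    record: AnimalRecord, ledger: MarkerLedger, loc: GutLocation, aa, members=None
) -> float:
    """Cumulative apparent digestibility (%) up to position ``loc``."""
    intake = _analyte_intake(record, aa, members)
    if intake <= 0:
        raise ZeroIntakeError(f"zero dietary intake of {aa}")
    return (intake - unabsorbed_mass(record, ledger, loc, aa, members)) / intake * 100.0


def available_digestibility(
    record: AnimalRecord, ledger: MarkerLedger, loc: GutLocation, aa, members=None
) -> float:
    """Digestibility (%) of the analyte that actually entered the small intestine.

    Returns NaN when the stomach retained the whole intake or more
    (entering mass <= 0), where the quantity is undefined.
    """
    intake = _analyte_intake(record, aa, members)
    stomach = record.sample(GutLocation.STOMACH)
    if stomach is None:
        raise MissingAnalyteError("no stomach sample")
    stomach_mg = _analyte_mass(stomach, aa, members)
    entering = intake - stomach_mg
    if entering <= 0:
        return float("nan")
    unabs_avail = unabsorbed_mass(record, ledger, loc, aa, members) - stomach_mg
    return (entering - unabs_avail) / entering * 100.0


def absorbed_per_g_protein(
    record: AnimalRecord, ledger: MarkerLedger, loc: GutLocation, aa, members=None
) -> float:
    """Apparent amount absorbed up to ``loc``, mg per g protein consumed."""
    protein = record.meal.protein_consumed_g
    if protein <= 0:
        raise ZeroIntakeError("zero protein consumed")
    intake = _analyte_intake(record, aa, members)
    return (intake - unabsorbed_mass(record, ledger, loc, aa, members)) / protein


def _common_analytes(record: AnimalRecord) -> list[str]:
    """Amino acids assayed in the meal and in every compartment that needs them."""
    keys = set(record.meal.composition.keys())
    for loc in (GutLocation.STOMACH, *SI_LOCATIONS):
        s = record.sample(loc)
        if s is None or s.aa_conc is None:
            return []
        keys &= set(s.aa_conc.keys())
    return sorted(keys)


def digest_record(
    record: AnimalRecord,
    ledger: MarkerLedger,
    groups: Optional[Mapping[str, AAGroupDef]] = None,
    group_policy: str = "strict",
) -> list[dict]:
    """All digestibility rows for one animal (individual AAs then groups)."""
    if groups is None:
        groups = default_groups()
    analytes: list[tuple[str, Optional[tuple[AminoAcid, ...]]]] = [
        (a, None) for a in _common_analytes(record)
    ]
    present = {a for a, _ in analytes}
    for name, g in groups.items():
        members = tuple(sorted(g.members, key=lambda m: m.value))
        missing = [m for m in members if m.value not in present]
        if missing:
            if group_policy == "strict":
                raise MissingAnalyteError(
                    f"group {name} members missing from record "
                    f"{record.animal_id}: {[m.value for m in missing]}"
                )
            members = tuple(m for m in members if m.value in present)
            if not members:
                continue
        analytes.append((name, members))

    stomach = record.sample(GutLocation.STOMACH)
    rows: list[dict] = []
    for analyte, members in analytes:
        intake = _analyte_intake(record, analyte, members)
        stomach_mg = _analyte_mass(stomach, analyte, members)
        retention = stomach_mg / intake if intake > 0 else float("nan")
        entering = intake - stomach_mg
        for loc in SI_LOCATIONS:
            flags: list[str] = []
            if ledger.ti_imputed:
                flags.append("imputed_ti_marker")
            if retention > 1:
                flags.append("retention_over_unity")
            try:
                unabs = unabsorbed_mass(record, ledger, loc, analyte, members)
                rel_after = released_after(record, ledger, loc, analyte, members)
                app = (intake - unabs) / intake * 100.0 if intake > 0 else float("nan")
                absorbed = (intake - unabs) / record.meal.protein_consumed_g
            except ZeroMarkerError:
                flags.append("zero_marker_at_location")
                unabs = rel_after = app = absorbed = float("nan")
            if entering > 0 and np.isfinite(unabs):
                avail = (entering - (unabs - stomach_mg)) / entering * 100.0
            else:
                avail = float("nan")
                if entering <= 0:
                    flags.append("available_undefined")
            rows.append(
                {
                    "animal_id": record.animal_id,
                    "species": record.meal.species,
                    "analyte": analyte,
                    "is_group": members is not None,
                    "location": location_label(loc),
                    "si_position": loc.si_position,
                    "intake_mg": intake,
                    "stomach_mg": stomach_mg,
                    "entering_mg": entering,
                    "retention_ratio": retention,
                    "released_after_mg": rel_after,
                    "unabsorbed_mg": unabs,
                    "unabsorbed_available_mg": unabs - stomach_mg
                    if np.isfinite(unabs)
                    else float("nan"),
                    "apparent_dig_pct": app,
                    "available_dig_pct": avail,
                    "absorbed_mg_per_g_protein": absorbed,
                    "flags": ";".join(flags),
                }
            )
    return rows


def digest_cohort(
    cohort: Sequence[AnimalRecord],
    groups: Optional[Mapping[str, AAGroupDef]] = None,
    group_policy: str = "strict",
    imputation_policy: str = "species_mean",
    ledgers: Optional[Mapping[str, MarkerLedger]] = None,
) -> pd.DataFrame:
    """Long table of digestibility results for a validated cohort.

    One row per animal x analyte x small-intestinal position; group rows are
    computed on summed member masses. Per-row failures (zero marker at a
    location) are recorded as NaN values with a flag, and the run continues.
    """
    if ledgers is None:
        ledgers = build_cohort_ledgers(cohort, imputation_policy)
    rows: list[dict] = []
    for record in cohort:
        rows.extend(digest_record(record, ledgers[record.animal_id], groups, group_policy))
    return pd.DataFrame(rows)
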