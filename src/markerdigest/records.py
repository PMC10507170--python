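"""Per-animal data model: meal, gut compartments, and record validation.

A single-time-point digesta study collects, per animal, the entire digesta
of an ordered series of gut compartments (stomach; proximal and distal
halves of the small intestine; the last ~20 cm of ileum; large intestine)
after one marked meal. Each compartment sample carries its freeze-dried
digesta mass and the TiO2 and amino-acid concentrations on a dry-matter
basis. All downstream mass arithmetic is in milligrams.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .aminoacids import AAProfile, Basis, canonicalize_aa_name


class GutLocation(Enum):
    """Ordered gut compartments; SI locations carry a fractional position.

    The proximal and distal small-intestine samples are taken to represent
    the midpoints of their segments, i.e. the 25% and 75% positions of
    small-intestinal length; the terminal ileum represents 100%.
    """

    STOMACH = 0
    PSI = 1
    DSI = 2
    TI = 3
    CECUM = 4
    PROX_COLON = 5
    DIST_COLON = 6
    LARGE_INTESTINE = 7  # pooled pseudo-location for cecum + colon

    def __lt__(self, other: "GutLocation") -> bool:
        return self.value < other.value

    @property
    def si_position(self) -> Optional[float]:
        return SI_POSITIONS.get(self)


SI_POSITIONS: dict[GutLocation, float] = {
    GutLocation.PSI: 0.25,
    GutLocation.DSI: 0.75,
    GutLocation.TI: 1.0,
}
SI_LOCATIONS: tuple[GutLocation, ...] = (GutLocation.PSI, GutLocation.DSI, GutLocation.TI)
LI_LOCATIONS: tuple[GutLocation, ...] = (
    GutLocation.CECUM,
    GutLocation.PROX_COLON,
    GutLocation.DIST_COLON,
    GutLocation.LARGE_INTESTINE,
)

_LOCATION_LABELS = {
    GutLocation.STOMACH: "stomach",
    GutLocation.PSI: "psi",
    GutLocation.DSI: "dsi",
    GutLocation.TI: "ti",
    GutLocation.CECUM: "cecum",
    GutLocation.PROX_COLON: "prox_colon",
    GutLocation.DIST_COLON: "dist_colon",
    GutLocation.LARGE_INTESTINE: "li",
}
_LABEL_TO_LOCATION = {v: k for k, v in _LOCATION_LABELS.items()}


def location_label(loc: GutLocation) -> str:
    return _LOCATION_LABELS[loc]


def parse_location(label: str) -> GutLocation:
    try:
        return _LABEL_TO_LOCATION[label.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown gut location {label!r}; accepted: {sorted(_LABEL_TO_LOCATION)}"
        ) from None


@dataclass(frozen=True)
class MilkMeal:
    """One marked milk meal, normalised for protein dose.

    Parameters
    ----------
    species : str
        Milk source label (``bovine``, ``caprine``, ``ovine`` or custom).
    body_weight : float
        Animal body weight, kg.
    protein_dose : float
        Protein offered, g per kg body weight (study convention: 2).
    marker_dose : float
        TiO2 inclusion, mg per g meal dry matter.
    meal_dm : float
        Meal dry matter consumed, g.
    composition : AAProfile
        Amino-acid composition, mg per g protein.
    """

    species: str
    body_weight: float
    protein_dose: float
    marker_dose: float
    meal_dm: float
    composition: AAProfile

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.protein_dose <= 0 or self.marker_dose <= 0 or self.meal_dm <= 0:
            raise ValueError("protein_dose, marker_dose and meal_dm must be > 0")
        if self.composition.basis is not Basis.MG_PER_G_PROTEIN:
            raise ValueError("meal composition must be on the mg_per_g_protein basis")

    @property
    def protein_consumed_g(self) -> float:
        return self.protein_dose * self.body_weight

    @property
    def marker_intake_mg(self) -> float:
        return self.marker_dose * self.meal_dm

    def aa_intake(self) -> AAProfile:
        """Dietary amino-acid intake in mg (composition x protein consumed)."""
        return self.composition.scale(self.protein_consumed_g, Basis.MG_TOTAL)

    def aa_intake_mg(self, aa) -> float:
        return self.composition[canonicalize_aa_name(str(aa))] * self.protein_consumed_g


@dataclass(frozen=True)
class CompartmentSample:
    """Digesta of one gut compartment: DM mass plus %DM concentrations."""

    location: GutLocation
    digesta_dm: float  # g freeze-dried digesta
    marker_conc: Optional[float] = None  # TiO2, % of DM; None = not assayed
    aa_conc: Optional[AAProfile] = None  # % of DM

    def __post_init__(self) -> None:
        if self.digesta_dm < 0:
            raise ValueError("digesta_dm must be >= 0")
        if self.marker_conc is not None and not (0 <= self.marker_conc <= 100):
            raise ValueError("marker_conc must lie in [0, 100] %DM")
        if self.aa_conc is not None:
            if self.aa_conc.basis is not Basis.PCT_DM:
                raise ValueError("compartment aa_conc must be on the pct_DM basis")
            for k, v in self.aa_conc.items():
                if v > 100:
                    raise ValueError(f"aa_conc[{k}] exceeds 100 %DM")


@dataclass(frozen=True)
class AnimalRecord:
    """All compartment samples of one animal plus its meal."""

    animal_id: str
    meal: MilkMeal
    samples: Mapping[GutLocation, CompartmentSample] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = dict(self.samples)
        for loc, s in samples.items():
            if s.location is not loc:
                raise ValueError(
                    f"sample keyed {loc.name} reports location {s.location.name}"
                )
        object.__setattr__(self, "samples", samples)

    def sample(self, loc: GutLocation) -> Optional[CompartmentSample]:
        return self.samples.get(loc)

    def li_samples(self) -> list[CompartmentSample]:
        return [self.samples[l] for l in LI_LOCATIONS if l in self.samples]


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``code`` is machine-readable."""

    code: str
    location: Optional[str]
    message: str


def validate_record(record: AnimalRecord, allow_missing_ti_marker: bool = True) -> list[Violation]:
    """Report-style validation; an empty list means the record is usable.

    The stomach, PSI and DSI samples must carry both marker and amino-acid
    concentrations; the terminal ileum must be present with amino-acid data
    (its marker may be missing when imputation will supply it); at least one
    large-intestine sample with marker data is required for the downstream
    marker pool.
    """
    v: list[Violation] = []
    for loc in (GutLocation.STOMACH, GutLocation.PSI, GutLocation.DSI):
        s = record.sample(loc)
        name = loc.name
        if s is None:
            v.append(Violation("missing-location", name, f"no {name} sample"))
            continue
        if s.marker_conc is None:
            v.append(Violation("missing-marker", name, f"{name} lacks marker_conc"))
        if s.aa_conc is None or len(s.aa_conc) == 0:
            v.append(Violation("missing-aa", name, f"{name} lacks aa_conc"))
    ti = record.sample(GutLocation.TI)
    if ti is None:
        v.append(Violation("missing-location", "TI", "no terminal-ileum sample"))
    else:
        if ti.aa_conc is None or len(ti.aa_conc) == 0:
            v.append(Violation("missing-aa", "TI", "terminal ileum lacks aa_conc"))
        if ti.marker_conc is None and not allow_missing_ti_marker:
            v.append(Violation("missing-marker", "TI", "terminal ileum lacks marker_conc"))
    li = record.li_samples()
    if not li:
        v.append(Violation("missing-location", "LI", "no large-intestine sample"))
    elif all(s.marker_conc is None for s in li):
        v.append(Violation("missing-marker", "LI", "large intestine lacks marker_conc"))
    return v
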