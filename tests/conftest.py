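import numpy as np
import pytest

from markerdigest import (
    AAProfile,
    AnimalRecord,
    Basis,
    CompartmentSample,
    GutLocation,
    MilkMeal,
    build_ledger,
)


@pytest.fixture
def t1_record() -> AnimalRecord:
    """Hand-constructed single-analyte animal with round mass balance.

    Marker intake 100 mg split 50/10/25/2/13 over stomach/PSI/DSI/TI/LI;
    leucine intake 100 mg with 50/8/15/1 mg in stomach/PSI/DSI/TI. All
    downstream expectations are hand-computable from these masses.
    """
    meal = MilkMeal(
        species="bovine",
        body_weight=5.0,
        protein_dose=2.0,
        marker_dose=5.0,
        meal_dm=20.0,
        composition=AAProfile({"LEU": 10.0}, Basis.MG_PER_G_PROTEIN),
    )

    def sample(loc, dm, marker, leu=None):
        return CompartmentSample(
            location=loc,
            digesta_dm=dm,
            marker_conc=marker,
            aa_conc=AAProfile({"LEU": leu}, Basis.PCT_DM) if leu is not None else None,
        )

    samples = {
        GutLocation.STOMACH: sample(GutLocation.STOMACH, 10.0, 0.5, 0.5),
        GutLocation.PSI: sample(GutLocation.PSI, 2.0, 0.5, 0.4),
        GutLocation.DSI: sample(GutLocation.DSI, 5.0, 0.5, 0.3),
        GutLocation.TI: sample(GutLocation.TI, 0.4, 0.5, 0.25),
        GutLocation.LARGE_INTESTINE: sample(GutLocation.LARGE_INTESTINE, 2.6, 0.5),
    }
    return AnimalRecord(animal_id="T1", meal=meal, samples=samples)


@pytest.fixture
def t1_ledger(t1_record):
    return build_ledger(t1_record)


def random_record(rng: np.random.Generator, animal_id: str = "R") -> AnimalRecord:
    """A random valid record (positive masses, in-range concentrations)."""
    bw = rng.uniform(4.0, 6.5)
    meal = MilkMeal(
        species=rng.choice(["bovine", "caprine", "ovine"]),
        body_weight=bw,
        protein_dose=2.0,
        marker_dose=rng.uniform(5.1, 5.8),
        meal_dm=rng.uniform(5.0, 8.0) * bw,
        composition=AAProfile(
            {"LEU": rng.uniform(40, 80), "LYS": rng.uniform(20, 45)},
            Basis.MG_PER_G_PROTEIN,
        ),
    )
    samples = {}
    for loc in (
        GutLocation.STOMACH,
        GutLocation.PSI,
        GutLocation.DSI,
        GutLocation.TI,
        GutLocation.LARGE_INTESTINE,
    ):
        samples[loc] = CompartmentSample(
            location=loc,
            digesta_dm=rng.uniform(0.2, 20.0),
            marker_conc=rng.uniform(0.01, 2.0),
            aa_conc=AAProfile(
                {"LEU": rng.uniform(0.0, 3.0), "LYS": rng.uniform(0.0, 2.0)},
                Basis.PCT_DM,
            ),
        )
    return AnimalRecord(animal_id=animal_id, meal=meal, samples=samples)
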