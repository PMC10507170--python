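"""Cohort statistics: describe, one-way Tukey letters, blocked two-factor ANOVA."""
import itertools

import numpy as np
import pandas as pd
import pytest

from markerdigest import describe, oneway_tukey, two_factor_blocked
from markerdigest.stats import EmptyGroupError, compact_letters


def test_describe_hand_values():
    out = describe({"g": [1.0, 2.0, 3.0]}).set_index("group")
    assert out.loc["g", "mean"] == pytest.approx(2.0)
    assert out.loc["g", "sem"] == pytest.approx(0.5774, abs=1e-4)


def test_describe_singleton_and_constant():
    out = describe({"one": [5.0], "const": [2.0, 2.0, 2.0]}).set_index("group")
    assert np.isnan(out.loc["one", "sem"])
    assert out.loc["const", "sem"] == 0.0
    zero = describe({"one": [5.0]}, single_sem="zero").set_index("group")
    assert zero.loc["one", "sem"] == 0.0
    with pytest.raises(EmptyGroupError):
        describe({"empty": []})


def test_compact_letters_pairwise_consistency():
    """Levels sharing a letter are exactly the non-significant pairs."""
    means = {"a": 10.0, "b": 9.0, "c": 1.0}
    sig = {frozenset(("a", "c")), frozenset(("b", "c"))}
    letters = compact_letters(list(means), means, sig)
    for x, y in itertools.combinations(means, 2):
        share = set(letters[x]) & set(letters[y])
        assert bool(share) == (frozenset((x, y)) not in sig)


def test_oneway_equal_means_share_letter():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, size=4)
    groups = {s: base for s in ("x", "y", "z")}
    ct = oneway_tukey(groups)
    assert len({ct.letters[l] for l in ct.levels}) == 1


def test_oneway_well_separated_groups_get_distinct_letters():
    """Two groups 10 sd apart at n=4 must be declared different."""
    rng = np.random.default_rng(1)
    groups = {
        "lo": rng.normal(0.0, 1.0, 4),
        "hi": rng.normal(10.0, 1.0, 4),
    }
    ct = oneway_tukey(groups)
    assert ct.letters["hi"] == "a"
    assert ct.letters["lo"] == "b"
    assert ct.p_values["group"] < 0.001


def test_oneway_degenerate_variance_flagged():
    ct = oneway_tukey({"x": [1.0, 1.0], "y": [1.0, 1.0]})
    assert ct.degenerate
    assert ct.p_values["group"] == 1.0


def _toy_blocked(seed=0, sp_effect=(0.0, 1.0, 2.0), loc_effect=(0.0, 1.0),
                 interaction=0.0, sd=1.0, n_animals=4):
    rng = np.random.default_rng(seed)
    rows = []
    for si, sp in enumerate(("bovine", "caprine", "ovine")):
        for a in range(n_animals):
            animal_effect = rng.normal(0, 0.5)
            for li, loc in enumerate(("psi", "dsi")):
                val = (
                    sp_effect[si]
                    + loc_effect[li]
                    + interaction * si * li
                    + animal_effect
                    + rng.normal(0, sd)
                )
                rows.append(
                    {"species": sp, "animal_id": f"{sp}{a}", "location": loc, "value": val}
                )
    return pd.DataFrame(rows)


def hand_blocked_anova(df):
    """Brute-force sums of squares for the balanced species x location
    design with animal as block (independent oracle)."""
    grand = df["value"].mean()
    n = len(df)
    sp_means = df.groupby("species")["value"].mean()
    an_means = df.groupby("animal_id")["value"].mean()
    loc_means = df.groupby("location")["value"].mean()
    cell_means = df.groupby(["species", "location"])["value"].mean()
    n_sp = df.groupby("species").size()
    n_an = df.groupby("animal_id").size()
    n_loc = df.groupby("location").size()
    n_cell = df.groupby(["species", "location"]).size()
    ss_sp = float((n_sp * (sp_means - grand) ** 2).sum())
    sp_of_animal = df.drop_duplicates("animal_id").set_index("animal_id")["species"]
    ss_an = float(
        sum(
            n_an[a] * (an_means[a] - sp_means[sp_of_animal[a]]) ** 2
            for a in an_means.index
        )
    )
    ss_loc = float((n_loc * (loc_means - grand) ** 2).sum())
    ss_cells = float((n_cell * (cell_means - grand) ** 2).sum())
    ss_int = ss_cells - ss_sp - ss_loc
    return ss_sp, ss_an, ss_loc, ss_int


def test_blocked_anova_matches_hand_sums_of_squares():
    df = _toy_blocked(seed=3)
    ct = two_factor_blocked(df)
    ss_sp, ss_an, ss_loc, ss_int = hand_blocked_anova(df)
    from scipy import stats as sps

    df_sp, df_an, df_loc, df_int = 2, 9, 1, 2
    f_sp = (ss_sp / df_sp) / (ss_an / df_an)
    p_sp = float(sps.f.sf(f_sp, df_sp, df_an))
    assert ct.p_values["species"] == pytest.approx(p_sp, rel=1e-9)


def test_blocked_anova_drops_nonsignificant_interaction_and_detects_mains():
    hits_sp = hits_loc = retained = 0
    reps = 40
    for rep in range(reps):
        df = _toy_blocked(seed=100 + rep, sp_effect=(0.0, 2.0, 4.0),
                          loc_effect=(0.0, 2.0), interaction=0.0, sd=0.8)
        ct = two_factor_blocked(df)
        hits_sp += ct.p_values["species"] <= 0.05
        hits_loc += ct.p_values["location"] <= 0.05
        retained += ct.interaction_retained
    assert hits_sp / reps > 0.8
    assert hits_loc / reps > 0.8
    assert retained / reps < 0.3


def test_blocked_anova_retains_large_interaction():
    retained = 0
    reps = 40
    for rep in range(reps):
        df = _toy_blocked(seed=500 + rep, sp_effect=(0, 0, 0), loc_effect=(0, 0),
                          interaction=5.0, sd=0.8)
        ct = two_factor_blocked(df)
        retained += ct.interaction_retained
    assert retained / reps >= 0.9


def test_blocked_anova_degenerate_all_equal():
    df = _toy_blocked(seed=1, sp_effect=(0, 0, 0), loc_effect=(0, 0), sd=0.0)
    df["value"] = 3.14
    ct = two_factor_blocked(df)
    assert ct.degenerate
    assert all(p == 1.0 for p in ct.p_values.values())


def test_blocked_anova_tukey_letters_separate_species():
    df = _toy_blocked(seed=7, sp_effect=(0.0, 8.0, 16.0), loc_effect=(0.0, 1.0), sd=0.5)
    ct = two_factor_blocked(df)
    assert ct.letters["ovine"] == "a"
    assert ct.letters["caprine"] == "b"
    assert ct.letters["bovine"] == "c"
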