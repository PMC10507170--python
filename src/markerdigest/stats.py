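"""Simplified cohort statistics: means +/- SEM, one-way ANOVA with Tukey
compact letter display, and a blocked two-factor (milk x location) ANOVA
with the drop-nonsignificant-interaction rule.

This is a deliberately simplified reanalysis layer. The original mixed-model
machinery (REML covariance-structure selection) is replaced by a fixed
blocked ANOVA with the animal as block: the species effect is tested
against the animal-within-species stratum, location and interaction against
the residual. Tukey-Kramer letters use the error stratum appropriate to
each factor. Outputs are not claimed to reproduce any published p-values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class EmptyGroupError(ValueError):
    pass


def describe(values_by_group: Mapping[str, Sequence[float]], single_sem: str = "nan") -> pd.DataFrame:
    """Arithmetic mean and SEM (sd/sqrt(n)) per group.

    ``single_sem`` controls singleton groups: "nan" flags an undefined SEM,
    "zero" reports 0.
    """
    if single_sem not in ("nan", "zero"):
        raise ValueError("single_sem must be 'nan' or 'zero'")
    rows = []
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise EmptyGroupError(f"group {name!r} is empty")
        if arr.size == 1:
            sem = float("nan") if single_sem == "nan" else 0.0
        else:
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
        rows.append({"group": name, "n": int(arr.size), "mean": float(arr.mean()), "sem": sem})
    return pd.DataFrame(rows)


def compact_letters(
    levels: Sequence[str],
    means: Mapping[str, float],
    significant_pairs: "set[frozenset[str]]",
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Levels not significantly different share at least one letter; letters
    are assigned in descending order of mean (the largest mean gets 'a').
    """
    columns: list[set[str]] = [set(levels)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for reduced in (col - {a}, col - {b}):
                if reduced and not any(reduced <= other for other in columns):
                    columns.append(reduced)
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: -max(means[l] for l in c))
    letters = {l: "" for l in levels}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for l in col:
            letters[l] += ch
    return {l: "".join(sorted(s)) for l, s in letters.items()}


@dataclass(frozen=True)
class ComparisonTable:
    """Result of a factor comparison: means, SEMs, letters and p-values."""

    analyte: Optional[str]
    levels: tuple[str, ...]
    means: Mapping[str, float]
    sems: Mapping[str, float]
    letters: Mapping[str, str]
    p_values: Mapping[str, float]  # factor name -> p
    interaction_retained: Optional[bool] = None
    degenerate: bool = False
    location_means: Optional[Mapping[str, float]] = None
    location_letters: Optional[Mapping[str, str]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": l,
                "mean": self.means[l],
                "sem": self.sems.get(l, float("nan")),
                "letters": self.letters.get(l, ""),
            }
            for l in self.levels
        ]
        return pd.DataFrame(rows)


def _tukey_pairs_from_mse(
    means: Mapping[str, float],
    counts: Mapping[str, int],
    mse: float,
    df_error: float,
    alpha: float,
) -> "set[frozenset[str]]":
    """Tukey-Kramer pairwise decisions from an explicit error stratum."""
    levels = list(means)
    k = len(levels)
    sig: set[frozenset[str]] = set()
    if mse <= 0 or df_error <= 0:
        return sig
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
            q = abs(means[a] - means[b]) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
            if p <= alpha:
                sig.add(frozenset((a, b)))
    return sig


def oneway_tukey(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    analyte: Optional[str] = None,
) -> ComparisonTable:
    """One-way ANOVA across groups with Tukey HSD letters at ``alpha``."""
    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least two observations")
    levels = tuple(groups)
    desc = describe(groups, single_sem="zero").set_index("group")
    means = {l: float(desc.loc[l, "mean"]) for l in levels}
    sems = {l: float(desc.loc[l, "sem"]) for l in levels}

    allvals = np.concatenate(list(groups.values()))
    if np.allclose(allvals, allvals[0]):
        return ComparisonTable(
            analyte=analyte,
            levels=levels,
            means=means,
            sems=sems,
            letters={l: "a" for l in levels},
            p_values={"group": 1.0},
            degenerate=True,
        )
    f_stat, p = sps.f_oneway(*groups.values())
    counts = {l: int(groups[l].size) for l in levels}
    n_total = sum(counts.values())
    df_error = n_total - len(levels)
    ss_error = sum(
        float(((arr - arr.mean()) ** 2).sum()) for arr in groups.values()
    )
    mse = ss_error / df_error
    sig = _tukey_pairs_from_mse(means, counts, mse, df_error, alpha)
    letters = compact_letters(levels, means, sig)
    return ComparisonTable(
        analyte=analyte,
        levels=levels,
        means=means,
        sems=sems,
        letters=letters,
        p_values={"group": float(p)},
    )


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank for a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def two_factor_blocked(
    df: pd.DataFrame,
    value: str = "value",
    species: str = "species",
    location: str = "location",
    animal: str = "animal_id",
    alpha: float = 0.05,
    analyte: Optional[str] = None,
) -> ComparisonTable:
    """Blocked two-factor ANOVA: species + location (+ interaction), animal as block.

    Sequential (type-I) sums of squares via explicit design matrices, robust
    to the species/animal collinearity of a nested design and to missing
    cells (general least squares on available observations). The
    interaction is refitted out when its p-value exceeds ``alpha``; species
    is tested against the animal-within-species mean square.
    """
    data = df[[value, species, location, animal]].dropna().copy()
    if data.empty:
        raise ValueError("no complete observations")
    y = data[value].to_numpy(dtype=float)
    n = y.size

    if np.allclose(y, y[0]):
        levels = tuple(pd.unique(data[species]))
        means = {l: float(y[0]) for l in levels}
        return ComparisonTable(
            analyte=analyte,
            levels=levels,
            means=means,
            sems={l: 0.0 for l in levels},
            letters={l: "a" for l in levels},
            p_values={"species": 1.0, "location": 1.0, "interaction": 1.0},
            interaction_retained=False,
            degenerate=True,
        )

    ones = np.ones((n, 1))
    sp_d = _dummies(data[species])
    an_d = _dummies(data[animal])
    loc_d = _dummies(data[location])
    inter_d = np.einsum("ij,ik->ijk", sp_d, loc_d).reshape(n, -1)

    X0 = ones
    X1 = np.hstack([X0, sp_d])
    X2 = np.hstack([X1, an_d])
    X3 = np.hstack([X2, loc_d])
    X4 = np.hstack([X3, inter_d])

    rss = {}
    rank = {}
    for name, X in (("0", X0), ("sp", X1), ("an", X2), ("loc", X3), ("int", X4)):
        rss[name], rank[name] = _rss(y, X)

    ss_sp, df_sp = rss["0"] - rss["sp"], rank["sp"] - rank["0"]
    ss_an, df_an = rss["sp"] - rss["an"], rank["an"] - rank["sp"]
    ss_loc, df_loc = rss["an"] - rss["loc"], rank["loc"] - rank["an"]
    ss_int, df_int = rss["loc"] - rss["int"], rank["int"] - rank["loc"]
    ss_res_full, df_res_full = rss["int"], n - rank["int"]

    def f_p(ss_num: float, df_num: int, ss_den: float, df_den: int) -> float:
        if df_num <= 0 or df_den <= 0 or ss_den <= 0:
            return float("nan")
        f = (ss_num / df_num) / (ss_den / df_den)
        return float(sps.f.sf(f, df_num, df_den))

    p_int = f_p(ss_int, df_int, ss_res_full, df_res_full)
    interaction_retained = bool(np.isfinite(p_int) and p_int <= alpha)
    if interaction_retained:
        ss_res, df_res = ss_res_full, df_res_full
    else:
        ss_res, df_res = rss["loc"], n - rank["loc"]

    p_sp = f_p(ss_sp, df_sp, ss_an, df_an)
    p_loc = f_p(ss_loc, df_loc, ss_res, df_res)

    sp_levels = tuple(sorted(pd.unique(data[species])))
    sp_means = {l: float(data.loc[data[species] == l, value].mean()) for l in sp_levels}
    sp_counts = {l: int((data[species] == l).sum()) for l in sp_levels}
    sp_sems = {
        l: float(
            data.loc[data[species] == l, value].std(ddof=1)
            / np.sqrt(sp_counts[l])
        )
        for l in sp_levels
    }
    ms_an = ss_an / df_an if df_an > 0 else float("nan")
    sp_sig = (
        _tukey_pairs_from_mse(sp_means, sp_counts, ms_an, df_an, alpha)
        if np.isfinite(ms_an)
        else set()
    )
    sp_letters = compact_letters(sp_levels, sp_means, sp_sig)

    loc_levels = tuple(sorted(pd.unique(data[location])))
    loc_means = {l: float(data.loc[data[location] == l, value].mean()) for l in loc_levels}
    loc_counts = {l: int((data[location] == l).sum()) for l in loc_levels}
    ms_res = ss_res / df_res if df_res > 0 else float("nan")
    loc_sig = (
        _tukey_pairs_from_mse(loc_means, loc_counts, ms_res, df_res, alpha)
        if np.isfinite(ms_res)
        else set()
    )
    loc_letters = compact_letters(loc_levels, loc_means, loc_sig)

    return ComparisonTable(
        analyte=analyte,
        levels=sp_levels,
        means=sp_means,
        sems=sp_sems,
        letters=sp_letters,
        p_values={"species": p_sp, "location": p_loc, "interaction": p_int},
        interaction_retained=interaction_retained,
        location_means=loc_means,
        location_letters=loc_letters,
    )
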