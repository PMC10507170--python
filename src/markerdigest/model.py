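"""Model/Results façade over the marker-ledger digestibility pipeline.

``DigestibilityModel`` is built from a cohort of animal records (or the
animals.csv/meals.csv pair) and a configuration; ``fit()`` runs terminal-
ileum imputation, builds the marker ledgers, computes the per-animal
digestibility table, and returns a ``DigestibilityResults`` object carrying
the estimates, cohort summaries, group comparisons and export helpers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .digestibility import digest_cohort
from .io import RunConfig, read_cohort, write_cohort, write_tsv
from .marker import MarkerLedger, build_cohort_ledgers, ledger_table, marker_distribution
from .records import AnimalRecord, validate_record
from .stats import ComparisonTable, describe, oneway_tukey, two_factor_blocked


class InvalidCohortError(ValueError):
    """The cohort failed validation; the message lists every violation."""


class DigestibilityModel:
    """Regional apparent amino-acid digestibility model for one cohort.

    Parameters
    ----------
    cohort : sequence of AnimalRecord
        Validated per-animal records (meal + compartment samples).
    config : RunConfig, optional
        Group definitions, imputation policy, alpha, report rounding.
    """

    def __init__(
        self,
        cohort: Sequence[AnimalRecord],
        config: Optional[RunConfig] = None,
    ) -> None:
        self.cohort = list(cohort)
        self.config = config or RunConfig()
        violations = {
            r.animal_id: validate_record(r) for r in self.cohort
        }
        bad = {aid: v for aid, v in violations.items() if v}
        if bad:
            msgs = "; ".join(
                f"{aid}: {', '.join(x.message for x in v)}" for aid, v in bad.items()
            )
            raise InvalidCohortError(f"cohort validation failed: {msgs}")

    @classmethod
    def from_csv(cls, animals_path, meals_path, config: Optional[RunConfig] = None):
        return cls(read_cohort(animals_path, meals_path), config=config)

    def fit(self) -> "DigestibilityResults":
        ledgers = build_cohort_ledgers(self.cohort, self.config.imputation_policy)
        table = digest_cohort(
            self.cohort,
            groups=self.config.group_defs(),
            group_policy=self.config.group_policy,
            ledgers=ledgers,
        )
        return DigestibilityResults(model=self, ledgers=ledgers, table=table)


@dataclass
class DigestibilityResults:
    """Fitted per-animal digestibility estimates and cohort summaries."""

    model: DigestibilityModel
    ledgers: Mapping[str, MarkerLedger]
    table: pd.DataFrame

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def ledger_table(self) -> pd.DataFrame:
        return ledger_table(self.ledgers)

    def marker_distribution(self) -> pd.DataFrame:
        """Mean marker share (% of dose) per gut location across the cohort."""
        return marker_distribution(self.ledgers)

    def species_means(self, column: str = "apparent_dig_pct") -> pd.DataFrame:
        """Species x location means +/- SEM of one estimate column."""
        rows = []
        for (analyte, loc), sub in self.table.groupby(["analyte", "location"], sort=False):
            d = describe(
                {sp: g[column].dropna().to_numpy() for sp, g in sub.groupby("species")},
                single_sem="zero",
            )
            d.insert(0, "analyte", analyte)
            d.insert(1, "location", loc)
            rows.append(d)
        return pd.concat(rows, ignore_index=True)

    def compare_gastric_retention(self, analyte: str) -> ComparisonTable:
        """One-way ANOVA + Tukey letters of gastric retention across species."""
        sub = self.table[
            (self.table["analyte"] == analyte) & (self.table["location"] == "psi")
        ]
        groups = {
            sp: g["retention_ratio"].dropna().to_numpy()
            for sp, g in sub.groupby("species")
        }
        return oneway_tukey(groups, alpha=self.config.alpha, analyte=analyte)

    def compare_digestibility(
        self,
        analyte: str,
        column: str = "apparent_dig_pct",
        locations: Sequence[str] = ("psi", "dsi"),
    ) -> ComparisonTable:
        """Blocked two-factor (species x location) comparison of one analyte."""
        sub = self.table[
            (self.table["analyte"] == analyte)
            & (self.table["location"].isin(list(locations)))
        ][["animal_id", "species", "location", column]].rename(columns={column: "value"})
        return two_factor_blocked(
            sub, alpha=self.config.alpha, analyte=analyte
        )

    def comparison_report(
        self, column: str = "apparent_dig_pct", locations: Sequence[str] = ("psi", "dsi")
    ) -> pd.DataFrame:
        """Per-analyte species/location comparison table (report layout)."""
        cfg = self.config
        rows = []
        for analyte in self.table["analyte"].unique():
            ct = self.compare_digestibility(analyte, column=column, locations=locations)
            row: dict = {"analyte": analyte}
            for sp in ct.levels:
                row[sp] = round(ct.means[sp], cfg.pct_decimals)
                row[f"{sp}_letters"] = ct.letters[sp]
                row[f"{sp}_raw"] = ct.means[sp]
            if ct.location_means:
                for loc, m in ct.location_means.items():
                    row[f"loc_{loc}"] = round(m, cfg.pct_decimals)
                    row[f"loc_{loc}_letters"] = (ct.location_letters or {}).get(loc, "")
                    row[f"loc_{loc}_raw"] = m
            row["p_species"] = ct.p_values.get("species")
            row["p_location"] = ct.p_values.get("location")
            row["p_interaction"] = ct.p_values.get("interaction")
            row["interaction_retained"] = ct.interaction_retained
            rows.append(row)
        return pd.DataFrame(rows)

    def retention_report(self) -> pd.DataFrame:
        """Per-analyte gastric-retention comparison (one-way + letters)."""
        cfg = self.config
        rows = []
        for analyte in self.table["analyte"].unique():
            row: dict = {"analyte": analyte}
            try:
                ct = self.compare_gastric_retention(analyte)
                for sp in ct.levels:
                    row[sp] = round(ct.means[sp], cfg.ratio_decimals)
                    row[f"{sp}_letters"] = ct.letters[sp]
                    row[f"{sp}_sem"] = round(ct.sems[sp], cfg.ratio_decimals)
                    row[f"{sp}_raw"] = ct.means[sp]
                row["p"] = ct.p_values.get("group")
            except ValueError:
                # too few species/observations to compare; report means only
                sub = self.table[
                    (self.table["analyte"] == analyte)
                    & (self.table["location"] == "psi")
                ]
                for sp, g in sub.groupby("species"):
                    row[sp] = round(float(g["retention_ratio"].mean()), cfg.ratio_decimals)
                    row[f"{sp}_raw"] = float(g["retention_ratio"].mean())
                row["p"] = float("nan")
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text overview of the fitted cohort."""
        n = len(self.model.cohort)
        species = sorted({r.meal.species for r in self.model.cohort})
        dist = self.marker_distribution()
        lines = [
            "Regional apparent amino-acid digestibility (marker-ratio method)",
            "=" * 64,
            f"Animals: {n} ({', '.join(species)})",
            f"Analytes: {self.table['analyte'].nunique()} "
            f"({self.table.loc[~self.table['is_group'], 'analyte'].nunique()} amino acids + groups)",
            f"Mean marker recovery: "
            f"{np.mean([l.recovery for l in self.ledgers.values()]):.3f}",
            "",
            "Marker distribution (% of dose):",
        ]
        for _, r in dist.iterrows():
            lines.append(
                f"  {r['location']:<8} {r['mean_pct_of_intake']:6.1f} "
                f"+/- {r['sem_pct_of_intake']:.1f}"
            )
        lines.append("")
        lines.append("Mean apparent digestibility (%) by species and SI position:")
        pivot = (
            self.table[~self.table["is_group"]]
            .groupby(["species", "si_position"])["apparent_dig_pct"]
            .mean()
            .unstack("si_position")
        )
        lines.append(pivot.round(1).to_string())
        return "\n".join(lines)

    def to_tsv(self, outdir, seed: Optional[int] = None) -> dict[str, Path]:
        """Write marker_ledger.tsv, digestibility.tsv and comparison reports."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        paths = {}
        for name, df in (
            ("marker_ledger.tsv", self.ledger_table()),
            ("digestibility.tsv", self.table),
            ("table_retention.tsv", self.retention_report()),
            ("table_digestibility.tsv", self.comparison_report()),
        ):
            p = outdir / name
            write_tsv(df, p, config=cfg, seed=seed)
            paths[name] = p
        return paths
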