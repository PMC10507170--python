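# markerdigest

Regional small-intestinal amino-acid digestibility from single-time-point
digesta studies, by the indigestible-marker (TiO₂) mass-balance method —
with a synthetic gut-transit/absorption cohort generator that makes every
estimator verifiable by parameter recovery.

## The problem

In milk-fed piglets (a common model for the human infant), the amount of
each dietary amino acid (AA) absorbed by a given point of the small
intestine cannot be measured directly. Instead, an indigestible particulate
marker (titanium dioxide) is mixed into a single protein-normalised milk
meal; a few hours later the entire gut contents are collected compartment
by compartment — stomach, proximal small intestine (PSI), distal small
intestine (DSI), terminal ileum (TI), large intestine (LI) — and assayed
for dry matter, TiO₂ and AA concentrations. Because the marker is not
absorbed, the AA-to-marker ratio in the digesta of a compartment
extrapolates the unabsorbed AA outflow already past it.

With `D` the dietary intake of an AA, `S` its mass still in the stomach,
`AAᵢ`/`Mᵢ` the AA/marker masses in compartment `i`, and `M_after(loc)` the
marker already past location `loc`, the package computes per animal,
analyte and small-intestinal position x ∈ {0.25, 0.75, 1.0}:

```
released_after(loc) = AA(loc) · M_after(loc) / M(loc)
unabsorbed(loc)     = S + Σ_{i ≤ loc} AAᵢ + released_after(loc)
apparent (%)        = (D − unabsorbed) / D · 100
gastric retention R = S / D
available (%)       = ((D − S) − (unabsorbed − S)) / (D − S) · 100
absorbed (mg/g protein) = (D − unabsorbed) / protein consumed
```

so that exactly `apparent = available · (1 − R)`. Group values (EAA, BCAA,
NEAA, LNAA) are computed on summed member masses. Gastric retention above 1
and negative apparent digestibility are preserved, not clipped (residual
protein from an earlier meal can leave more of an AA in the stomach than
the test meal supplied); available digestibility is then undefined.

The audience is nutrition/digestive-physiology researchers processing
marker-based digesta trials, and methodologists who want the estimator's
behaviour characterised on simulated cohorts with known ground truth.

## Worked example

```python
from markerdigest import DigestibilityModel, default_config, simulate_cohort

cfg = default_config()                      # 3 milk types x 4 piglets
records, truth = simulate_cohort(cfg, seed=1)
results = DigestibilityModel(records).fit()
print(results.summary())
```

prints

```
Regional apparent amino-acid digestibility (marker-ratio method)
================================================================
Animals: 12 (bovine, caprine, ovine)
Analytes: 20 (16 amino acids + groups)
Mean marker recovery: 0.992

Marker distribution (% of dose):
  stomach    54.0 +/- 1.6
  psi         8.5 +/- 0.7
  dsi        22.8 +/- 1.1
  ti          1.9 +/- 0.2
  li         12.1 +/- 0.6

Mean apparent digestibility (%) by species and SI position:
si_position  0.25  0.75  1.00
species
bovine       15.6  24.6  25.2
caprine      17.0  27.8  28.3
ovine        27.9  45.2  46.4
```

Reading the output: ~99% of the TiO₂ dose was recovered; about half of it
was still in the stomach at sampling, with the rest split over PSI / DSI /
TI / LI roughly 9/23/2/12% of the dose. Apparent digestibility rises along
the small intestine (cumulative positions 25% → 75% → 100%) and is lowest
for bovine milk, whose firmer gastric curd retains the most AA in the
stomach — correcting for gastric retention (`available_dig_pct` in
`results.table`) largely removes the species differences.

Further entry points:

```python
results.table                         # long per-animal estimates
results.marker_distribution()         # marker ledger summary
results.compare_gastric_retention("LEU")      # one-way ANOVA + Tukey letters
results.compare_digestibility("LEU")          # blocked species x location ANOVA
results.to_tsv("outdir/")             # marker_ledger.tsv, digestibility.tsv, reports
```

Real data enter through two CSVs (`DigestibilityModel.from_csv`):

- `animals.csv` — one row per animal × location: `animal_id, species,
  body_weight_kg, location, digesta_dm_g, tio2_pct_dm, aa_<KEY>_pct_dm…`
  (blank cell = not assayed; AA headers accept synonyms, e.g. `aa_Asp_…`
  maps to the ASX pool).
- `meals.csv` — one row per species: `species, fresh_milk_g_per_kg_bw,
  protein_g_per_kg_bw, dm_g_per_kg_bw, tio2_mg_per_g_dm,
  aa_<KEY>_mg_per_g_protein…`.

Terminal-ileum marker concentrations are often unmeasurable (too little
digesta); the ledger imputes the missing TI marker **mass** from donor
animals (`species_mean`, `overall_mean` or `fail` policy) and flags imputed
rows.

The same pipeline is scriptable from a shell:

```sh
markerdigest simulate --seed 17 --out run/
markerdigest digest --animals run/animals.csv --meals run/meals.csv --out run/
markerdigest all --seed 17 --out run/      # simulate -> digest -> compare
```

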