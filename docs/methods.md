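# Methods

## The marker-ratio accounting model

The package treats a single-time-point digesta study as a mass-balance
problem. A meal carries a dietary amino-acid (AA) mass `D` (composition in
mg/g protein × protein consumed) and a TiO₂ marker mass `M` (dose in mg/g
DM × meal DM). At sampling, each gut compartment contributes a freeze-dried
digesta mass and %DM concentrations, so compartment masses are products:
`mass = DM(g) × conc(%DM)/100 × 1000` mg. All internal arithmetic is in
mg; unit conversions happen only at the I/O boundary.

The marker ledger splits recovered marker at each small-intestinal (SI)
location into `until(loc)` (stomach + compartments up to and including
`loc`) and `after(loc)` (everything downstream, with the large intestine as
a single pooled pool). By construction `until + after` equals total
recovered marker at every location (conservation), `until` is
non-decreasing and `after` non-increasing along the tract. Whole-tract
recovery (recovered/dosed) is reported but never used to rescale masses.

Unabsorbed AA at a location is the cumulative digesta AA up to that
location plus the marker-extrapolated outflow
`AA(loc) × after(loc)/marker(loc)`. The three SI sampling sites are read as
cumulative fractional positions of SI length: the proximal and distal
halves represent their midpoints (25% and 75%) and the terminal ileum 100%.
The published calculation spells out only the first-quarter case; the
extension to 75% and 100% used here is the cumulative generalisation (add
the intervening compartment contents, extrapolate with that location's own
marker ratio), which is the only reading consistent with the positions
being cumulative fractions.

Three derived quantities per animal × analyte × position:

- apparent digestibility `(D − unabsorbed)/D × 100`;
- available digestibility, the same computation on the material that
  actually left the stomach (`D − S` as intake, stomach mass excluded from
  unabsorbed). Algebraically `apparent = available × (1 − R)` with
  `R = S/D` the gastric retention ratio; the pipeline emits both and the
  identity is tested at machine precision;
- apparent amount absorbed, `(D − unabsorbed)` per g protein consumed.

Group analytes (BCAA ⊂ EAA; LNAA; NEAA) are computed on **summed member
masses** at every step, never by averaging member digestibilities — the
two differ whenever member intakes differ. NEAA membership varies between
laboratories; the default excludes proline (configurable), and because
published NEAA totals are not always the sum of their listed components,
NEAA totals are not used as oracles anywhere in the test suite.

### Degenerate and anomalous inputs

- `R > 1` is biologically meaningful here (residual protein from a
  pre-study meal) and is preserved; apparent digestibility then goes
  negative and available digestibility is reported missing (NaN, flagged),
  since nothing from the test meal is available.
- Zero marker mass at a location makes the extrapolation undefined; the
  row is emitted as missing with a flag rather than as 0.
- Terminal-ileum marker concentrations are frequently unmeasurable. The
  imputation donates marker **mass** (not concentration) from donor
  animals — the scant TI digesta makes its DM itself unreliable, and all
  downstream formulas consume mass. Policies: same-species donors with
  fallback to the overall mean, overall mean, or fail. Measured animals are
  never altered and imputed rows carry a provenance flag.
- All divisions run at full floating precision; rounding (1 decimal for
  percentages, 2 for retention ratios) happens only in rendered report
  tables, which carry paired `*_raw` columns.

## Synthetic cohorts and what they do (and do not) emulate

`simulate_cohort` generates the test bed: per species, a gastric AA
retention `R` (per-AA map or scalar), a gastric marker fraction `g`, an
SI+LI marker split, and a positional absorption curve `a(x)` (piecewise
constant, or saturating `a_max·(1−e^{−kx})`). AA and marker retention are
deliberately decoupled (`R ≠ g`): curd formation traps protein, not the
particulate marker. Compartment masses follow by mass balance — stomach AA
`R·D`; post-gastric compartment `i` receives the emptied pool `D(1−R)` in
proportion to its marker share and keeps `(1−a(x_i))` of it. DM masses are
back-derived so the marker concentration equals the meal dose before
noise; multiplicative log-normal noise (default sd 0.05) is applied to
concentrations only, because concentrations are what the assay measures;
DM is treated as exact.

Closed-form exactness (proved by substitution and tested to 1e-9): under a
piecewise-constant curve and zero noise, unabsorbed = `R·D + D(1−R)(1−a)`
independent of the marker split, so the estimator returns exactly
`a·(1−R)` apparent and `a` available at every position. Under a saturating
curve the cumulative estimator at 75%/100% mixes segments with different
absorbed fractions and acquires a deterministic bias; the recovery report
(`recover_parameters`) quantifies it.

Default study conditions (3 species × 4 animals): body weight 5.17 ± 0.55
kg; protein dose 2 g/kg BW; TiO₂ 5.45 mg/g DM; meal DM per kg BW and milk
AA composition from the bundled per-species reference tables; per-AA `R`
from the bundled gastric-retention table (bovine ≈ 0.7, caprine ≈ 0.5,
ovine ≈ 0.4 on average; bovine lysine 1.11 reproduces the over-unity
anomaly); marker split 52/9/24/2/13% over stomach/PSI/DSI/TI/LI; recovery
loss 0.02 (98% recovery). The absorption curve defaults to
`a_max = 0.9, k = 2.9`, a design-time calibration placing available
digestibility near 0.47 at the 25% point and 0.81 at 75% so that the first
quarter carries roughly 58% of available uptake. No per-animal variance
components are published for such cohorts, so the biological CVs (0.2 on
the retention multiplier, 0.2 on marker-split fractions, renormalised) are
assumptions; tryptophan and cysteine retention, absent from the bundled
digesta table, default to the group totals.

What passing the simulation suite shows: the estimators invert the
generative mass balance exactly in the identifiable regime, degrade
gracefully under noise (species-mean retention within ±0.05 of realized
truth in ≥95% of seeded replicates at n = 4, noise sd 0.05), and
shrink in error with cohort size. What it does not show: robustness to
features real digesta have and the generator omits — correlated assay
errors within a sample, DM measurement error, incomplete digesta
collection, time-varying absorption, or endogenous AA secretion (the model
is apparent digestibility only; no endogenous-loss correction is applied,
and "true" digestibility is out of scope).

## Simplified statistics layer

The original inferential machinery for such studies is a REML mixed model
with covariance-structure selection; this package deliberately replaces it
with a fixed blocked ANOVA and labels every output a simplified
reanalysis — no published p-value is claimed to be reproduced.

- One-way comparisons (milk composition, gastric retention): ANOVA F-test
  with Tukey HSD pairwise decisions at α = 0.05 and a compact letter
  display (insert-and-absorb algorithm; levels share a letter iff not
  significantly different). Type-I error of the F-test is verified at the
  nominal rate by a seeded null simulation.
- Species × location comparisons: sequential (type-I) sums of squares with
  explicit design matrices — intercept, species, animal-within-species,
  location, interaction — fitted by least squares, which is robust to the
  species/animal collinearity of the nested design and degrades to a
  general linear model on available cells when unbalanced. Species is
  tested against the animal-within-species mean square; location and
  interaction against the residual. Following the field's convention, the
  interaction is removed and the model refitted when its p-value exceeds
  0.05. Tukey–Kramer letters use the error stratum matching each factor
  (studentized-range distribution from scipy).
- Degenerate inputs (all values identical) short-circuit to p = 1 with a
  single shared letter and a flag.

## Problem sizes

Test-suite and acceptance-script simulation sizes were chosen to give
stable Monte-Carlo estimates at interactive runtimes: 200 replicates of the
default 12-animal cohort for retention-recovery coverage, 20 replicates
each at n = 4 and n = 40 per species for the RMSE-vs-n comparison, 1,000
random records for ledger invariants, and 2,000 replicates of a 3 × 4 null
for the ANOVA type-I error (binomial sd ≈ 0.005 at rate 0.05).

## Known limitations

- The marker-ratio extrapolation assumes digesta are well mixed within a
  compartment and the marker co-migrates with the solid phase; liquid-phase
  transit is not modelled.
- The cumulative estimator is exactly unbiased only under
  position-constant absorption; with saturating absorption its 75%/100%
  values are conservative (biased toward the upstream segment).
- The simulator draws one retention multiplier per animal (perfectly
  correlated across AAs); real animal-by-AA interactions would inflate
  group-level variance relative to the simulation.
- Group totals published to one decimal cannot always be reproduced exactly
  from their printed components (rounding accumulates to ~0.1–0.15 mg/g
  protein over 6–9 members); aggregation tests use that tolerance.
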