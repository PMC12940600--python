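# Methods

This note documents the models implemented in `aqpd`, the assumptions they
make, the defaults and why they were chosen, what the synthetic scenario
generator does and does not emulate, and the numerical conventions adopted
where the design was genuinely open.

## 1. Study design being modelled

The analysis treats the 2020 calendar year of an urban monitoring station
as a natural experiment: six non-overlapping, decree-defined phases
(Pre-Pandemic, 1 Jan–15 Mar; Strict Lockdown, 16 Mar–3 May; Phase 1,
4 May–4 Jun; Phase 2, 5–30 Jun; Phase 3, 1 Jul–26 Sep; Phase 4,
27 Sep–31 Dec) partition the year, with Pre-Pandemic as the reference
category in every contrast. All timestamps are naive local time (Peru,
UTC−5, no daylight saving); days are local calendar dates — monitoring
networks aggregate by local day. Phase intervals are inclusive on both
ends; the printed dates already partition the year, so boundary ownership
never arises.

## 2. Quality control and aggregation

Hourly values are aggregated to daily means only when at least
`min_valid_hours` (default 18, i.e. ≥75% completeness, the
guideline-recommended threshold) of the 24 hours are valid; days below the
threshold are excluded *for that variable only*, and no imputation is ever
performed. Valid-hour counts are carried alongside every daily mean.
Unparseable cells and negative concentrations are treated as missing at
read time, with per-column counts logged.

The daily O3 guideline metric is the maximum rolling 8-hour mean. The
convention here: windows *end* within the local day (so early-morning
windows may straddle midnight) and a window is valid when ≥6 of its 8
hours are present; a day with no valid window is missing. Regression and
forest models use daily means for all pollutants including O3 — the 8-hour
metric feeds only guideline-exceedance counting, which uses a strict `>`
(guidelines are upper bounds, and the boundary case is otherwise
undefined).

Continuous predictors are mean-centred and scaled to unit *sample*
standard deviation (ddof = 1, matching R's default) using constants from
the full analysis window, not per phase — coefficients must be comparable
across phases. Wind direction is carried through the containers but enters
no model.

## 3. Variance decomposition

Per pollutant, the meteorology-only model (temperature, wind speed,
relative humidity) and the full model (plus five phase indicators,
reference omitted) are fitted by OLS **on the identical complete-case row
set**, intersected across both models before fitting: the incremental-R²
subtraction is meaningless on differing samples. The partition is

    R²_meteo = R²(M1),  R²_covid = R²(M2) − R²(M1) ≥ 0,
    %meteo = R²_meteo / R²(M2) × 100,  %covid = 100 − %meteo,

with the degenerate R²(M2) = 0 case flagged rather than divided. The
increment is tested with the classical RSS-based nested ANOVA F on
(5, df₂) degrees of freedom — the form in which such tables report it —
while coefficient-level inference offers HC3 sandwich standard errors
(HC0–HC2 selectable). HC3 is the small-sample standard within the White
estimator family; it refuses rows with leverage 1, where its weighting is
undefined. Variance inflation factors are reported per predictor with a
warning above 5. Seasonal meteorology is genuinely collinear with the
phase calendar (phases are blocks of the seasonal cycle), so VIF warnings
on phase indicators are expected and informative, not errors: the
coefficient standard errors already price that collinearity in.

Sensitivity axes re-run the whole analysis: completeness thresholds 12/18/
20; austral summer (Dec–Feb) and winter (Jun–Aug) strata by calendar
month regardless of phase boundaries; exclusion of daily values beyond 3
standard deviations of the full-period per-pollutant mean, applied before
modelling; and an extended meteorology set adding pressure and solar
radiation. Seasonal strata that do not contain the configured reference
phase fall back to the earliest phase present; strata in which a pollutant
retains only one phase skip that pollutant with a recorded reason.
Sensitivity variants are pure functions of their configuration and never
mutate the base run; they re-run the regression and HIA stages (the forest
cross-check is a per-run option left off in the variants, since the axes
interrogate the regression attribution).

## 4. Ensemble-tree cross-check

Bagged regression trees give a non-parametric check on the regression
attribution: 500 trees, mtry = max(1, ⌊p/3⌋), minimum terminal node size
5, fixed seed. The bagging loop is explicit (bootstrap indices drawn per
tree around scikit-learn `DecisionTreeRegressor`s) because the per-tree
out-of-bag rows are needed for the permutation importance; canned forests
do not expose them cleanly.

The phase factor enters as a single ordinal code in chronological order.
Since the phases are temporally ordered, threshold splits select
contiguous phase blocks; this keeps p = 4 — so the default mtry is 1, as
intended for this predictor set — and makes "permute the phase column" a
single natural operation. The alternative (one-hot with importances summed
over indicators) changes p and fragments the factor's importance.

Importance measures: (1) permutation importance — per tree, the increase
in OOB MSE when the predictor's values are shuffled among that tree's OOB
rows, averaged over trees and divided by the standard deviation of the
per-tree increases (the scaled convention of the classic forest
implementation); the raw mean increase is reported alongside; (2) total
impurity decrease summed over all splits on the predictor. OOB MSE/R² come
from averaging each observation's predictions over the trees that held it
out. Exact per-tree randomness differs across software ecosystems; the
reproducibility contract is internal (same seed ⇒ identical importances),
not cross-ecosystem bit equality.

The concordance report compares dominance direction: the forest's
meteorology share (clipped raw permutation importances of the
meteorological predictors over the combined total) against the
regression's %meteo, with an *indeterminate* verdict when total importance
vanishes or the forest has no OOB skill (OOB R² ≤ 0) — a skill-less model
cannot adjudicate dominance.

## 5. Health impact assessment

The log-linear, no-threshold concentration–response chain RR =
exp(β·ΔPM2.5), AF = (RR−1)/RR, Deaths = Population × (Rate/100 000) × AF
is evaluated per phase with Δ taken between phase means, relative to the
reference phase. Defaults: β = 0.00072 per µg/m³ (95% CI 0.00059–0.00085,
GBD 2021 cardiovascular), population 67 167, baseline rate 120 per
100 000 per year. Deaths are annualized — no scaling by phase duration —
matching the convention of reporting *annual* attributable deaths at each
phase's concentration level; per-period scaling is deliberately not the
default. The total population is exposed (the GBD comparative-risk
convention), not an adult subset.

Uncertainty: the RR interval evaluates the β CI bounds; the deaths
interval is a 2.5th–97.5th percentile from seeded Monte Carlo (default
10 000 draws) with β ~ Normal(β, CI-width/3.92) and the baseline rate ~
Normal(rate, cv·rate) truncated at zero, cv = 0.10 by default. The named
distributions are a choice — only "probability distributions" are implied
by the design — and the Normal-from-symmetric-CI is the least-structured
reading. As widths → 0 the interval collapses to the analytic point
(tested). A β registry (GBD2021 = 0.00072, GBD2019 = 0.00076,
WHO2021 = 0.00076, Pope = 0.00080) drives the sensitivity table; for small
βΔ, deaths scale almost linearly in β (AF ≈ βΔ to first order).

Known divergence: carrying the published per-phase PM2.5 means through
this chain with the stated parameters yields Phase 1 attributable deaths
≈ 0.25/yr, not the 0.23 printed in the source table, and the
directly-evaluated RRs for the two negative-Δ phases round to 0.999/1.000
rather than the printed 0.998/0.999. The package reports the
formula-exact values; the printed deaths column is not reproducible from
the stated formulas and parameters.

A second known non-reproduction: the published decomposition table's
percentage shares do not all follow from its *rounded* R² columns (e.g.
0.119/0.227 = 52.4%, printed 52.3%) because shares were evidently computed
on unrounded R²s; only the O3 row (0.800/0.812 → 98.5%) reproduces exactly
from printed values and is used as an exact check.

## 6. The synthetic scenario generator

The generator's role is to produce hourly data with the statistical
structure the analysis assumes, so every downstream stage is testable
without the (undeposited) original record. Its defaults define the study
conditions:

- **Phase means.** Per-pollutant per-phase daily mean targets equal the
  published phase means (e.g. PM2.5: 12.60, 14.51, 16.91, 15.04, 10.91,
  11.96 µg/m³ across the six phases).
- **Meteorology.** Sinusoidal seasonal cycles with austral phase:
  temperature mean 21 °C, amplitude 4 °C, maximum mid-January (medians
  ~25 °C summer → ~17 °C winter), afternoon-peaking diurnal cycle of
  3 °C; relative humidity mean 70%, amplitude 5% peaking in winter; solar
  radiation mean 250 W/m², amplitude 120 W/m², shaped by a normalized
  daylight profile; pressure mean 1010 hPa, amplitude 2 hPa. Only medians
  and ranges are reported for the real site; smooth cycles suffice for the
  statistical structure the models exploit.
- **Wind–PM coupling.** Day-level wind ~ Normal(3, 1) m/s (floored at
  0.1); PM10 and PM2.5 respond at −2 µg/m³ per m/s of the day's wind
  anomaly, giving the negative dispersion association without biasing
  phase means.
- **SO2 point-source spikes.** Poisson arrivals (0.1 events/day at
  baseline) of 3-hour plumes with exponential magnitude (mean 40 µg/m³),
  both scaled down phase-by-phase in proportion to the configured phase
  means, emulating declining smelter episodes. The expected spike
  contribution is subtracted from the base level so configured phase means
  stay exact in expectation.
- **NO2 weekday uplift.** A multiplicative weekday factor (default +15%)
  centred at the long-run weekday fraction 5/7, preserving phase means.
- **Noise.** A day-level Gaussian component (sd = `noise_sd`, defaults
  chosen to match the published daily SD scale: 14, 4, 0.7, 4, 5 µg/m³
  for PM10/PM2.5/NO2/O3/SO2) shared by the day's 24 hours, plus hourly
  jitter at half that sd, truncated at zero. The day-level component
  carries the day-to-day variability daily statistics see; a purely
  hourly noise large enough to produce realistic daily SDs would be
  heavily truncated at zero and bias means upward. Optional AR(1) on the
  day-level noise (`ar1_rho`, default 0 — no autocorrelation structure is
  documented for the source record).
- **Missingness.** Block outages per variable; the defaults blank SO2
  from 6 Oct and O3 from 16 Oct to year-end, reproducing the documented
  instrument-maintenance gaps (SO2: 9 valid days in Phase 4; O3: 19).

With noise, spikes, coupling and uplift disabled, every daily mean equals
its configured phase mean to machine precision — the exactness baseline
used by tests and by the acceptance script. Identical seeds produce
byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: heavy-tailed extremes (Gaussian noise
truncates the upper tail; the real record's maxima, e.g. a 182 µg/m³
PM10 day, are not reproduced), wind-direction chemistry, marine-aerosol
composition and boundary-layer physics, serially correlated synoptic
episodes (unless AR(1) is enabled), and any pollutant–meteorology coupling
beyond the wind–PM slope (notably, synthetic O3 is linked to season only
through the phase calendar, not to temperature within phases). The
generator targets statistical, not physical, realism.

## 7. Numerical conventions and degenerate inputs

- Sample (n−1) standard deviations everywhere.
- Percent-change CIs: the 95% interval is built on the difference scale,
  diff ± 1.96·√(SE_i² + SE_ref²) with standard errors of the mean, then
  divided by the reference mean. The alternative reading (attaching the
  ±1.96·SE term after the ×100 on the percent scale directly) is
  dimensionally incoherent; users comparing against the source table
  should note the ambiguity.
- Dunn's pairwise z uses the tie-corrected pooled-rank variance
  N(N+1)/12 − Σ(t³−t)/(12(N−1)); Benjamini–Hochberg adjustment spans all
  15 phase pairs per pollutant (the family size is otherwise unstated).
  An all-identical sample short-circuits to H = 0, p = 1.
- Spearman matrices use pairwise-complete deletion with a minimum of 3
  complete pairs per cell; cells below that are missing.
- Weekday–weekend contrasts use Welch (unequal-variance) intervals; a
  zero-variance stratum yields a degenerate zero-width interval, and
  strata with fewer than two valid days are flagged, not computed.
- Empty phases yield n = 0 summary records with missing statistics;
  single-day phases have undefined (missing) sd.
- Rank-deficient design matrices are rejected naming the collinear
  columns; fits require at least 3 more rows than coefficients.
- The pipeline manifest hashes the analysis-relevant configuration
  (SHA-256 over canonical JSON, excluding output paths), so two runs with
  the same hash and seed produce byte-identical tables.

## 8. Problem sizes used by the test suite

The suite exercises full synthetic years (8 784 hourly rows → 366 daily
rows) for end-to-end checks; calibration properties use 1 000 replicates
of a 60-row null for the nested-F type-I error, 50 replicate years for
phase-effect recovery, and 40–200 replicates for decomposition and forest
properties — sizes at which the Monte Carlo error of each asserted
quantity is small relative to its tolerance.
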