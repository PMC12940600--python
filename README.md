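# aqpd — air-quality phase decomposition

`aqpd` separates **meteorological** from **intervention-phase** drivers of
air-pollutant variability and converts the resulting PM2.5 changes into a
cardiovascular **health impact assessment**. It re-implements, as a tested,
reusable Python pipeline, the analysis design used for the 2020 monitoring
record of Ilo, a coastal industrial city in southern Peru, where the year
was divided into six decree-defined phases (Pre-Pandemic baseline, Strict
Lockdown, and reopening Phases 1–4). Because that monitoring record is not
publicly deposited, the package ships a first-class **synthetic scenario
generator** that emulates its statistical structure, so every stage runs,
and is tested, without any external data.

It is written for air-quality scientists and environmental epidemiologists
who want intervention-assessment machinery — QC'd aggregation, variance
decomposition, ensemble-tree cross-checks, concentration–response health
impacts — as an importable library with a thin CLI.

## The statistics at the core

**Nested-regression variance decomposition.** For each pollutant's daily
mean *Y*, two OLS models are fitted on the identical complete-case rows:

- M1 (meteorology only): `Y = β₀ + β₁·Temp + β₂·WindSpeed + β₃·Humidity + ε`
- M2 (full): M1 plus five phase indicators (Pre-Pandemic as reference)

with meteorological predictors standardized over the full window. The full
model's R² is partitioned as `R²_meteo = R²(M1)` and
`R²_covid = R²(M2) − R²(M1) ≥ 0`, with percentage shares
`%meteo = R²_meteo/R²(M2)·100` and `%covid = 100 − %meteo`. The phase
increment is tested with the nested ANOVA F statistic
`F = ((RSS₁ − RSS₂)/5) / (RSS₂/df₂)`; coefficient inference can use HC3
sandwich standard errors.

**Ensemble-tree cross-check.** Bagged regression trees (500 trees,
mtry = ⌊p/3⌋, minimum node size 5, seeded) on the same predictors provide
out-of-bag error, permutation importance (%IncMSE) and impurity-decrease
importance (IncNodePurity), and a concordance verdict against the
regression split.

**Health impact assessment.** The log-linear, no-threshold
concentration–response function

```
RR = exp(β · ΔPM2.5)        AF = (RR − 1)/RR
Deaths = Population × (BaselineRate/100 000) × AF
```

uses by default the GBD 2021 cardiovascular coefficient β = 0.00072 per
µg/m³ (95% CI 0.00059–0.00085), a population of 67 167 and a baseline
cardiovascular mortality rate of 120 per 100 000 per year. Uncertainty is
propagated by Monte Carlo (10 000 draws over β and the baseline rate) and
by a registry of alternative β values (GBD 2019, WHO 2021, Pope).

## Worked example

```python
from aqpd import (aggregate_daily, decompose_variance, default_ilo_config,
                  fit_nested_models, generate_scenario, hia_table)

cfg = default_ilo_config(seed=123)            # six phases, published means
daily = aggregate_daily(generate_scenario(cfg), 18, cfg.calendar)
m1, m2 = fit_nested_models(daily, "pm25", calendar=cfg.calendar)
print(decompose_variance(m1, m2))
print(hia_table(daily, "Pre-Pandemic")[["phase", "delta_pm25", "rr", "deaths"]])
```

Running `python examples/02_variance_decomposition.py` prints (seed 123):

```
pollutant    n  R2full  R2met   %met  %covid      F       p
     pm10  366   0.227  0.054   23.9    76.1  15.95  0.0000
     pm25  366   0.330  0.195   59.2    40.8  14.32  0.0000
      no2  366   0.227  0.119   52.2    47.8  10.05  0.0000
       o3  289   0.721  0.531   73.7    26.3  38.00  0.0000
      so2  279   0.644  0.491   76.2    23.8  23.20  0.0000
```

For PM2.5, 59.2% of the explained variance is attributable to weather and
40.8% to the intervention phases, and the phases add significant power
beyond meteorology (F(5, 357), p < 0.001). `examples/04_health_impact.py`
then shows the peak phase (Phase 1) carrying RR ≈ 1.004 and ≈ 0.30
additional attributable cardiovascular deaths per year for this synthetic
draw, with a 95% Monte Carlo interval of (0.22, 0.38). The other examples
cover the generator, the forest cross-check, and the full pipeline with
its four-axis sensitivity suite.

## Layout

- `src/aqpd/` — the library: `scenario`/`simulate` (synthetic generator),
  `io`/`qc` (CSV dialects, completeness-gated aggregation), `descriptive`,
  `decomposition`, `forest`, `health`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests

A thin CLI mirrors the library:
`aqpd simulate|aggregate|hia|run|sensitivity` (see `aqpd --help`).
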