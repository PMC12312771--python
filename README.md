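# ipdmasem

Estimators and simulation tools for **individual participant data
meta-analytic structural equation modeling** (IPD MASEM): synthesizing raw
per-subject observations from many primary studies by fitting a path model
to the pooled, clustered data.

When participants are nested in studies, the covariance of the pooled data
decomposes into a within-study and a between-study part,
Σ_T = Σ_W + Σ_B, each implied by its own path structure
Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ. Meta-analysts usually care about the
*within-study* coefficients. The estimators compared here differ exactly in
whether they separate the levels:

| method | level separation | what it reports |
|---|---|---|
| NP — naive pooling | none | single-level paths, SEs ignore clustering |
| CR — cluster-robust | none (design-based) | same paths, sandwich SEs, scaled χ² |
| PS — partially saturated two-level | within modeled, between free | within-study paths, df = 2 |
| 2L — two-level path model | both modeled | within- and between-study paths, df = 4 |
| MVMA — multivariate meta-analysis | two-stage | GLS-pooled per-study paths |
| OSMASEM — one-stage MASEM | correlation-based | paths from pooled correlations, df = 2 |

The package ships the four two-level population scenarios of a published
comparison of these methods (a five-variable Theory of Planned Behavior
model: ATT, SN, PBC → INT → BEH), a seeded two-stage multivariate-normal
generator with variable-level missingness, every estimator above, and a
replication-study runner that evaluates convergence, estimates, RMSE,
relative SE bias, and exact/close fit rejection across the
4 scenarios × k ∈ {10, 30, 50} × missingness grid.

## Worked example

Fit the single-level estimators to one simulated collection of 50 studies
under the high-ICC, structurally unequal scenario
(`examples/03_single_level_vs_cluster_robust.py`):

```python
from ipdmasem import ConditionSpec, cluster_robust_fit, naive_pooling_fit
from ipdmasem.generate import center_within, generate_replication

cond = ConditionSpec("S3_high_unequal", k=50, master_seed=1)
ds = generate_replication(cond, 0)
naive = naive_pooling_fit(ds)
robust = cluster_robust_fit(ds)
```

prints

```
within-study population values: INT~ATT = 0.43, BEH~INT = 0.07
                 INT~ATT       se   BEH~INT     chi2
naive              0.437   0.0049     0.398   344.24
cluster-rob.       0.437   0.0531     0.398     2.68
centered           0.434   0.0041     0.073     6.45
```

The naive and cluster-robust point estimates are identical, and BEH~INT
(0.398) sits far from the within-study value 0.07, pulled toward the
between-study value 0.91: single-level estimates blend the levels. The
sandwich repairs the SE (0.0049 → 0.0531) and the scaling repairs the χ²
(344 → 2.7 on df = 2), but not the estimates themselves. Study-mean
centering recovers the within-study coefficient (0.073). The two-level,
MVMA and OSMASEM estimators (`examples/04`–`05`) recover 0.07/0.53 directly.

A miniature replication study (`examples/06_mini_simulation_study.py`, 25
replications of the same condition) reproduces the headline pattern —
naive-pooling SEs biased by ≈ −92% and exact fit rejected in ≈ 96% of
replications, while the model-based estimators stay near the nominal 5%:

```
 method  convergence_rate  mean[INT~ATT]  se_bias_pct[INT~ATT]  exact_fit_rejection
     NP             100.0           0.36                -92.25                 96.0
     CR             100.0           0.36                -22.82                 12.0
     PS             100.0           0.43                 -0.03                  0.0
     2L             100.0           0.43                 -0.03                 12.0
   MVMA             100.0           0.43                  0.47                  NaN
OSMASEM             100.0           0.43                 10.46                  0.0
```

Each `examples/` script is a short narrative: build or load a small input,
run one capability, print what the numbers mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the study's headline quantities from scratch: the implied
covariance entries of the scenario tables, the equal-structure ICC, mean
within-level path estimates of the two-level approaches over 200 seeded
replications, the naive-pooling SE bias and exact-fit rejection rate over
300 replications of the high-ICC condition, and the maximum close-fit
rejection of the model-based methods over a reduced 16-cell condition grid.
It runs in roughly 15 minutes on one CPU and writes one JSON object keyed
by target id.

## Layout

```
src/ipdmasem/
  scenarios.py     population (B, Ψ) tables, implied Σ, ICC profiles
  generate.py      two-stage IPD simulation, missingness, centering, CSV I/O
  single_level.py  ML path fitting, sandwich SEs, scaled χ², RMSEA close fit
  twolevel.py      exact FIML for unbalanced two-level path models
  meta.py          fixed-effects MVMA and one-stage MASEM
  runner.py        condition grid, evaluation criteria, tables and figures
examples/          one narrative script per capability
docs/methods.md    modeling assumptions, numerical choices, limitations
```
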