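# Methods

`ipdmasem` is a simulation and estimation toolkit for individual
participant data meta-analytic structural equation modeling (IPD MASEM):
fitting a path model to raw per-subject observations pooled across primary
studies. Its purpose is methodological — to make the behavior of the common
synthesis estimators (naive pooling, cluster-robust single-level SEM,
two-level SEM, multivariate meta-analysis, one-stage MASEM) measurable
under a controlled two-level data-generating process.

## The population model

Five observed variables — attitudes (ATT), subjective norms (SN), perceived
behavioral control (PBC), intentions (INT), behavior (BEH) — follow the
Theory of Planned Behavior path model: INT ← ATT, SN, PBC and
BEH ← PBC, INT. A path model with coefficient matrix **B** (row = outcome)
and residual covariance **Ψ** implies the covariance

    Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ.

Data are two-level: study means μ_j ~ N(0, Σ_B), participant observations
y_ij ~ N(μ_j, Σ_W), each level with its own (B, Ψ). The intraclass
correlation of a variable is its between-level share of total variance,
Σ_B[v,v] / (Σ_W[v,v] + Σ_B[v,v]).

Four shipped population scenarios cross structural (in)equality of the
levels with ICC size: low (~0.05), medium (empirically derived, 0.18–0.40),
and high (0.50) ICC with unequal level structures, and a high-ICC scenario
with identical levels (ICC exactly .50 by construction). Matrices live in
`data/scenarios.csv`; the implied Σ of each level is recomputed at load and
cross-checked against the published covariance block. One table cell is a
known rounding casualty (the high-ICC unequal scenario's between-level
SN–INT covariance propagates to 0.7811 vs a tabled 0.77 — the inputs are
printed to two decimals), so the load-time check allows 0.0125 there; all
other cells agree within 0.005. B and Ψ are canonical throughout; the
tabled Σ blocks are never used as inputs. The low-ICC scenario's computed
ICC profile is ≈0.048, slightly below the nominal .0525 sometimes quoted
for it; the computed profile is authoritative here.

## Data generation

* Study sizes: integers drawn uniformly (with replacement) from
  [90, 1238] — the min/max of the health-behavior IPD collection the
  scenarios are modeled on. Only the bounds are published; uniform is the
  minimal-assumption law.
* Grand means are fixed at 0. Every estimator carries a free mean
  structure, so means are pure nuisance.
* Variable-level missingness: BEH is removed entirely from exactly ⌊k/2⌋
  studies selected uniformly at random (not i.i.d. coin flips), matching a
  "50% of studies" design exactly. Rows of the remaining four variables
  stay complete — missingness is variable-level, not participant-level.
* Seed hierarchy: a master seed plus a (scenario, k, missingness,
  replication) spawn key produce independent child streams, so conditions
  and replications can run in any order, or in parallel, bit-identically.

## Estimators

**Naive pooling (NP)** fits the path model by normal-theory ML to the
pooled sample covariance (divisor N−1), pretending rows are independent.
χ² = (N−1)·F_ML; SEs come from the expected (Fisher) information of the ML
discrepancy. For this recursive model with uncorrelated residuals the ML
solution coincides with ordered least-squares regressions; the quasi-Newton
refinement from those closed-form start values is retained for generality.

**Cluster-robust (CR)** keeps the NP point estimates (they are identical by
construction) and repairs inference: SEs by the cluster sandwich
A⁻¹(Σ_j g_j g_jᵀ)A⁻ᵀ with per-study score contributions g_j, and the exact
fit statistic by mean (Satorra–Bentler-type) scaling T/c with
c = tr(UΓ)/df, where Γ aggregates moment fluctuations at the cluster level.
No small-sample (k/(k−1)-style) correction is applied; the residual
negative SE bias at small k is part of what the simulations measure.
`CR-centered` applies CR after subtracting each study's own means, which
moves the point estimates to the within-study level.

**Two-level FIML** evaluates the exact unbalanced-cluster likelihood from
sufficient statistics: within-cluster deviations load on Σ_W with n_j − 1
degrees of freedom; the cluster mean is one observation with covariance
Σ_B + Σ_W/n_j. Clusters missing BEH contribute the four-variable marginal
at both levels. Three specifications: partially saturated (structured
within, free Σ_B; df = 2), two-level path model (both levels structured;
df = 4), and the saturated–saturated baseline anchoring the
likelihood-ratio χ². Positive definiteness is maintained by construction —
log-Cholesky factors for saturated blocks and exogenous blocks, log
residual variances — rather than by a barrier, which removes a failure mode
during line search. Gradients are analytic (chain rule through the
reduced-form Σ and the Cholesky factors) and evaluation is batched over
clusters, which is what makes thousands of replications affordable.
Convergence requires the max-norm of the gradient of the
*per-observation-scaled* deviance below 1e−5 (an absolute threshold on the
unscaled deviance would be meaningless across N spanning 10³–10⁵);
non-convergence marks the replication excluded, never raises mid-study.
Standard errors come from the observed information (finite differences of
the analytic gradient). RMSEA for two-level fits uses total participant
count as N — a documented knob, since the convention is not settled.

**MVMA** (fixed-effects) fits the model per study (BEH-missing studies fit
the three-path reduced model, df = 0), then pools coefficient vectors by
GLS with selection matrices: β̂ = (Σ Xᵀ V⁻¹ X)⁻¹ Σ Xᵀ V⁻¹ β̂_j, V_j from
the stage-1 expected information. T² is fixed at 0 because the generating
process holds within-study parameters constant across studies; the Q
statistic is reported but unused. MVMA has no meta-analytic model fit test.

**OSMASEM** (fixed-effects) pools study correlation vectors (strict
half-vectorization, column-major lower triangle in the fixed variable
order) by inverse-variance GLS, with normal-theory (Olkin–Siotani) sampling
covariances evaluated at the sample correlations and scaled by 1/n_j. The
model-implied correlation structure — exogenous block parameterized as
correlations via tanh, residual variances solved to give unit implied
diagonals — is fitted to the pooled vector by WLS with the pooled precision
as weight; χ² is the minimized discrepancy on df = 10 − 8 = 2. This
two-step fixed-weight GLS is deterministic and fast; it is not the
iteratively reweighted ML some software uses, so agreement with such
software is distributional (rejection rates, mean estimates), not
digit-level. Infeasible standardization (an implied residual variance ≤ 0)
yields `converged=False`.

## Evaluation

Per condition × method, over converged replications only: convergence rate,
mean estimate and RMSE per path, relative SE bias 100·(mean SE − empirical
SD)/SD (|bias| ≤ 10% conventionally acceptable), exact-fit rejection
(χ² p < α) and close-fit rejection (noncentral-χ² p for H₀: RMSEA < .05
below α), with α = 0.05 throughout. RMSEA = √(max(χ²−df,0)/(df(N−1))).
Cells with convergence below 50% are flagged and excluded from comparison.
The Monte Carlo band around a nominal rate is α ± 1.96·√(α(1−α)/reps). The
RMSE definition includes the square root (its occasionally radical-free
typesetting is treated as a slip), and close-fit "rejection" means a small
close-fit p-value — the conventional direction.

## What the generator does and does not emulate

Green tests establish behavior under exactly multivariate-normal two-level
data with constant within-study parameters, MCAR-style variable-level
missingness, and uniformly distributed study sizes. Real IPD collections
add non-normality, participant-level item nonresponse, genuinely
heterogeneous within-study effects (where fixed-effects pooling is no
longer the right benchmark), and informative study sizes — none of which
are modeled here. Convergence *rates* under missingness at k=10 are
software-specific in published comparisons (algorithm-switch behavior) and
are reproduced only qualitatively: failures concentrate at small k with
missing data.

## Numerical choices

* Covariance divisor N−1 everywhere, matching the (N−1)·F_ML statistic.
* Single-level optimization: BFGS on transformed parameters (log-Cholesky
  exogenous block, log residual variances) from closed-form starts; the
  fitted covariance must pass a Cholesky check or the fit is flagged
  non-converged.
* Two-level starts: within from the pooled within-study (centered)
  covariance; between from the covariance of study means minus
  Σ_W·mean(1/n_j), eigenvalue-floored to positive definiteness.
* Scenario load cross-check tolerance 0.0125 (see above); test-suite
  tolerance ±0.01 everywhere except the one documented cell.
* Oracles (dense per-cluster likelihood, regression closed forms,
  covariance propagation through the structural equations) live outside the
  public API and share no code with the production paths.

## Known limitations

Random-effects MVMA/OSMASEM, participant-level missingness, latent-variable
models, more than two levels, and observed-information "MLR"-style variants
are out of scope. The cluster-robust implementation is one conventional
sandwich/scaling variant; other software's exact choices differ in
finite-sample corrections, so CR columns should be compared as patterns,
not digits.
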