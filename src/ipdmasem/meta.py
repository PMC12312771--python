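"""Meta-analytic estimators: MVMA of path coefficients and one-stage MASEM.

Both are fixed-effects here (between-study heterogeneity T2 fixed at 0),
matching a data-generating process in which the within-study parameters do
not vary across studies.

* MVMA: the path model is fitted in every primary study; the per-study
  coefficient vectors are pooled by inverse-variance GLS. Studies missing
  the behavior variable contribute the three intention paths only — the
  pooling handles unequal effect sets through selection matrices.
* OSMASEM: each study contributes the strict half-vectorization of its
  correlation matrix with a normal-theory (Olkin–Siotani) sampling
  covariance; the pooled correlation vector is matched to the model-implied
  correlation structure vechs((I-B)^-1 Psi (I-B)^-T) under unit-diagonal
  standardization by weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._linalg import vech_indices
from .scenarios import VARIABLES
from .single_level import (
    FitResult,
    PathModelSpec,
    fit_measures,
    fit_path_model_ml,
    tpb_spec,
)

__all__ = [
    "StudyEffect",
    "StudyCorrelations",
    "MetaAnalysisResult",
    "fit_per_study",
    "mvma_fixed",
    "study_correlations",
    "fit_osmasem",
    "pair_labels",
    "effects_to_frame",
    "effects_from_frame",
]


@dataclass(frozen=True)
class StudyEffect:
    """Stage-1 output for one study: path estimates and their sampling covariance."""

    study_id: int
    names: tuple[str, ...]
    beta: np.ndarray
    V: np.ndarray


@dataclass(frozen=True)
class StudyCorrelations:
    """One study's correlation vector (vechs order) with sampling covariance."""

    study_id: int
    names: tuple[str, ...]
    r: np.ndarray
    V: np.ndarray
    n_j: int


@dataclass(frozen=True)
class MetaAnalysisResult:
    names: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    q_stat: float
    k: int
    t2: float = 0.0  # fixed-effects configuration

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _study_cov(study) -> tuple[np.ndarray, list[int]]:
    cols = np.flatnonzero(study.observed_mask)
    x = study.observations[:, cols]
    xc = x - x.mean(axis=0)
    return xc.T @ xc / (study.n_j - 1), cols


def fit_per_study(ds, spec: PathModelSpec | None = None) -> list[StudyEffect]:
    """Stage 1 of MVMA: ML path-model fit in every primary study.

    Studies with unobserved variables get the spec restricted to what they
    observed; non-converged studies are dropped (they do not enter stage 2).
    """
    spec = tpb_spec() if spec is None else spec
    effects = []
    for s in ds.studies:
        S, cols = _study_cov(s)
        obs_vars = tuple(VARIABLES[c] for c in cols)
        sub = spec if obs_vars == spec.variables else spec.restrict(obs_vars)
        fit = fit_path_model_ml(S, s.n_j, sub, method="stage1")
        if not fit.converged:
            continue
        npaths = len(sub.edges)
        acov = fit.extra["acov"]
        effects.append(
            StudyEffect(
                study_id=s.study_id,
                names=sub.path_names,
                beta=np.array([fit.estimates[n] for n in sub.path_names]),
                V=acov[:npaths, :npaths],
            )
        )
    return effects


def mvma_fixed(
    effects: list[StudyEffect], names: tuple[str, ...] | None = None
) -> MetaAnalysisResult:
    """Fixed-effects multivariate meta-analysis by GLS pooling.

    beta = (sum X' V^-1 X)^-1 sum X' V^-1 beta_j, with X_j selecting the
    effects study j provides. The heterogeneity Q statistic is reported but
    plays no role in the pooling.
    """
    if len(effects) < 1:
        raise ValueError("no study effects to pool")
    if names is None:
        names = tpb_spec().path_names
        if not any(set(e.names) & set(names) for e in effects):
            names = tuple(dict.fromkeys(n for e in effects for n in e.names))
    m = len(names)
    counts = {n: sum(n in e.names for e in effects) for n in names}
    missing = [n for n, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"effects {missing} are observed in no study")
    xtvx = np.zeros((m, m))
    xtvb = np.zeros(m)
    terms = []
    for e in effects:
        sel = [names.index(n) for n in e.names if n in names]
        rows = [e.names.index(names[i]) for i in sel]
        v_inv = np.linalg.inv(e.V[np.ix_(rows, rows)])
        b = e.beta[rows]
        xtvx[np.ix_(sel, sel)] += v_inv
        xtvb[sel] += v_inv @ b
        terms.append((sel, v_inv, b))
    cov = np.linalg.inv(xtvx)
    beta = cov @ xtvb
    q = 0.0
    for sel, v_inv, b in terms:
        resid = b - beta[sel]
        q += float(resid @ v_inv @ resid)
    return MetaAnalysisResult(tuple(names), beta, cov, q, k=len(effects))


def effects_to_frame(effects: list[StudyEffect]):
    """Long-format view of stage-1 effects (one row per effect pair, with the
    sampling covariance entries) for CSV inspection."""
    import pandas as pd

    rows = []
    for e in effects:
        for a, na in enumerate(e.names):
            for b, nb in enumerate(e.names):
                if b < a:
                    continue
                rows.append(
                    {
                        "study_id": e.study_id,
                        "effect_a": na,
                        "effect_b": nb,
                        "beta_a": float(e.beta[a]),
                        "vcov": float(e.V[a, b]),
                    }
                )
    return pd.DataFrame(rows)


def effects_from_frame(df) -> list[StudyEffect]:
    """Inverse of :func:`effects_to_frame`."""
    effects = []
    for sid, sub in df.groupby("study_id", sort=True):
        names = tuple(dict.fromkeys(sub["effect_a"]))
        m = len(names)
        beta = np.empty(m)
        V = np.empty((m, m))
        for _, row in sub.iterrows():
            a, b = names.index(row["effect_a"]), names.index(row["effect_b"])
            beta[a] = row["beta_a"]
            V[a, b] = V[b, a] = row["vcov"]
        effects.append(StudyEffect(int(sid), names, beta, V))
    return effects


# ---------------------------------------------------------------------------
# correlations


def pair_labels(variables: tuple[str, ...]) -> tuple[str, ...]:
    """Labels of the strict lower triangle in project vechs order."""
    r, c = vech_indices(len(variables), strict=True)
    return tuple(f"{variables[j]}~~{variables[i]}" for i, j in zip(r, c))


def _corr_sampling_cov(R: np.ndarray, n: int) -> np.ndarray:
    """Normal-theory asymptotic covariance of sample correlations (Olkin–
    Siotani), evaluated at R and scaled by 1/n."""
    p = R.shape[0]
    rows, cols = vech_indices(p, strict=True)
    pairs = list(zip(rows, cols))
    m = len(pairs)
    V = np.empty((m, m))
    for a in range(m):
        i, j = pairs[a]
        for b in range(a, m):
            k, l = pairs[b]
            term = (
                0.5 * R[i, j] * R[k, l]
                * (R[i, k] ** 2 + R[i, l] ** 2 + R[j, k] ** 2 + R[j, l] ** 2)
                + R[i, k] * R[j, l]
                + R[i, l] * R[j, k]
                - R[i, j] * (R[j, k] * R[j, l] + R[i, k] * R[i, l])
                - R[k, l] * (R[j, k] * R[i, k] + R[j, l] * R[i, l])
            )
            V[a, b] = V[b, a] = term / n
    return V


def study_correlations(ds) -> list[StudyCorrelations]:
    """Per-study correlation vectors (vechs order) with sampling covariances.

    Studies with a degenerate variance are dropped.
    """
    out = []
    for s in ds.studies:
        S, cols = _study_cov(s)
        sd = np.sqrt(np.diag(S))
        if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
            continue
        R = S / np.outer(sd, sd)
        np.fill_diagonal(R, 1.0)
        labels = pair_labels(tuple(VARIABLES[c] for c in cols))
        r, c = vech_indices(len(cols), strict=True)
        out.append(
            StudyCorrelations(
                study_id=s.study_id,
                names=labels,
                r=R[r, c],
                V=_corr_sampling_cov(R, s.n_j),
                n_j=s.n_j,
            )
        )
    return out


def _implied_unit_sigma(spec: PathModelSpec, paths: np.ndarray, exo_corr: np.ndarray):
    """Implied covariance with unit diagonal: exogenous block is a correlation
    matrix, residual variances are solved so every implied variance is 1.
    Returns (sigma, min_residual_variance)."""
    p = spec.p
    idx = {v: i for i, v in enumerate(spec.variables)}
    sigma = np.zeros((p, p))
    exo_i = [idx[v] for v in spec.exogenous]
    sigma[np.ix_(exo_i, exo_i)] = exo_corr
    coefs = dict(zip(spec.path_names, paths))
    min_psi = np.inf
    for v in spec.variables:
        if v in spec.exogenous:
            continue
        vi = idx[v]
        parents = spec.parents(v)
        pi = [idx[u] for u in parents]
        b = np.array([coefs[f"{v}~{u}"] for u in parents])
        explained = float(b @ sigma[np.ix_(pi, pi)] @ b)
        psi_v = 1.0 - explained
        min_psi = min(min_psi, psi_v)
        for u in spec.variables:
            ui = idx[u]
            if ui == vi:
                continue
            cov_vu = float(b @ sigma[pi, ui])
            sigma[vi, ui] = sigma[ui, vi] = cov_vu
        sigma[vi, vi] = 1.0
    return sigma, min_psi


def fit_osmasem(
    cors: list[StudyCorrelations], spec: PathModelSpec | None = None
) -> FitResult:
    """Fixed-effects one-stage MASEM on pooled study correlations.

    The study correlation vectors are pooled by inverse-variance GLS (with
    selection matrices for studies observing a variable subset); the path
    model's implied correlation structure is then fitted to the pooled
    vector by weighted least squares with the pooled precision as weight.
    chi2 is the minimized discrepancy on df = 10 - 8 = 2 for the TPB model.
    """
    spec = tpb_spec() if spec is None else spec
    if len(cors) < 2:
        raise ValueError("one-stage MASEM needs at least 2 studies")
    names = pair_labels(spec.variables)
    m = len(names)
    W = np.zeros((m, m))
    rhs = np.zeros(m)
    n_total = 0
    for c in cors:
        sel = [names.index(n) for n in c.names if n in names]
        rows = [c.names.index(names[i]) for i in sel]
        v_inv = np.linalg.inv(c.V[np.ix_(rows, rows)])
        W[np.ix_(sel, sel)] += v_inv
        rhs[sel] += v_inv @ c.r[rows]
        n_total += c.n_j
    rho_bar = np.linalg.solve(W, rhs)

    # pooled correlation matrix for start values
    p = spec.p
    R_bar = np.eye(p)
    r_i, c_i = vech_indices(p, strict=True)
    R_bar[r_i, c_i] = rho_bar
    R_bar[c_i, r_i] = rho_bar

    q_exo = len(spec.exogenous)
    exo_pairs = [(i, j) for j in range(q_exo) for i in range(j + 1, q_exo)]
    idx = {v: i for i, v in enumerate(spec.variables)}
    exo_i = [idx[v] for v in spec.exogenous]

    def unpack(x):
        paths = x[: len(spec.edges)]
        z = x[len(spec.edges) :]
        P = np.eye(q_exo)
        for t, (i, j) in enumerate(exo_pairs):
            P[i, j] = P[j, i] = np.tanh(z[t])
        return paths, P

    def resid(x):
        paths, P = unpack(x)
        sigma, min_psi = _implied_unit_sigma(spec, paths, P)
        if min_psi <= 0:
            return None, min_psi
        return rho_bar - sigma[r_i, c_i], min_psi

    # optimize on a per-observation scale so the gradient tolerance is
    # meaningful regardless of the pooled sample size
    def objective(x):
        d, min_psi = resid(x)
        if d is None:
            return (1e6 - 1e4 * min_psi) / n_total
        return float(d @ W @ d) / n_total

    # start: regressions on the pooled correlation matrix
    from .single_level import _regression_start

    theta0 = _regression_start(R_bar, spec)
    x0 = np.concatenate(
        [
            theta0[: len(spec.edges)],
            np.arctanh(
                np.clip(
                    [R_bar[exo_i[i], exo_i[j]] for i, j in exo_pairs], -0.97, 0.97
                )
            ),
        ]
    )
    res = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-10})
    x_hat = res.x
    d_hat, min_psi = resid(x_hat)
    df = m - x_hat.size
    if d_hat is None or min_psi <= 0:
        return FitResult.failure("OSMASEM", df=df, n=n_total)
    chi2 = float(d_hat @ W @ d_hat)
    # delta-method covariance of the WLS estimator
    J = np.empty((m, x_hat.size))
    h = 1e-6
    for t in range(x_hat.size):
        e = np.zeros_like(x_hat)
        e[t] = h
        dp, _ = resid(x_hat + e)
        dm, _ = resid(x_hat - e)
        J[:, t] = -(dp - dm) / (2 * h)
    try:
        acov = np.linalg.inv(J.T @ W @ J)
    except np.linalg.LinAlgError:
        return FitResult.failure("OSMASEM", df=df, n=n_total)
    se_all = np.sqrt(np.maximum(np.diag(acov), 0.0))
    paths, P = unpack(x_hat)
    estimates = dict(zip(spec.path_names, paths.tolist()))
    se = dict(zip(spec.path_names, se_all[: len(spec.edges)].tolist()))
    for t, (i, j) in enumerate(exo_pairs):
        estimates[f"{spec.exogenous[j]}~~{spec.exogenous[i]}"] = float(P[i, j])
    rmsea, close_p = fit_measures(chi2, df, n_total)
    return FitResult(
        method="OSMASEM",
        estimates=estimates,
        se=se,
        chi2=chi2,
        df=df,
        chi2_p=float(stats.chi2.sf(chi2, df)),
        rmsea=rmsea,
        rmsea_close_p=close_p,
        loglik=float("nan"),
        converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-6),
        n_effective=n_total,
        extra={"rho_bar": rho_bar, "k": len(cors)},
    )
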