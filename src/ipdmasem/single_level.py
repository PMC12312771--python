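"""Single-level path-model estimation.

Normal-theory maximum likelihood on a sample covariance matrix, with

* naive standard errors from the expected (Fisher) information of the ML
  discrepancy,
* cluster-robust (sandwich) standard errors and a mean-scaled chi-square
  for data pooled across primary studies, and
* RMSEA-based close-fit testing against H0: RMSEA < .05.

The chi-square convention is (N - 1) * F_ML throughout, and sample
covariances use the N - 1 divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from ._linalg import (
    chol_to_sigma,
    duplication_matrix,
    sigma_to_chol,
    unvech,
    vech,
)
from .scenarios import VARIABLES, PathModelMatrices, implied_sigma

__all__ = [
    "PathModelSpec",
    "FitResult",
    "tpb_spec",
    "fit_path_model_ml",
    "naive_pooling_fit",
    "cluster_robust_fit",
    "fit_measures",
    "CLOSE_FIT_RMSEA",
]

#: Null value for the close-fit test H0: RMSEA < .05.
CLOSE_FIT_RMSEA = 0.05

TPB_EDGES = (
    ("INT", "ATT"),
    ("INT", "SN"),
    ("INT", "PBC"),
    ("BEH", "PBC"),
    ("BEH", "INT"),
)


@dataclass(frozen=True)
class PathModelSpec:
    """A recursive path model: directed edges plus a saturated exogenous block.

    Exogenous variables (never an outcome) get free variances and pairwise
    covariances; endogenous variables get free, mutually uncorrelated
    residual variances. Parameters are named lavaan-style:
    ``INT~ATT`` (path), ``ATT~~SN`` (covariance), ``INT~~INT`` (variance).
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        order = {v: i for i, v in enumerate(self.variables)}
        for out, pred in self.edges:
            if out not in order or pred not in order:
                raise ValueError(f"edge {out}~{pred} uses unknown variable")
            if order[pred] >= order[out]:
                raise ValueError(
                    "edges must run from earlier to later variables (acyclic, "
                    f"got {out}~{pred})"
                )

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> tuple[str, ...]:
        outs = {o for o, _ in self.edges}
        return tuple(v for v in self.variables if v in outs)

    @property
    def exogenous(self) -> tuple[str, ...]:
        outs = {o for o, _ in self.edges}
        return tuple(v for v in self.variables if v not in outs)

    @property
    def path_names(self) -> tuple[str, ...]:
        return tuple(f"{o}~{p}" for o, p in self.edges)

    @property
    def param_names(self) -> tuple[str, ...]:
        exo = self.exogenous
        cov_names = [
            f"{exo[j]}~~{exo[i]}"
            for j in range(len(exo))
            for i in range(j, len(exo))
        ]
        var_names = [f"{v}~~{v}" for v in self.endogenous]
        return self.path_names + tuple(cov_names) + tuple(var_names)

    @property
    def n_params(self) -> int:
        q = len(self.exogenous)
        return len(self.edges) + q * (q + 1) // 2 + len(self.endogenous)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_params

    def parents(self, outcome: str) -> tuple[str, ...]:
        return tuple(p for o, p in self.edges if o == outcome)

    def restrict(self, variables: tuple[str, ...]) -> "PathModelSpec":
        """Sub-model on a variable subset, dropping edges that touch removed
        variables (used when a variable is unobserved in some studies)."""
        keep = [v for v in self.variables if v in variables]
        edges = tuple(e for e in self.edges if e[0] in keep and e[1] in keep)
        return PathModelSpec(tuple(keep), edges)

    def matrices(self, theta: np.ndarray) -> PathModelMatrices:
        """Assemble (B, Psi) from a natural parameter vector."""
        idx = {v: i for i, v in enumerate(self.variables)}
        B = np.zeros((self.p, self.p))
        Psi = np.zeros((self.p, self.p))
        k = 0
        for o, pr in self.edges:
            B[idx[o], idx[pr]] = theta[k]
            k += 1
        exo = self.exogenous
        for j in range(len(exo)):
            for i in range(j, len(exo)):
                a, b = idx[exo[i]], idx[exo[j]]
                Psi[a, b] = Psi[b, a] = theta[k]
                k += 1
        for v in self.endogenous:
            Psi[idx[v], idx[v]] = theta[k]
            k += 1
        return PathModelMatrices(self.variables, B, Psi)


def tpb_spec(variables: tuple[str, ...] = VARIABLES) -> PathModelSpec:
    """The Theory of Planned Behavior path model (or its reduction to a
    variable subset, e.g. without BEH)."""
    edges = tuple(e for e in TPB_EDGES if e[0] in variables and e[1] in variables)
    return PathModelSpec(tuple(variables), edges)


@dataclass
class FitResult:
    """One estimator's output for one dataset."""

    method: str
    estimates: dict[str, float]
    se: dict[str, float]
    chi2: float
    df: int
    chi2_p: float
    rmsea: float
    rmsea_close_p: float
    loglik: float
    converged: bool
    n_effective: int
    scaling_factor: float = 1.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def failure(cls, method: str, df: int = 0, n: int = 0) -> "FitResult":
        nan = float("nan")
        return cls(method, {}, {}, nan, df, nan, nan, nan, nan, False, n)


def fit_measures(
    chi2: float, df: int, n: int, scaling: float = 1.0
) -> tuple[float, float]:
    """RMSEA and the close-fit p-value from a (possibly scaled) chi-square.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1))); the close-fit p-value is
    the upper tail of the noncentral chi-square with noncentrality
    .05^2 * df * (N - 1) evaluated at chi2. Close fit is rejected when the
    p-value drops below alpha.
    """
    if df < 1:
        raise ValueError("RMSEA undefined for df < 1")
    chi2 = chi2 / scaling
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    lam = CLOSE_FIT_RMSEA**2 * df * (n - 1)
    close_p = float(stats.ncx2.sf(chi2, df, lam))
    return rmsea, close_p


# ---------------------------------------------------------------------------
# ML machinery


def _regression_start(S: np.ndarray, spec: PathModelSpec) -> np.ndarray:
    """Ordered-regression closed forms; for recursive models with
    uncorrelated residuals these are the exact ML estimates."""
    idx = {v: i for i, v in enumerate(spec.variables)}
    coefs: dict[str, float] = {}
    for out in spec.endogenous:
        parents = spec.parents(out)
        pi = [idx[v] for v in parents]
        oi = idx[out]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, oi])
        for v, bv in zip(parents, b):
            coefs[f"{out}~{v}"] = float(bv)
    theta = [coefs[name] for name in spec.path_names]
    exo = spec.exogenous
    ei = [idx[v] for v in exo]
    Sexo = S[np.ix_(ei, ei)]
    for j in range(len(exo)):
        for i in range(j, len(exo)):
            theta.append(Sexo[i, j])
    for out in spec.endogenous:
        parents = spec.parents(out)
        pi = [idx[v] for v in parents]
        oi = idx[out]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, oi])
        theta.append(float(S[oi, oi] - S[pi, oi] @ b))
    return np.asarray(theta)


def _natural_to_trans(theta: np.ndarray, spec: PathModelSpec) -> np.ndarray:
    ne, q = len(spec.edges), len(spec.exogenous)
    nc = q * (q + 1) // 2
    exo_block = unvech(theta[ne : ne + nc], q)
    return np.concatenate(
        [theta[:ne], sigma_to_chol(exo_block), np.log(theta[ne + nc :])]
    )


def _trans_to_natural(x: np.ndarray, spec: PathModelSpec) -> np.ndarray:
    ne, q = len(spec.edges), len(spec.exogenous)
    nc = q * (q + 1) // 2
    exo_block = chol_to_sigma(x[ne : ne + nc], q)
    return np.concatenate([x[:ne], vech(exo_block), np.exp(x[ne + nc :])])


def _fml(S: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(
        logdet + np.trace(np.linalg.solve(sigma, S)) - logdet_s - S.shape[0]
    )


def _delta_matrix(theta: np.ndarray, spec: PathModelSpec, h: float = 1e-6) -> np.ndarray:
    """Jacobian of vech(Sigma(theta)) w.r.t. the natural parameters."""
    cols = []
    for t in range(theta.size):
        e = np.zeros_like(theta)
        e[t] = h
        hi = vech(implied_sigma(spec.matrices(theta + e)))
        lo = vech(implied_sigma(spec.matrices(theta - e)))
        cols.append((hi - lo) / (2 * h))
    return np.column_stack(cols)


def _weight_matrix(sigma: np.ndarray) -> np.ndarray:
    """Normal-theory GLS weight 0.5 D' (Sigma^-1 kron Sigma^-1) D on vech."""
    q = np.linalg.inv(sigma)
    D = duplication_matrix(sigma.shape[0])
    return 0.5 * D.T @ np.kron(q, q) @ D


def fit_path_model_ml(
    S: np.ndarray,
    N: int,
    spec: PathModelSpec,
    method: str = "ML",
) -> FitResult:
    """Fit a path model to a sample covariance by normal-theory ML.

    Minimizes F_ML = log|Sigma(theta)| + tr(S Sigma^-1) - log|S| - p by
    quasi-Newton from ordered-regression start values; chi2 = (N-1) F_ML;
    standard errors come from the expected information of F_ML scaled by
    N - 1. Optimizer failure or an indefinite fitted covariance yields
    ``converged=False`` rather than an exception.
    """
    S = np.asarray(S, dtype=float)
    p = spec.p
    if S.shape != (p, p) or N <= p:
        raise ValueError("S must be p x p with N > p")
    try:
        start_nat = _regression_start(S, spec)
        x0 = _natural_to_trans(start_nat, spec)

        def objective(x: np.ndarray) -> float:
            sigma = implied_sigma(spec.matrices(_trans_to_natural(x, spec)))
            return _fml(S, sigma)

        res = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-8})
        x_hat = res.x if res.fun <= objective(x0) else x0
        theta = _trans_to_natural(x_hat, spec)
        m_hat = spec.matrices(theta)
        sigma_hat = implied_sigma(m_hat)
        np.linalg.cholesky(sigma_hat)
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        return FitResult.failure(method, df=spec.df, n=N)

    fml = _fml(S, sigma_hat)
    chi2 = max((N - 1) * fml, 0.0)
    df = spec.df
    chi2_p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    delta = _delta_matrix(theta, spec)
    W = _weight_matrix(sigma_hat)
    info = delta.T @ W @ delta
    try:
        acov = np.linalg.inv(info) / (N - 1)
        se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        return FitResult.failure(method, df=df, n=N)
    if df > 0:
        rmsea, close_p = fit_measures(chi2, df, N)
    else:
        rmsea, close_p = 0.0, float("nan")
    s_ml = S * (N - 1) / N
    loglik = -0.5 * N * (
        p * np.log(2 * np.pi)
        + np.linalg.slogdet(sigma_hat)[1]
        + np.trace(np.linalg.solve(sigma_hat, s_ml))
    )
    names = spec.param_names
    return FitResult(
        method=method,
        estimates=dict(zip(names, theta.tolist())),
        se=dict(zip(names, se.tolist())),
        chi2=chi2,
        df=df,
        chi2_p=chi2_p,
        rmsea=rmsea,
        rmsea_close_p=close_p,
        loglik=float(loglik),
        converged=True,
        n_effective=N,
        extra={"sigma_hat": sigma_hat, "theta": theta, "spec": spec, "acov": acov},
    )


def _pooled(ds, spec: PathModelSpec, on_missing: Literal["restrict", "error"]):
    """Pooled rows, grand-mean-centered, for the commonly observed variables."""
    common = np.logical_and.reduce([s.observed_mask for s in ds.studies])
    obs_vars = tuple(v for v, m in zip(VARIABLES, common) if m)
    missing_needed = [v for v in spec.variables if v not in obs_vars]
    if missing_needed:
        if on_missing == "error":
            raise ValueError(
                f"variables {missing_needed} are unobserved in some studies"
            )
        spec = spec.restrict(obs_vars)
    cols = [VARIABLES.index(v) for v in spec.variables]
    X = np.vstack([s.observations[:, cols] for s in ds.studies])
    sizes = [s.n_j for s in ds.studies]
    Xc = X - X.mean(axis=0, keepdims=True)
    N = X.shape[0]
    S = Xc.T @ Xc / (N - 1)
    return Xc, sizes, S, N, spec


def naive_pooling_fit(
    ds,
    spec: PathModelSpec | None = None,
    on_missing: Literal["restrict", "error"] = "restrict",
) -> FitResult:
    """Treat all pooled observations as one independent sample (naive pooling)."""
    spec = tpb_spec() if spec is None else spec
    _, _, S, N, spec = _pooled(ds, spec, on_missing)
    return fit_path_model_ml(S, N, spec, method="NP")


def cluster_robust_fit(
    ds,
    spec: PathModelSpec | None = None,
    on_missing: Literal["restrict", "error"] = "restrict",
) -> FitResult:
    """Naive-pooling point estimates with design-based corrections.

    Standard errors use the cluster sandwich A^-1 B A^-1 (A the expected
    information, B the sum of per-study score outer products); the exact-fit
    statistic is mean-scaled by c = tr(U Gamma)/df with Gamma the
    cluster-aggregated asymptotic covariance of the sample moments.
    """
    spec = tpb_spec() if spec is None else spec
    if len(ds.studies) < 2:
        raise ValueError("cluster-robust estimation needs at least 2 studies")
    Xc, sizes, S, N, spec = _pooled(ds, spec, on_missing)
    base = fit_path_model_ml(S, N, spec, method="CR")
    if not base.converged:
        return base
    sigma_hat = base.extra["sigma_hat"]
    theta = base.extra["theta"]
    p = spec.p
    Q = np.linalg.inv(sigma_hat)
    delta = _delta_matrix(theta, spec)
    d_mats = [unvech(delta[:, t], p) for t in range(delta.shape[1])]
    # off-diagonal vech entries represent two matrix cells; unvech restores both

    # per-study moment contributions
    s_ml = vech(Xc.T @ Xc / N)
    starts = np.cumsum([0] + sizes)
    scores, dvecs = [], []
    for j in range(len(sizes)):
        block = Xc[starts[j] : starts[j + 1]]
        C_j = block.T @ block
        M = Q @ (C_j - sizes[j] * sigma_hat) @ Q
        scores.append([0.5 * np.sum(D * M) for D in d_mats])
        dvecs.append(vech(C_j) - sizes[j] * s_ml)
    G = np.asarray(scores)
    A = N * np.array(
        [[0.5 * np.sum((Q @ Di) * (Dj.T @ Q)) for Dj in d_mats] for Di in d_mats]
    )
    try:
        a_inv = np.linalg.inv(A)
        cov = a_inv @ (G.T @ G) @ a_inv
    except np.linalg.LinAlgError:
        return FitResult.failure("CR", df=spec.df, n=N)
    base.se = {
        name: float(np.sqrt(max(cov[t, t], 0.0)))
        for t, name in enumerate(spec.param_names)
    }
    # mean-scaled exact-fit statistic
    if spec.df > 0:
        W = _weight_matrix(sigma_hat)
        WD = W @ delta
        U = W - WD @ np.linalg.solve(delta.T @ WD, WD.T)
        Gamma = np.einsum("ji,jk->ik", np.asarray(dvecs), np.asarray(dvecs)) / N
        c = float(np.trace(U @ Gamma) / spec.df)
        base.scaling_factor = c
        scaled = base.chi2 / c
        base.chi2 = scaled
        base.chi2_p = float(stats.chi2.sf(scaled, spec.df))
        base.rmsea, base.rmsea_close_p = fit_measures(scaled, spec.df, N)
    return base
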