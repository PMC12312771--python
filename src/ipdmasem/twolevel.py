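"""Two-level path-model estimation by full-information maximum likelihood.

The total covariance of clustered observations decomposes as
Sigma_T = Sigma_W + Sigma_B. Three model classes are supported:

* the partially saturated (maximum) model — hypothesized within-study
  structure, unrestricted between-study covariance;
* the two-level path model — hypothesized structure at both levels;
* the saturated-saturated baseline, whose maximized log-likelihood anchors
  the likelihood-ratio chi-square of the structured models.

The likelihood is exact for unbalanced clusters and is evaluated from
per-cluster sufficient statistics: within-cluster deviations load on
Sigma_W with n_j - 1 degrees of freedom and the cluster mean contributes
one observation with covariance Sigma_B + Sigma_W / n_j. Clusters missing
the behavior variable contribute the corresponding 4-variable marginal.
Level covariances are kept positive definite during the search through a
log-Cholesky parameterization (saturated blocks and exogenous blocks) and
log residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._linalg import chol_grad, chol_to_sigma, nearest_psd, sigma_to_chol, vech, unvech
from .scenarios import VARIABLES
from .single_level import (
    FitResult,
    PathModelSpec,
    _regression_start,
    fit_measures,
    tpb_spec,
)

__all__ = [
    "TwoLevelSpec",
    "twolevel_loglik",
    "loglik_from_sigmas",
    "fit_saturated",
    "fit_partially_saturated",
    "fit_twolevel",
]

#: Convergence requires the max-norm of the per-observation-scaled gradient
#: below this threshold (and positive-definite level covariances, which hold
#: by construction of the parameterization).
GRAD_TOL = 1e-5

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TwoLevelSpec:
    """Within and between model structure; ``between=None`` means saturated.

    A free mean vector (one mean per variable) is always included.
    """

    within: PathModelSpec | None
    between: PathModelSpec | None

    @property
    def p(self) -> int:
        s = self.within or self.between
        return len(VARIABLES) if s is None else s.p

    def n_level_params(self, spec: PathModelSpec | None) -> int:
        p = self.p
        return p * (p + 1) // 2 if spec is None else spec.n_params


# ---------------------------------------------------------------------------
# sufficient statistics


class _Suffstats:
    """Per-dataset sufficient statistics, grouped by observed-variable mask."""

    def __init__(self, ds) -> None:
        groups: dict[tuple, list] = {}
        for s in ds.studies:
            groups.setdefault(tuple(s.observed_mask.tolist()), []).append(s)
        self.groups = []
        self.n_total = ds.n_total
        for mask, studies in groups.items():
            cols = np.flatnonzero(np.asarray(mask))
            ns = np.array([s.n_j for s in studies], dtype=float)
            obs = [s.observations[:, cols] for s in studies]
            ybar = np.array([o.mean(axis=0) for o in obs])
            a_sum = np.zeros((len(cols), len(cols)))
            for o, yb in zip(obs, ybar):
                d = o - yb
                a_sum += d.T @ d
            self.groups.append(
                {
                    "cols": cols,
                    "ns": ns,
                    "ybar": ybar,
                    "a_sum": a_sum,
                    "nm1": float(np.sum(ns - 1.0)),
                }
            )


def _loglik_grads(mu, sigma_w, sigma_b, stats_: _Suffstats, want_grad: bool):
    """Exact log-likelihood and (optionally) gradients w.r.t. mu and the two
    level covariances (full-matrix convention: dll = sum(G * dSigma))."""
    p = mu.size
    ll = 0.0
    g_mu = np.zeros(p)
    g_w = np.zeros((p, p))
    g_b = np.zeros((p, p))
    for g in stats_.groups:
        cols = g["cols"]
        ix = np.ix_(cols, cols)
        sw = sigma_w[ix]
        sb = sigma_b[ix]
        ns = g["ns"]
        pg = len(cols)
        sign, logdet_w = np.linalg.slogdet(sw)
        if sign <= 0:
            return -np.inf, g_mu, g_w, g_b
        sw_inv = np.linalg.inv(sw)
        v = sb[None, :, :] + sw[None, :, :] / ns[:, None, None]
        sign_v, logdet_v = np.linalg.slogdet(v)
        if np.any(sign_v <= 0):
            return -np.inf, g_mu, g_w, g_b
        v_inv = np.linalg.inv(v)
        r = g["ybar"] - mu[cols]
        q = np.einsum("jab,jb->ja", v_inv, r)
        ll += -0.5 * (
            g["nm1"] * (pg * _LOG2PI + logdet_w)
            + float(np.sum(sw_inv * g["a_sum"]))
            + ns.size * pg * _LOG2PI
            + pg * float(np.sum(np.log(ns)))
            + float(np.sum(logdet_v))
            + float(np.sum(q * r))
        )
        if want_grad:
            mean_part = -0.5 * v_inv + 0.5 * np.einsum("ja,jb->jab", q, q)
            g_b[ix] += mean_part.sum(axis=0)
            g_w[ix] += (
                -0.5 * g["nm1"] * sw_inv
                + 0.5 * sw_inv @ g["a_sum"] @ sw_inv
                + np.einsum("j,jab->ab", 1.0 / ns, mean_part)
            )
            np.add.at(g_mu, cols, q.sum(axis=0))
    return ll, g_mu, g_w, g_b


def loglik_from_sigmas(mu, sigma_w, sigma_b, ds) -> float:
    """Exact two-level MVN log-likelihood for given mean and level covariances."""
    ll, *_ = _loglik_grads(
        np.asarray(mu, float),
        np.asarray(sigma_w, float),
        np.asarray(sigma_b, float),
        _Suffstats(ds),
        want_grad=False,
    )
    return ll


# ---------------------------------------------------------------------------
# parameter packing


def _n_trans(spec: PathModelSpec | None, p: int) -> int:
    return p * (p + 1) // 2 if spec is None else spec.n_params


def _level_sigma_and_grad(spec, x, p, grad_sigma=None):
    """Level covariance from transformed parameters; optionally chain the
    symmetric full-matrix gradient back onto the transformed parameters."""
    if spec is None:
        sigma = chol_to_sigma(x, p)
        if grad_sigma is None:
            return sigma, None
        return sigma, chol_grad(grad_sigma, x, p)
    ne, q = len(spec.edges), len(spec.exogenous)
    nc = q * (q + 1) // 2
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    for t, (o, pr) in enumerate(spec.edges):
        B[idx[o], idx[pr]] = x[t]
    psi = np.zeros((p, p))
    exo_i = [idx[v] for v in spec.exogenous]
    psi[np.ix_(exo_i, exo_i)] = chol_to_sigma(x[ne : ne + nc], q)
    res = np.exp(x[ne + nc :])
    endo_i = [idx[v] for v in spec.endogenous]
    psi[endo_i, endo_i] = res
    m = np.linalg.inv(np.eye(p) - B)
    sigma = m @ psi @ m.T
    if grad_sigma is None:
        return sigma, None
    gx = np.zeros_like(x)
    mp_sig = m.T @ grad_sigma @ sigma
    for t, (o, pr) in enumerate(spec.edges):
        gx[t] = 2.0 * mp_sig[idx[o], idx[pr]]
    k_psi = m.T @ grad_sigma @ m
    gx[ne : ne + nc] = chol_grad(k_psi[np.ix_(exo_i, exo_i)], x[ne : ne + nc], q)
    gx[ne + nc :] = k_psi[endo_i, endo_i] * res
    return sigma, gx


def _level_natural(spec, x, p):
    """Named natural parameters of one level from its transformed vector."""
    if spec is None:
        return {}
    ne, q = len(spec.edges), len(spec.exogenous)
    nc = q * (q + 1) // 2
    exo_block = chol_to_sigma(x[ne : ne + nc], q)
    nat = np.concatenate([x[:ne], vech(exo_block), np.exp(x[ne + nc :])])
    return dict(zip(spec.param_names, nat.tolist()))


def _level_start(spec, sigma, p):
    """Transformed start values for one level from a target covariance."""
    sigma = nearest_psd(sigma, 1e-4)
    if spec is None:
        return sigma_to_chol(sigma)
    theta = _regression_start(sigma, spec)
    ne, q = len(spec.edges), len(spec.exogenous)
    nc = q * (q + 1) // 2
    exo = nearest_psd(unvech(theta[ne : ne + nc], q), 1e-4)
    res = np.maximum(theta[ne + nc :], 1e-4)
    return np.concatenate([theta[:ne], sigma_to_chol(exo), np.log(res)])


class _Objective:
    def __init__(self, ds, spec: TwoLevelSpec) -> None:
        self.stats = _Suffstats(ds)
        self.spec = spec
        self.p = spec.p
        self.nw = _n_trans(spec.within, self.p)
        self.nb = _n_trans(spec.between, self.p)
        self.scale = float(self.stats.n_total)

    def split(self, x):
        p = self.p
        return x[:p], x[p : p + self.nw], x[p + self.nw :]

    def value_and_grad(self, x):
        mu, xw, xb = self.split(x)
        sw, _ = _level_sigma_and_grad(self.spec.within, xw, self.p)
        sb, _ = _level_sigma_and_grad(self.spec.between, xb, self.p)
        ll, g_mu, g_w, g_b = _loglik_grads(mu, sw, sb, self.stats, want_grad=True)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(x)
        _, gxw = _level_sigma_and_grad(self.spec.within, xw, self.p, g_w)
        _, gxb = _level_sigma_and_grad(self.spec.between, xb, self.p, g_b)
        grad = np.concatenate([g_mu, gxw, gxb])
        return -ll / self.scale, -grad / self.scale

    def loglik(self, x) -> float:
        f, _ = self.value_and_grad(x)
        return -f * self.scale


def twolevel_loglik(theta: np.ndarray, ds, spec: TwoLevelSpec) -> float:
    """Log-likelihood at a transformed parameter vector (means, within, between)."""
    return _Objective(ds, spec).loglik(np.asarray(theta, float))


def _start_vector(ds, spec: TwoLevelSpec) -> np.ndarray:
    p = spec.p
    complete = [s for s in ds.studies if s.observed_mask.all()]
    pool = complete if complete else list(ds.studies)
    a_sum = np.zeros((p, p))
    nm1 = 0.0
    for s in pool:
        d = s.observations - s.observations.mean(axis=0)
        a_sum += d.T @ d
        nm1 += s.n_j - 1
    sw = a_sum / max(nm1, 1.0)
    ybar = np.array([s.observations.mean(axis=0) for s in pool])
    ns = np.array([s.n_j for s in pool], dtype=float)
    mu = ybar.mean(axis=0)
    if len(pool) > 1:
        sb = np.cov(ybar.T, ddof=1) - sw * float(np.mean(1.0 / ns))
    else:
        sb = np.eye(p) * 0.05
    sb = nearest_psd(sb, 1e-3)
    return np.concatenate(
        [mu, _level_start(spec.within, sw, p), _level_start(spec.between, sb, p)]
    )


def _maximize(ds, spec: TwoLevelSpec):
    obj = _Objective(ds, spec)
    x0 = _start_vector(ds, spec)
    res = optimize.minimize(
        obj.value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-6, "maxcor": 30},
    )
    converged = bool(np.isfinite(res.fun) and np.max(np.abs(res.jac)) < GRAD_TOL)
    return obj, res.x, -res.fun * obj.scale, converged


def fit_saturated(ds):
    """Saturated-saturated baseline; returns (loglik, x_hat, converged)."""
    obj, x, ll, conv = _maximize(ds, TwoLevelSpec(None, None))
    return ll, x, conv


def _path_se(obj: _Objective, x_hat: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Observed-information SEs via finite differences of the analytic
    gradient of the unscaled negative log-likelihood."""
    n = x_hat.size
    H = np.zeros((n, n))
    for t in range(n):
        e = np.zeros(n)
        e[t] = h
        _, gp = obj.value_and_grad(x_hat + e)
        _, gm = obj.value_and_grad(x_hat - e)
        H[:, t] = (gp - gm) / (2 * h) * obj.scale
    H = (H + H.T) / 2.0
    try:
        acov = np.linalg.inv(H)
        return np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def _fit_structured(ds, spec: TwoLevelSpec, method: str, df: int, baseline, compute_se):
    if baseline is None:
        baseline = fit_saturated(ds)
    ll_sat, _, sat_conv = baseline
    try:
        obj, x_hat, ll, conv = _maximize(ds, spec)
    except (np.linalg.LinAlgError, ValueError):
        return FitResult.failure(method, df=df, n=ds.n_total)
    if not (conv and sat_conv):
        return FitResult.failure(method, df=df, n=ds.n_total)
    mu, xw, xb = obj.split(x_hat)
    estimates = dict(_level_natural(spec.within, xw, obj.p))
    for name, val in _level_natural(spec.between, xb, obj.p).items():
        estimates[f"between.{name}"] = val
    se = {}
    if compute_se:
        se_all = _path_se(obj, x_hat)
        offset = obj.p
        if spec.within is not None:
            for t, name in enumerate(spec.within.path_names):
                se[name] = float(se_all[offset + t])
        if spec.between is not None:
            for t, name in enumerate(spec.between.path_names):
                se[f"between.{name}"] = float(se_all[offset + obj.nw + t])
    chi2 = max(2.0 * (ll_sat - ll), 0.0)
    n = ds.n_total
    rmsea, close_p = fit_measures(chi2, df, n)
    return FitResult(
        method=method,
        estimates=estimates,
        se=se,
        chi2=chi2,
        df=df,
        chi2_p=float(stats.chi2.sf(chi2, df)),
        rmsea=rmsea,
        rmsea_close_p=close_p,
        loglik=ll,
        converged=True,
        n_effective=n,
        extra={"loglik_saturated": ll_sat},
    )


def fit_partially_saturated(
    ds,
    within_spec: PathModelSpec | None = None,
    baseline=None,
    compute_se: bool = True,
):
    """Hypothesized within-study model, saturated between-study covariance.

    The exact-fit chi-square is the likelihood ratio against the
    saturated-saturated baseline (df = 2 for the five-variable TPB model).
    """
    within = tpb_spec() if within_spec is None else within_spec
    spec = TwoLevelSpec(within, None)
    return _fit_structured(ds, spec, "PS", within.df, baseline, compute_se)


def fit_twolevel(
    ds,
    within_spec: PathModelSpec | None = None,
    between_spec: PathModelSpec | None = None,
    baseline=None,
    compute_se: bool = True,
):
    """Hypothesized structure at both levels (df = 4 for the TPB model).

    Within-level path estimates carry plain names; between-level parameters
    are prefixed ``between.``.
    """
    within = tpb_spec() if within_spec is None else within_spec
    between = tpb_spec() if between_spec is None else between_spec
    spec = TwoLevelSpec(within, between)
    return _fit_structured(
        ds, spec, "2L", within.df + between.df, baseline, compute_se
    )
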