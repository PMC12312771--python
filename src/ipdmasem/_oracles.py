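"""Brute-force oracles and tiny fixtures used by the test suite.

Everything here is deliberately simple and shares no code with the
production likelihood or optimizer paths; these functions exist so that the
estimators can be checked against independent computations on inputs small
enough for dense evaluation. Not part of the public API.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .generate import (
    ConditionSpec,
    MetaDataset,
    apply_missingness,
    simulate_meta_dataset,
)
from .scenarios import ScenarioID, get_scenario
from .single_level import PathModelSpec


def make_toy_dataset(seed: int = 0, missing: bool = False, k: int = 6) -> MetaDataset:
    """A hand-sized IPD collection (k=6 studies of 8-12 participants) drawn
    from the equal-structure scenario; small enough for dense likelihoods."""
    cond = ConditionSpec(
        ScenarioID.S4_high_equal,
        k=k,
        missing=missing,
        n_min=8,
        n_max=12,
        master_seed=seed,
    )
    rng = np.random.default_rng(seed)
    ds = simulate_meta_dataset(get_scenario(cond.scenario), cond, rng)
    return apply_missingness(ds, rng)


def brute_force_loglik(
    mu: np.ndarray, sigma_w: np.ndarray, sigma_b: np.ndarray, ds: MetaDataset
) -> float:
    """Two-level MVN log-likelihood via each cluster's dense (n_j p) x (n_j p)
    covariance: Sigma_W on the block diagonal plus Sigma_B in every block."""
    mu = np.asarray(mu, float)
    total = 0.0
    for s in ds.studies:
        cols = np.flatnonzero(s.observed_mask)
        y = s.observations[:, cols]
        n_j, p = y.shape
        if n_j * p > 200:
            raise MemoryError("cluster too large for the dense oracle")
        sw = sigma_w[np.ix_(cols, cols)]
        sb = sigma_b[np.ix_(cols, cols)]
        big = np.kron(np.ones((n_j, n_j)), sb) + np.kron(np.eye(n_j), sw)
        total += stats.multivariate_normal.logpdf(
            y.ravel(), mean=np.tile(mu[cols], n_j), cov=big
        )
    return float(total)


def regression_closed_form(S: np.ndarray, spec: PathModelSpec) -> dict[str, float]:
    """Path coefficients by solving each outcome's normal equations on S."""
    idx = {v: i for i, v in enumerate(spec.variables)}
    out: dict[str, float] = {}
    for v in spec.endogenous:
        parents = spec.parents(v)
        pi = [idx[u] for u in parents]
        spp = S[np.ix_(pi, pi)]
        if abs(np.linalg.det(spp)) < 1e-12:
            raise ValueError(f"singular predictor block for {v}")
        b = np.linalg.solve(spp, S[pi, idx[v]])
        for u, bu in zip(parents, b):
            out[f"{v}~{u}"] = float(bu)
    return out
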