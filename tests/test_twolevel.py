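"""Two-level FIML: likelihood correctness, nesting, model recovery."""

import numpy as np
import pytest
from scipy import stats

from ipdmasem._oracles import brute_force_loglik, make_toy_dataset
from ipdmasem.generate import ConditionSpec, generate_replication
from ipdmasem.scenarios import get_scenario
from ipdmasem.single_level import tpb_spec
from ipdmasem.twolevel import (
    TwoLevelSpec,
    _Objective,
    _level_sigma_and_grad,
    _start_vector,
    fit_partially_saturated,
    fit_saturated,
    fit_twolevel,
    loglik_from_sigmas,
    twolevel_loglik,
)


def _random_sigmas(rng, scale=0.3):
    a = rng.normal(size=(5, 7))
    b = rng.normal(size=(5, 7))
    return a @ a.T / 7 + 0.3 * np.eye(5), scale * (b @ b.T / 7 + 0.3 * np.eye(5))


@pytest.mark.parametrize("missing", [False, True])
def test_loglik_matches_dense_oracle(missing, toy_ds, toy_ds_missing):
    """Sufficient-statistic likelihood equals the dense per-cluster MVN density
    (Sigma_W block-diagonal + Sigma_B everywhere) to 1e-8, for 10 random
    parameter draws, with and without the masked behavior variable."""
    ds = toy_ds_missing if missing else toy_ds
    rng = np.random.default_rng(17)
    for _ in range(10):
        mu = rng.normal(scale=0.5, size=5)
        sw, sb = _random_sigmas(rng)
        fast = loglik_from_sigmas(mu, sw, sb, ds)
        dense = brute_force_loglik(mu, sw, sb, ds)
        assert fast == pytest.approx(dense, abs=1e-8)


def test_loglik_via_transformed_parameters(toy_ds):
    """The packed-parameter entry point agrees with the dense oracle."""
    spec = TwoLevelSpec(tpb_spec(), None)
    x = _start_vector(toy_ds, spec)
    obj = _Objective(toy_ds, spec)
    mu, xw, xb = obj.split(x)
    sw, _ = _level_sigma_and_grad(spec.within, xw, 5)
    sb, _ = _level_sigma_and_grad(spec.between, xb, 5)
    assert twolevel_loglik(x, toy_ds, spec) == pytest.approx(
        brute_force_loglik(mu, sw, sb, toy_ds), abs=1e-8
    )


def test_zero_between_reduces_to_iid_likelihood(toy_ds):
    """With Sigma_B -> 0 the two-level likelihood is the i.i.d. MVN
    log-likelihood of the pooled rows."""
    rng = np.random.default_rng(3)
    mu = rng.normal(scale=0.3, size=5)
    sw, _ = _random_sigmas(rng)
    sb = np.zeros((5, 5))
    rows = np.vstack([s.observations for s in toy_ds.studies])
    iid = float(np.sum(stats.multivariate_normal.logpdf(rows, mean=mu, cov=sw)))
    assert loglik_from_sigmas(mu, sw, sb, toy_ds) == pytest.approx(iid, abs=1e-8)


def test_participant_permutation_invariance(toy_ds):
    rng = np.random.default_rng(5)
    mu = np.zeros(5)
    sw, sb = _random_sigmas(rng)
    base = loglik_from_sigmas(mu, sw, sb, toy_ds)
    from dataclasses import replace

    studies = tuple(
        replace(s, observations=s.observations[rng.permutation(s.n_j)])
        for s in toy_ds.studies
    )
    shuffled = replace(toy_ds, studies=studies)
    assert loglik_from_sigmas(mu, sw, sb, shuffled) == pytest.approx(base, abs=1e-9)


def test_saturated_fit_is_a_local_maximum(toy_ds):
    """The saturated-saturated optimum dominates random parameter
    perturbations under the independent dense likelihood."""
    ll_hat, x_hat, conv = fit_saturated(toy_ds)
    assert conv
    spec = TwoLevelSpec(None, None)
    obj = _Objective(toy_ds, spec)
    mu, xw, xb = obj.split(x_hat)
    sw, _ = _level_sigma_and_grad(None, xw, 5)
    sb, _ = _level_sigma_and_grad(None, xb, 5)
    assert brute_force_loglik(mu, sw, sb, toy_ds) == pytest.approx(ll_hat, abs=1e-6)
    rng = np.random.default_rng(11)
    for _ in range(20):
        x_pert = x_hat + rng.normal(scale=0.05, size=x_hat.size)
        mu2, xw2, xb2 = obj.split(x_pert)
        sw2, _ = _level_sigma_and_grad(None, xw2, 5)
        sb2, _ = _level_sigma_and_grad(None, xb2, 5)
        assert brute_force_loglik(mu2, sw2, sb2, toy_ds) <= ll_hat + 1e-8


@pytest.fixture(scope="module")
def medium_ds():
    cond = ConditionSpec(
        "S2_medium_unequal", k=12, n_min=40, n_max=80, master_seed=21
    )
    return generate_replication(cond, 0)


class TestStructuredFits:
    def test_nesting_and_df(self, medium_ds):
        baseline = fit_saturated(medium_ds)
        ps = fit_partially_saturated(medium_ds, baseline=baseline)
        tl = fit_twolevel(medium_ds, baseline=baseline)
        assert ps.converged and tl.converged
        assert ps.df == 2 and tl.df == 4
        # log-likelihood ordering: saturated >= partially saturated >= two-level
        assert baseline[0] >= ps.loglik - 1e-6
        assert ps.loglik >= tl.loglik - 1e-6
        assert ps.chi2 >= 0 and tl.chi2 >= 0

    def test_ps_and_2l_within_estimates_agree(self, medium_ds):
        """With a correctly specified between model, the within-level paths of
        the partially saturated and the two-level fits coincide closely."""
        baseline = fit_saturated(medium_ds)
        ps = fit_partially_saturated(medium_ds, baseline=baseline)
        tl = fit_twolevel(medium_ds, baseline=baseline)
        diffs = [
            abs(ps.estimates[n] - tl.estimates[n]) for n in tpb_spec().path_names
        ]
        assert max(diffs) < 0.02

    def test_within_estimates_near_population(self):
        """Mean within-level paths over a handful of k=50 replications sit
        near the generating values."""
        cond = ConditionSpec("S3_high_unequal", k=50, master_seed=33)
        truth = {"INT~ATT": 0.43, "INT~SN": 0.16, "INT~PBC": 0.31,
                 "BEH~PBC": 0.53, "BEH~INT": 0.07}
        sums = {n: 0.0 for n in truth}
        reps = 5
        for rep in range(reps):
            ds = generate_replication(cond, rep)
            fit = fit_partially_saturated(ds, compute_se=False)
            assert fit.converged
            for n in truth:
                sums[n] += fit.estimates[n]
        for n, t in truth.items():
            assert sums[n] / reps == pytest.approx(t, abs=0.02)

    def test_missing_data_fits_converge(self):
        cond = ConditionSpec(
            "S2_medium_unequal", k=30, missing=True, master_seed=40
        )
        ds = generate_replication(cond, 0)
        baseline = fit_saturated(ds)
        ps = fit_partially_saturated(ds, baseline=baseline)
        tl = fit_twolevel(ds, baseline=baseline)
        assert ps.converged and tl.converged
        assert ps.estimates["BEH~PBC"] == pytest.approx(0.53, abs=0.15)
        assert tl.estimates["between.BEH~INT"] == pytest.approx(0.91, abs=0.6)
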