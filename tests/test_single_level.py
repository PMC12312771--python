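"""Single-level ML path-model fitting, sandwich corrections, fit measures."""

import numpy as np
import pytest
from scipy import stats

from ipdmasem._oracles import regression_closed_form
from ipdmasem.generate import ConditionSpec, MetaDataset, StudyData, generate_replication
from ipdmasem.scenarios import VARIABLES, get_scenario
from ipdmasem.single_level import (
    PathModelSpec,
    cluster_robust_fit,
    fit_measures,
    fit_path_model_ml,
    naive_pooling_fit,
    tpb_spec,
)

SPEC = tpb_spec()


def _iid_dataset(n_per_study, k, sigma, seed):
    """Independent rows arbitrarily split into 'studies' (no clustering)."""
    rng = np.random.default_rng(seed)
    studies = tuple(
        StudyData(j, rng.multivariate_normal(np.zeros(5), sigma, size=n_per_study),
                  np.ones(5, dtype=bool))
        for j in range(k)
    )
    cond = ConditionSpec("S4_high_equal", k=max(k, 2), n_min=1, n_max=10**6)
    return MetaDataset(studies, condition=cond)


class TestSpec:
    def test_tpb_parameter_count_and_df(self):
        assert len(SPEC.edges) == 5
        assert SPEC.n_params == 13
        assert SPEC.df == 2

    def test_reduced_four_variable_spec(self):
        reduced = SPEC.restrict(("ATT", "SN", "PBC", "INT"))
        assert len(reduced.edges) == 3
        assert reduced.n_params == 10
        assert reduced.df == 0

    def test_cyclic_edges_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModelSpec(("A", "B"), (("A", "B"),))


class TestML:
    def test_population_input_recovers_parameters(self):
        pop = get_scenario("S1_low_unequal")
        fit = fit_path_model_ml(pop.sigma_w, 5000, SPEC)
        assert fit.converged
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.estimates["INT~ATT"] == pytest.approx(0.43, abs=1e-6)
        assert fit.estimates["BEH~PBC"] == pytest.approx(0.53, abs=1e-6)
        assert fit.estimates["BEH~INT"] == pytest.approx(0.07, abs=1e-6)

    def test_matches_regression_closed_forms(self):
        """ML point estimates equal ordered-regression solutions on random
        positive-definite inputs (recursive model, uncorrelated residuals)."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=(5, 8))
            S = a @ a.T / 8 + 0.5 * np.eye(5)
            fit = fit_path_model_ml(S, 500, SPEC)
            oracle = regression_closed_form(S, SPEC)
            for name, val in oracle.items():
                assert fit.estimates[name] == pytest.approx(val, abs=1e-6)

    def test_saturated_spec_fits_perfectly(self):
        sat = PathModelSpec(
            VARIABLES,
            tuple(
                (VARIABLES[i], VARIABLES[j])
                for i in range(5)
                for j in range(i)
            ),
        )
        assert sat.df == 0
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 9))
        fit = fit_path_model_ml(a @ a.T / 9 + np.eye(5), 200, sat)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_chi2_null_distribution(self):
        """(N-1) F_ML on model-true covariances behaves as chi-square(2):
        rejection at alpha=.05 stays in the Monte Carlo binomial band."""
        pop = get_scenario("S1_low_unequal")
        n, reps = 400, 400
        rng = np.random.default_rng(123)
        rejections = 0
        for _ in range(reps):
            S = stats.wishart.rvs(n - 1, pop.sigma_w, random_state=rng) / (n - 1)
            fit = fit_path_model_ml(S, n, SPEC)
            rejections += fit.chi2_p < 0.05
        lo, hi = 2.9, 7.1  # 1.96-sigma binomial band around 5% at 400 reps
        assert lo <= 100 * rejections / reps <= hi

    def test_invalid_input_raises(self):
        with pytest.raises(ValueError):
            fit_path_model_ml(np.eye(5), 3, SPEC)


class TestNaivePooling:
    def test_no_between_variance_recovers_within(self):
        ds = _iid_dataset(400, 25, get_scenario("S1_low_unequal").sigma_w, seed=2)
        fit = naive_pooling_fit(ds)
        assert fit.converged
        assert fit.estimates["INT~ATT"] == pytest.approx(0.43, abs=0.03)
        assert fit.n_effective == 10000

    def test_missing_data_restricts_to_common_variables(self):
        cond = ConditionSpec("S1_low_unequal", k=10, missing=True, master_seed=6)
        ds = generate_replication(cond, 0)
        fit = naive_pooling_fit(ds)
        assert "BEH~PBC" not in fit.estimates and "INT~ATT" in fit.estimates
        with pytest.raises(ValueError, match="unobserved"):
            naive_pooling_fit(ds, on_missing="error")


class TestClusterRobust:
    def test_point_estimates_identical_to_naive_pooling(self):
        cond = ConditionSpec("S3_high_unequal", k=20, master_seed=10)
        ds = generate_replication(cond, 0)
        np_fit = naive_pooling_fit(ds)
        cr_fit = cluster_robust_fit(ds)
        for name in SPEC.param_names:
            assert cr_fit.estimates[name] == pytest.approx(
                np_fit.estimates[name], abs=1e-12
            )

    def test_sandwich_reduces_to_naive_for_iid_singleton_clusters(self):
        """With size-1 clusters and i.i.d. model-true data, the cluster
        sandwich and the information SEs agree and the scaling factor is ~1."""
        ds = _iid_dataset(1, 4000, get_scenario("S1_low_unequal").sigma_w, seed=3)
        np_fit = naive_pooling_fit(ds)
        cr_fit = cluster_robust_fit(ds)
        assert cr_fit.scaling_factor == pytest.approx(1.0, abs=0.1)
        for name in SPEC.path_names:
            assert cr_fit.se[name] == pytest.approx(np_fit.se[name], rel=0.15)

    def test_clustered_data_inflates_robust_se(self):
        cond = ConditionSpec("S3_high_unequal", k=50, master_seed=11)
        ds = generate_replication(cond, 0)
        np_fit = naive_pooling_fit(ds)
        cr_fit = cluster_robust_fit(ds)
        assert cr_fit.se["INT~ATT"] > 3 * np_fit.se["INT~ATT"]

    def test_needs_two_clusters(self):
        ds = _iid_dataset(50, 1, np.eye(5), seed=0)
        with pytest.raises(ValueError, match="2 studies"):
            cluster_robust_fit(ds)


class TestFitMeasures:
    def test_truncation_at_zero(self):
        rmsea, _ = fit_measures(1.5, 2, 1000)
        assert rmsea == 0.0

    def test_close_fit_not_rejected_at_the_null_point(self):
        # chi2 equal to its null expectation: comfortably close fit
        for n in (200, 2000, 20000):
            _, p = fit_measures(2.0, 2, n)
            assert p > 0.5

    def test_df_zero_flagged(self):
        with pytest.raises(ValueError):
            fit_measures(1.0, 0, 100)
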