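"""Two-stage MVMA and one-stage MASEM on study correlations."""

import numpy as np
import pytest

from ipdmasem._oracles import regression_closed_form
from ipdmasem.generate import ConditionSpec, MetaDataset, StudyData, generate_replication
from ipdmasem.meta import (
    StudyCorrelations,
    StudyEffect,
    fit_osmasem,
    fit_per_study,
    mvma_fixed,
    pair_labels,
    study_correlations,
)
from ipdmasem.scenarios import VARIABLES, get_scenario
from ipdmasem.single_level import tpb_spec

PATHS = tpb_spec().path_names


def _one_study_ds(obs, mask=None):
    mask = np.ones(5, dtype=bool) if mask is None else mask
    obs = np.asarray(obs, dtype=float)
    filled = np.full((obs.shape[0], 5), np.nan)
    filled[:, np.flatnonzero(mask)] = obs
    cond = ConditionSpec("S4_high_equal", k=2, n_min=1, n_max=10**6)
    return MetaDataset((StudyData(0, filled, mask),), condition=cond)


class TestStage1:
    def test_large_study_recovers_population_paths(self):
        pop = get_scenario("S1_low_unequal")
        rng = np.random.default_rng(0)
        ds = _one_study_ds(rng.multivariate_normal(np.zeros(5), pop.sigma_w, 100_000))
        (eff,) = fit_per_study(ds)
        assert eff.names == PATHS
        assert np.allclose(eff.beta, [0.43, 0.16, 0.31, 0.53, 0.07], atol=0.01)

    def test_masked_study_contributes_three_paths(self):
        cond = ConditionSpec("S1_low_unequal", k=10, missing=True, master_seed=1)
        ds = generate_replication(cond, 0)
        effects = fit_per_study(ds)
        sizes = sorted(len(e.beta) for e in effects)
        assert sizes == [3] * 5 + [5] * 5
        masked = next(e for e in effects if len(e.beta) == 3)
        assert masked.names == ("INT~ATT", "INT~SN", "INT~PBC")

    def test_sampling_covariance_scales_inversely_with_n(self):
        pop = get_scenario("S1_low_unequal")
        rng = np.random.default_rng(4)
        obs = rng.multivariate_normal(np.zeros(5), pop.sigma_w, 4000)
        v_small = fit_per_study(_one_study_ds(obs[:2000]))[0].V
        v_large = fit_per_study(_one_study_ds(obs))[0].V
        assert np.diag(v_small) / np.diag(v_large) == pytest.approx(
            np.full(5, 2.0), rel=0.05
        )


class TestMVMA:
    def test_identity_weights_give_arithmetic_mean(self):
        e1 = StudyEffect(0, PATHS, np.arange(5.0), np.eye(5))
        e2 = StudyEffect(1, PATHS, np.arange(5.0) + 1.0, np.eye(5))
        res = mvma_fixed([e1, e2])
        assert np.allclose(res.beta, np.arange(5.0) + 0.5)
        assert np.allclose(res.cov, np.eye(5) / 2)

    def test_single_study_passthrough(self):
        v = np.diag([1.0, 2.0, 3.0, 4.0, 5.0])
        e = StudyEffect(0, PATHS, np.ones(5), v)
        res = mvma_fixed([e])
        assert np.allclose(res.beta, 1.0)
        assert np.allclose(res.cov, v)

    def test_order_invariance_and_subset_effects(self):
        rng = np.random.default_rng(2)
        effects = []
        for j in range(6):
            names = PATHS if j % 2 == 0 else PATHS[:3]
            m = len(names)
            a = rng.normal(size=(m, m + 2))
            effects.append(
                StudyEffect(j, names, rng.normal(size=m), a @ a.T / (m + 2) + np.eye(m))
            )
        fwd = mvma_fixed(effects)
        rev = mvma_fixed(effects[::-1])
        assert np.allclose(fwd.beta, rev.beta)
        assert np.allclose(fwd.cov, rev.cov)

    def test_infinite_variance_study_has_no_influence(self):
        rng = np.random.default_rng(3)
        base = [
            StudyEffect(j, PATHS, rng.normal(size=5), np.eye(5)) for j in range(3)
        ]
        noisy = base + [StudyEffect(9, PATHS, rng.normal(size=5) * 50, np.eye(5) * 1e9)]
        assert np.allclose(mvma_fixed(base).beta, mvma_fixed(noisy).beta, atol=1e-5)

    def test_unobserved_effect_rejected(self):
        e = StudyEffect(0, PATHS[:3], np.zeros(3), np.eye(3))
        with pytest.raises(ValueError, match="no study"):
            mvma_fixed([e], names=PATHS)


def test_stage1_effects_csv_round_trip(tmp_path):
    import pandas as pd

    cond = ConditionSpec("S1_low_unequal", k=6, missing=True, n_min=60, n_max=90, master_seed=2)
    effects = fit_per_study(generate_replication(cond, 0))
    from ipdmasem.meta import effects_from_frame, effects_to_frame

    path = tmp_path / "stage1.csv"
    effects_to_frame(effects).to_csv(path, index=False)
    back = effects_from_frame(pd.read_csv(path))
    assert np.allclose(mvma_fixed(back).beta, mvma_fixed(effects).beta)


class TestStudyCorrelations:
    def test_two_variable_classical_variance(self):
        rng = np.random.default_rng(5)
        n = 500
        rho = 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        obs = rng.multivariate_normal([0, 0], cov, n)
        mask = np.array([True, True, False, False, False])
        (sc,) = study_correlations(_one_study_ds(obs, mask))
        r = sc.r[0]
        assert sc.V[0, 0] == pytest.approx((1 - r**2) ** 2 / n, rel=1e-10)

    def test_entry_counts_with_and_without_masking(self):
        cond = ConditionSpec("S2_medium_unequal", k=10, missing=True, master_seed=7)
        ds = generate_replication(cond, 0)
        cors = study_correlations(ds)
        sizes = sorted(len(c.r) for c in cors)
        assert sizes == [6] * 5 + [10] * 5

    def test_vechs_labels_follow_variable_order(self):
        labels = pair_labels(VARIABLES)
        assert len(labels) == 10
        assert labels[0] == "ATT~~SN" and labels[-1] == "INT~~BEH"


class TestOSMASEM:
    def _population_cors(self, k=5, n=400):
        pop = get_scenario("S1_low_unequal")
        sd = np.sqrt(np.diag(pop.sigma_w))
        R = pop.sigma_w / np.outer(sd, sd)
        from ipdmasem._linalg import vech_indices

        r_i, c_i = vech_indices(5, strict=True)
        return R, [
            StudyCorrelations(j, pair_labels(VARIABLES), R[r_i, c_i], np.eye(10) / n, n)
            for j in range(k)
        ]

    def test_population_input_recovers_standardized_paths(self):
        """Feeding the population correlation vector recovers the standardized
        path coefficients with a vanishing discrepancy."""
        R, cors = self._population_cors()
        fit = fit_osmasem(cors)
        assert fit.converged
        assert fit.df == 2
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        oracle = regression_closed_form(R, tpb_spec())
        for name, val in oracle.items():
            assert fit.estimates[name] == pytest.approx(val, abs=1e-5)

    def test_simulated_medium_condition(self):
        cond = ConditionSpec("S2_medium_unequal", k=30, master_seed=19)
        ds = generate_replication(cond, 0)
        fit = fit_osmasem(study_correlations(ds))
        assert fit.converged
        assert fit.estimates["INT~ATT"] == pytest.approx(0.43, abs=0.05)
        assert fit.estimates["BEH~PBC"] == pytest.approx(0.53, abs=0.05)
        assert fit.n_effective == ds.n_total

    def test_needs_two_studies(self):
        _, cors = self._population_cors(k=1)
        with pytest.raises(ValueError, match="2 studies"):
            fit_osmasem(cors)
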