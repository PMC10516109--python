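"""Crossnobis estimation, NNLS decomposition, and predicted error rates."""

import numpy as np
import pandas as pd
import pytest

from bindgeom import geometry_decomposition as gd
from bindgeom import synthetic_data as sd
from bindgeom import theory as T
from bindgeom.geometry_decomposition import RDM
from bindgeom.theory import CodeParams


class TestCrossnobis:
    def test_unbiased_at_zero_distance(self, rng):
        # identical distributions: mean estimate ~ 0, single draws may be < 0
        ests = []
        for seed in range(40):
            r = np.random.default_rng(seed).standard_normal((80, 20))
            labels = ["a"] * 40 + ["b"] * 40
            rdm = gd.crossnobis_rdm(r, labels, n_folds=4, seed=seed)
            ests.append(rdm.pair("a", "b"))
        ests = np.array(ests)
        assert (ests < 0).any()
        assert abs(ests.mean()) < 3 * ests.std() / np.sqrt(len(ests))

    def test_recovers_true_offset(self, rng):
        delta = 1.3
        ests = []
        for seed in range(30):
            r = np.random.default_rng(seed).standard_normal((120, 15))
            r[:60, 0] += delta
            rdm = gd.crossnobis_rdm(r, ["a"] * 60 + ["b"] * 60, n_folds=5, seed=seed)
            ests.append(rdm.pair("a", "b"))
        ests = np.array(ests)
        se = ests.std() / np.sqrt(len(ests))
        assert abs(ests.mean() - delta**2) < 3 * se

    def test_plain_euclidean_is_upward_biased(self, rng):
        # the bias contrast that motivates cross-validated distances
        gaps = []
        for seed in range(20):
            r = np.random.default_rng(seed).standard_normal((60, 25))
            labels = ["a"] * 30 + ["b"] * 30
            naive = np.sum((r[:30].mean(0) - r[30:].mean(0)) ** 2)
            rdm = gd.crossnobis_rdm(r, labels, n_folds=3, seed=seed)
            gaps.append(naive - rdm.pair("a", "b"))
        # expected bias ~ 2 * trace(noise cov) / n_per_condition
        assert np.mean(gaps) > 0
        assert np.mean(gaps) == pytest.approx(2 * 25 / 30, rel=0.5)

    def test_empty_condition_and_fold_errors(self, rng):
        r = rng.standard_normal((20, 4))
        with pytest.raises(ValueError, match="empty condition"):
            gd.crossnobis_rdm(r, ["a"] * 20, conditions=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            gd.crossnobis_rdm(r, ["a"] * 10 + ["b"] * 10, n_folds=6)


class TestDecomposeRDM:
    def test_exact_recovery_of_consistent_system(self):
        conditions = [("low", "left"), ("low", "right"), ("high", "left"), ("high", "right")]
        A = gd._design_rows(conditions)
        d_true = np.array([1.0, 1.0, 0.25])  # dLV2, dLA2, m2
        d_emp = A @ d_true
        mat = np.zeros((4, 4))
        mat[np.triu_indices(4, 1)] = d_emp
        mat = mat + mat.T
        res = gd.decompose_rdm(RDM(conditions, mat))
        assert res.dLV2 == pytest.approx(1.0)
        assert res.dLA2 == pytest.approx(1.0)
        assert res.m2 == pytest.approx(0.25)
        assert res.dN2 == pytest.approx(0.5)
        assert res.residual == pytest.approx(0.0, abs=1e-10)

    def test_design_matrix_shape(self):
        conditions = [("low", "left"), ("low", "right"), ("high", "left"), ("high", "right")]
        A = gd._design_rows(conditions)
        assert A.shape == (6, 3)  # six pairs, three unknowns
        assert (A[:, 2] == 2.0).all()

    def test_nonnegativity_clipping(self):
        conditions = [("low", "left"), ("low", "right"), ("high", "left"), ("high", "right")]
        A = gd._design_rows(conditions)
        d_emp = A @ np.array([1.0, 0.5, 0.0]) - 0.3  # push m2 negative
        mat = np.zeros((4, 4))
        mat[np.triu_indices(4, 1)] = d_emp
        res = gd.decompose_rdm(RDM(conditions, mat + mat.T))
        assert res.m2 >= 0.0

    def test_condition_count_guard(self):
        with pytest.raises(ValueError):
            gd.decompose_rdm(RDM(["a", "b"], np.zeros((2, 2))))


class TestSessionDecomposition:
    def test_parameter_recovery(self, default_params):
        sess = sd.generate_discrete_session(100, default_params, 300, seed=5)
        res = gd.decompose_session(
            sess.rates, sess.labels["condition"], n_boot=50, seed=5
        )
        assert res.dLV == pytest.approx(default_params.dLV, rel=0.1)
        assert res.dLA == pytest.approx(default_params.dLA, rel=0.1)
        assert res.dN == pytest.approx(default_params.dN, rel=0.1)
        assert res.sigma_hat == pytest.approx(default_params.sigma, rel=0.1)
        lo, hi = np.percentile(res.bootstrap["dLV"], [2.5, 97.5])
        assert lo < default_params.dLV < hi + 0.1

    def test_pure_linear_code_clips_nonlinear_part(self):
        p = CodeParams(dLV=1.0, dLA=0.8, dN=0.0, sigma=0.4)
        sess = sd.generate_discrete_session(60, p, 200, seed=6)
        res = gd.decompose_session(sess.rates, sess.labels["condition"], n_boot=0)
        assert res.dN < 0.25

    def test_epsilon_scaling_with_trials(self):
        p = CodeParams(dLV=1.0, dLA=0.8, dN=0.8, sigma=0.5)
        eps = {}
        for n_t in (100, 400):
            sess = sd.generate_discrete_session(80, p, n_t, seed=7)
            _, e = gd.estimate_noise_and_sem(
                sess.rates, sess.labels["condition"],
                train_pair=(("low", "left"), ("high", "left")),
            )
            eps[n_t] = e
        # quadrupling trials halves the standard-error distance
        assert eps[100] / eps[400] == pytest.approx(2.0, rel=0.2)
        # and matches the analytic sigma * sqrt(2N/n)
        assert eps[400] == pytest.approx(0.5 * np.sqrt(2 * 80 / 400), rel=0.15)


class TestPredictedErrorRates:
    def test_linear_code_predicts_chance_binding(self):
        decomp = gd.DecompositionResult(dLV2=1.0, dLA2=0.5, m2=0.0, sigma_hat=0.5)
        pred = gd.predicted_error_rates(decomp)
        assert pred["binding_error"] == pytest.approx(0.125)

    def test_epsilon_increases_generalization_error(self):
        rates = []
        for eps in (0.0, 0.5, 1.0):
            decomp = gd.DecompositionResult(
                dLV2=1.0, dLA2=0.5, m2=0.25, sigma_hat=0.5, epsilon_hat=eps
            )
            rates.append(gd.predicted_error_rates(decomp)["generalization_error"])
        assert rates[0] < rates[1] < rates[2]

    def test_tradeoff_curve_moves_in_opposite_directions(self):
        decomp = gd.DecompositionResult(dLV2=1.0, dLA2=0.5, m2=0.25, sigma_hat=0.4)
        curve = gd.predicted_error_rates(decomp, n_power_steps=11)["tradeoff"]
        b = curve["binding_error"].to_numpy()
        g = curve["generalization_error"].to_numpy()
        assert (np.diff(b) >= -1e-12).all()  # more linear power -> more misbinding
        assert (np.diff(g[1:]) <= 1e-12).all()  # and better generalization
        # total power is conserved along the sweep
        spec_v = T.StimulusSpec(1, 2)
        spec = T.StimulusSpec(2, 2, 2)
        p_tot = [
            T.linear_power_from_distance(r.dLV, spec_v)
            + T.nonlinear_power_from_distance(r.dN, spec)
            for r in curve.itertuples()
        ]
        assert np.allclose(p_tot, p_tot[0])

    def test_requires_noise_estimate(self):
        decomp = gd.DecompositionResult(dLV2=1.0, dLA2=0.5, m2=0.25)
        with pytest.raises(ValueError):
            gd.predicted_error_rates(decomp)


class TestMisbindingContrasts:
    @pytest.fixture(scope="class")
    @staticmethod
    def late_session():
        gen = sd.GenerativeSession(
            task=sd.TaskConfig(n_trials=2500, seed=31), n_neurons=50, seed=31
        )
        return sd.generate_population_session(gen).window("late")

    def test_all_contrasts_positive_with_both_conjunctions(self, late_session):
        tab = gd.misbinding_distance_contrasts(
            late_session.rates, late_session.labels["condition8"], n_boot=80, seed=0
        )
        tab = tab.set_index("contrast")
        for name in ("temporal", "spatial", "spatiotemporal"):
            assert tab.loc[name, "p_vs_zero"] < 0.05
            assert tab.loc[name, "distance2"] > 0
        # same-value order pairs coincide by construction
        assert tab.loc["low-low", "p_vs_zero"] > 0.05

    def test_spatial_only_conjunction(self):
        gen = sd.GenerativeSession(
            task=sd.TaskConfig(n_trials=2500, seed=33),
            n_neurons=50,
            dN_time=0.0,
            seed=33,
        )
        late = sd.generate_population_session(gen).window("late")
        tab = gd.misbinding_distance_contrasts(
            late.rates, late.labels["condition8"], n_boot=80, seed=0
        ).set_index("contrast")
        assert tab.loc["spatial", "p_vs_zero"] < 0.05
        assert tab.loc["temporal", "p_vs_zero"] > 0.05
        assert abs(tab.loc["temporal", "distance2"]) < 0.2

    def test_missing_condition_raises(self, late_session):
        labels = [("low", "low", "LR")] * len(late_session.labels)
        with pytest.raises(ValueError, match="missing"):
            gd.misbinding_distance_contrasts(late_session.rates, labels)
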