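"""Least-squares ARX identification, quality metrics, and excitation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gammaloop as gl
from gammaloop.errors import (
    InsufficientDataError,
    InvalidInputError,
    NonUniqueSolutionError,
    UnstableCompositeError,
)
from gammaloop.sysid import DesignSystem, evaluate_fit

REF_RECURSION = np.array([5.6758, -13.6152, 17.6747, -13.0990, 5.2554, -0.8917])


def reference_realization(seed, n=2000):
    model = gl.reference_arx_model()
    stim = gl.step_stimulus(n)
    return gl.simulate_arx(model, 1.0, stim, seed=seed), stim


class TestDesignSystem:
    def test_direct_transcription_p1(self):
        des = gl.build_design_system(np.array([1.0, 2, 3, 4]), 1, 1.0,
                                     np.zeros(4))
        assert np.allclose(des.C, [[1, 1, 0], [2, 1, 0], [3, 1, 0]])
        assert np.allclose(des.d, [2, 3, 4])

    def test_shapes(self, step2000):
        x = np.arange(2000.0)
        des = gl.build_design_system(x, 6, 1.0, step2000)
        assert des.C.shape == (1994, 8)
        assert des.d.shape == (1994,)

    def test_step_column(self, step2000):
        x = np.arange(2000.0)
        des = gl.build_design_system(x, 6, 1.0, step2000)
        u_col = des.C[:, 7]
        # row t targets x(t), t = 6..1999; step turns on at index 1000
        assert np.all(u_col[: 1000 - 6] == 0.0)
        assert np.all(u_col[1000 - 6:] == 2.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            gl.build_design_system(np.ones(5), 3, 1.0, np.zeros(5))


class TestFit:
    def test_noise_free_exact_recovery(self):
        truth = gl.ARXModel(a=(-1.2, 0.4), b_dc=2.0, b_s=0.5,
                            noise_variance=0.0)
        stim = gl.step_stimulus(400)
        s = gl.simulate_arx(truth, 1.0, stim, seed=0)
        rep = gl.fit_arx(gl.build_design_system(s, 2, 1.0, stim))
        assert np.allclose(rep.model.a, truth.a, rtol=1e-8)
        assert rep.model.b_dc == pytest.approx(2.0, rel=1e-8)
        assert rep.model.b_s == pytest.approx(0.5, rel=1e-8)
        assert rep.eps_pred <= 1e-20

    def test_reference_single_run_metrics(self, step2000):
        s, stim = reference_realization(seed=3)
        rep = gl.fit_arx(gl.build_design_system(s, 6, 1.0, stim))
        a_hat = -np.asarray(rep.model.a)
        a_err = np.sum((a_hat - REF_RECURSION) ** 2) / np.sum(REF_RECURSION**2)
        assert a_err < 1e-4
        assert rep.fit_perc > 99.99

    def test_collinear_exogenous_columns_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        with pytest.raises(NonUniqueSolutionError, match="u_"):
            gl.fit_arx(gl.build_design_system(x, 2, 1.0, np.ones(200)))

    def test_matches_normal_equations(self):
        """Orthogonal-decomposition solution equals (C^T C)^{-1} C^T d on a
        well-conditioned system."""
        truth = gl.ARXModel(a=(-0.7, 0.2), b_dc=1.0, b_s=0.3,
                            noise_variance=0.01)
        stim = gl.step_stimulus(500)
        s = gl.simulate_arx(truth, 1.0, stim, seed=1)
        des = gl.build_design_system(s, 2, 1.0, stim)
        rep = gl.fit_arx(des)
        v_ne = np.linalg.solve(des.C.T @ des.C, des.C.T @ des.d)
        v_qr = np.concatenate([-np.asarray(rep.model.a),
                               [rep.model.b_dc, rep.model.b_s]])
        assert np.allclose(v_qr, v_ne, rtol=1e-8)


class TestOrderSweep:
    def test_reference_levels_off_at_six(self, step2000):
        s, stim = reference_realization(seed=1)
        table = gl.order_sweep(s, range(1, 13), 1.0, stim)
        eps = table.set_index("p")["eps_pred"]
        assert np.all(np.diff(eps.values) <= 1e-12)  # monotone non-increasing
        assert eps[5] / eps[6] > 2.0       # still improving at p=6
        assert eps[6] / eps[12] < 1.05     # flat beyond p=6

    def test_ma_process_flat_beyond_three(self):
        ma = gl.make_ma_process(seed=7, n_samples=2000)
        stim = gl.step_stimulus(2000)
        table = gl.order_sweep(ma, range(1, 13), 1.0, stim)
        eps = table.set_index("p")["eps_pred"]
        assert (eps[3] - eps[12]) / eps[3] < 0.05

    def test_white_noise_unpredictable(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        table = gl.order_sweep(x, [1, 4, 8], 1.0, gl.step_stimulus(2000))
        assert np.all(np.abs(table["fit_perc"]) < 10.0)


class TestCrossValidation:
    def test_reference_trials_no_overtraining(self, reference_trials,
                                              step2000):
        _, X = reference_trials
        train, test = gl.kfold_cv(X, 6, 1.0, step2000)
        assert abs(train - test) < 0.01

    def test_identical_trials_equal_metrics(self, step2000):
        s, stim = reference_realization(seed=5)
        X = np.vstack([s.values, s.values])
        train, test = gl.kfold_cv(X, 6, 1.0, stim)
        assert test == pytest.approx(train, abs=1e-9)

    def test_plant_mismatch_degrades_test_score(self):
        stim = gl.step_stimulus(2000)
        a = gl.simulate_arx(gl.demo_plant(noise_variance=1e-4), 1.0, stim,
                            seed=0)
        other = gl.ARXModel(a=(-0.2, 0.05), b_dc=3.4689e-4, b_s=8.7828e-5,
                            noise_variance=1e-4)
        b = gl.simulate_arx(other, 1.0, stim, seed=1)
        X = np.vstack([a.values, a.values, b.values])
        train, test = gl.kfold_cv(X, 6, 1.0, stim)
        assert test < train

    def test_single_trial_rejected(self, step2000):
        with pytest.raises(InvalidInputError):
            gl.kfold_cv(np.ones((1, 2000)), 6, 1.0, step2000)


class TestAverageModels:
    def test_identical_models_unchanged(self, demo):
        assert gl.average_models([demo, demo]) == demo

    def test_elementwise_mean(self):
        m1 = gl.ARXModel(a=(-0.2,), b_dc=1.0, b_s=0.2, noise_variance=0.1)
        m2 = gl.ARXModel(a=(-0.4,), b_dc=3.0, b_s=0.4, noise_variance=0.3)
        avg = gl.average_models([m1, m2])
        assert avg.a[0] == pytest.approx(-0.3)
        assert avg.b_dc == 2.0
        assert avg.b_s == pytest.approx(0.3)
        assert avg.noise_variance == pytest.approx(0.2)

    def test_unstable_composite_raises(self):
        """Coefficient averaging can destabilize for order >= 3 (the AR
        stability region is non-convex there)."""
        a1 = (1.62791227, 0.66053108, 0.02041796)
        a2 = (-2.63338926, 2.30533898, -0.67071364)
        m1 = gl.ARXModel(a=a1, b_dc=1.0, b_s=0.1, noise_variance=0.0)
        m2 = gl.ARXModel(a=a2, b_dc=1.0, b_s=0.1, noise_variance=0.0)
        assert m1.is_stable and m2.is_stable
        with pytest.raises(UnstableCompositeError):
            gl.average_models([m1, m2])

    def test_mixed_orders_rejected(self, demo):
        m1 = gl.ARXModel(a=(-0.2,), b_dc=1.0, b_s=0.2, noise_variance=0.1)
        with pytest.raises(InvalidInputError):
            gl.average_models([demo, m1])


class TestExcitation:
    def test_step_limit_order_one(self, step2000):
        diag = gl.excitation_diagnostics(1.0, step2000, q=1, n=2000)
        assert np.allclose(diag.limit_matrix, [[1, 1], [1, 2]])
        assert diag.consistent
        assert np.linalg.det(diag.limit_matrix) == pytest.approx(1.0)

    def test_step_limit_order_two_singular(self, step2000):
        diag = gl.excitation_diagnostics(1.0, step2000, q=2, n=2000)
        assert np.allclose(diag.limit_matrix,
                           [[1, 1, 1], [1, 2, 2], [1, 2, 2]])
        assert not diag.consistent
        assert abs(np.linalg.det(diag.limit_matrix)) < 1e-12

    def test_finite_matrix_converges_to_limit(self):
        for n in (200, 2000, 20000):
            stim = gl.step_stimulus(n)
            diag = gl.excitation_diagnostics(1.0, stim, q=1, n=n)
            assert np.max(np.abs(diag.finite_matrix - diag.limit_matrix)) < 20.0 / n


class TestStatisticalProperties:
    def test_estimator_consistency_in_n(self):
        """Normalized a-error decreases with record length (median over
        20 seeds at N in {500, 2000, 8000})."""
        model = gl.reference_arx_model()
        medians = []
        for n in (500, 2000, 8000):
            stim = gl.step_stimulus(n)
            errs = []
            for seed in range(20):
                s = gl.simulate_arx(model, 1.0, stim, seed=seed)
                rep = gl.fit_arx(gl.build_design_system(s, 6, 1.0, stim))
                a_hat = -np.asarray(rep.model.a)
                errs.append(np.sum((a_hat - REF_RECURSION) ** 2)
                            / np.sum(REF_RECURSION**2))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_eps_pred_converges_to_noise_variance(self):
        model = gl.reference_arx_model()
        stim = gl.step_stimulus(8000)
        eps = []
        for seed in range(10):
            s = gl.simulate_arx(model, 1.0, stim, seed=seed)
            eps.append(gl.fit_arx(gl.build_design_system(s, 6, 1.0, stim)).eps_pred)
        assert np.median(eps) == pytest.approx(model.noise_variance, rel=0.15)


@given(st.floats(min_value=0.1, max_value=1000.0))
def test_fit_perc_scale_invariant(scale):
    """Fit percentage is unchanged by a common rescaling of the data and
    input gains (the record and the b/sigma parameters all scale together)."""
    truth = gl.ARXModel(a=(-0.7, 0.2), b_dc=1.0, b_s=0.3, noise_variance=0.01)
    stim = gl.step_stimulus(400)
    s = gl.simulate_arx(truth, 1.0, stim, seed=2)
    base = gl.fit_arx(gl.build_design_system(s, 2, 1.0, stim))
    scaled = gl.fit_arx(gl.build_design_system(scale * s.values, 2, 1.0, stim))
    assert scaled.fit_perc == pytest.approx(base.fit_perc, abs=1e-6)
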