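"""Design building, probit likelihood, group-LASSO fitting, kernels,
prediction and stochastic simulation of the encoding model."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from hippomimo import (
    GLVMCoefficients,
    MIMOConfig,
    build_design,
    cross_validate_lambda,
    fit_mimo,
    fit_miso_glvm,
    glvm_neg_log_likelihood,
    laguerre_basis,
    predict_intensity,
    project_kernels,
    reconstruct_kernels,
    simulate_output,
)
from hippomimo.glvm import default_lambda_grid, lambda_max
from hippomimo.spike_data import ConcatenatedSession

from conftest import make_toy_session


def _blank_session(n_inputs, n_segments, segment_bins, inputs=None, outputs=None):
    T = n_segments * segment_bins
    return ConcatenatedSession(
        inputs=np.zeros((n_inputs, T), np.int8) if inputs is None else inputs,
        outputs=np.zeros((1, T), np.int8) if outputs is None else outputs,
        segment_bounds=[i * segment_bins for i in range(n_segments)],
        input_ids=[f"in{i}" for i in range(n_inputs)],
        output_ids=["out0"],
    )


@pytest.fixture(scope="module")
def small_bases():
    return laguerre_basis(0.9, 2, 100), laguerre_basis(0.9, 2, 100)


class TestDesign:
    def test_zero_input_gives_zero_features(self, small_bases):
        ff, fb = small_bases
        sess = _blank_session(2, 3, 300)
        d = build_design(sess, ff, fb, 0)
        # everything except the intercept column is zero
        assert np.abs(d.X[:, 1:]).max() == 0

    def test_unit_impulse_reproduces_basis(self, small_bases):
        ff, fb = small_bases
        sess = _blank_session(1, 2, 300)
        sess.inputs[0, 310] = 1  # local time 10 in segment 2
        d = build_design(sess, ff, fb, 0)
        v0 = d.X[:, 1]  # first-order feature of basis 0
        np.testing.assert_allclose(v0[310:401], ff.values[0, :91], atol=1e-9)
        assert np.abs(v0[:310]).max() < 1e-12  # no leakage across the boundary

    def test_second_order_columns_are_products(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=4)
        d = build_design(sess, ff, fb, 0)
        g1 = next(g for g in d.groups if g.kind == "first_order")
        g2 = next(g for g in d.groups if g.kind == "second_order")
        v = d.X[:, g1.sl]
        prods = np.column_stack([v[:, 0] * v[:, 0], v[:, 1] * v[:, 0], v[:, 1] * v[:, 1]])
        np.testing.assert_allclose(d.X[:, g2.sl], prods, atol=1e-10)

    def test_memory_longer_than_segment_rejected(self):
        ff = laguerre_basis(0.9, 2, 500)
        fb = laguerre_basis(0.9, 2, 100)
        sess = _blank_session(1, 3, 300)
        with pytest.raises(ValueError, match="memory"):
            build_design(sess, ff, fb, 0)


class TestLikelihood:
    def test_zero_coefficients_closed_form(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=5)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        nll = glvm_neg_log_likelihood(np.zeros(d.n_columns), d, y, return_grad=False)
        assert nll == pytest.approx(len(y) * np.log(2), rel=1e-12)

    def test_gradient_matches_finite_differences(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(n_segments=2, segment_bins=200, seed=6)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        rng = np.random.default_rng(0)
        c = rng.normal(0, 0.1, d.n_columns)
        _, g = glvm_neg_log_likelihood(c, d, y)
        eps = 1e-6
        for j in rng.choice(d.n_columns, 6, replace=False):
            cp, cm = c.copy(), c.copy()
            cp[j] += eps
            cm[j] -= eps
            fd = (
                glvm_neg_log_likelihood(cp, d, y, return_grad=False)
                - glvm_neg_log_likelihood(cm, d, y, return_grad=False)
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_duplicating_data_doubles_nll(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(n_segments=2, segment_bins=200, seed=7)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        c = np.full(d.n_columns, 0.05)
        nll1 = glvm_neg_log_likelihood(c, d, y, return_grad=False)
        d.X = np.vstack([d.X, d.X])
        y2 = np.concatenate([y, y])
        nll2 = glvm_neg_log_likelihood(c, d, y2, return_grad=False)
        assert nll2 == pytest.approx(2 * nll1, rel=1e-12)

    def test_non_binary_output_rejected(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=8)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        y[0] = 0.5
        with pytest.raises(ValueError, match="binary"):
            glvm_neg_log_likelihood(np.zeros(d.n_columns), d, y)


class TestFit:
    def test_lambda_max_zeroes_every_penalized_group(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=9)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        co = fit_miso_glvm(d, y, lambda_max(d, y) * (1 + 1e-9))
        assert len(co.zero_groups()) == 2 * sess.inputs.shape[0]

    def test_unpenalized_fit_matches_generic_optimizer(self, small_bases):
        """lambda = 0 must agree with an independent probit MLE on a
        200-bin toy problem."""
        ff = laguerre_basis(0.9, 2, 50)
        fb = laguerre_basis(0.9, 2, 50)
        sess, *_ = make_toy_session(
            n_inputs=1, n_segments=2, segment_bins=100, rate_per_bin=0.15, seed=10,
            config=MIMOConfig(J=2, L=2, alpha_ff=0.9, alpha_fb=0.9,
                              memory_ff_bins=50, memory_fb_bins=50),
        )
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        co = fit_miso_glvm(d, y, 0.0, tol=1e-12, max_iter=500)
        res = minimize(
            lambda c: glvm_neg_log_likelihood(c, d, y, return_grad=False),
            np.zeros(d.n_columns),
            jac=lambda c: glvm_neg_log_likelihood(c, d, y)[1],
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        np.testing.assert_allclose(co.to_vector(), res.x, atol=1e-4)

    def test_objective_decreases_and_matches_nll_at_zero_lambda(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=11)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        co = fit_miso_glvm(d, y, 0.0)
        nll = glvm_neg_log_likelihood(co, d, y, return_grad=False)
        assert co.diagnostics["objective"] == pytest.approx(nll, rel=1e-10)
        assert co.diagnostics["objective"] <= len(y) * np.log(2)  # below null model

    def test_sparsity_path_endpoints(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=12)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        hi = fit_miso_glvm(d, y, lambda_max(d, y) * 1.01)
        lo = fit_miso_glvm(d, y, 0.0)
        assert len(hi.zero_groups()) == 2 * sess.inputs.shape[0]
        assert len(lo.zero_groups()) == 0  # generic data: all groups active


class TestCrossValidation:
    def test_singleton_grid_returned(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=13)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        lam, cv = cross_validate_lambda(d, y, lambda_grid=[0.37])
        assert lam == 0.37 and len(cv.lambda_grid) == 1

    def test_chosen_lambda_minimizes_curve(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=14)
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        lam, cv = cross_validate_lambda(d, y, lambda_grid=[0.01, 0.1, 1.0, 10.0])
        idx = int(np.flatnonzero(cv.lambda_grid == lam)[0])
        assert cv.mean_nll[idx] == cv.mean_nll.min()

    def test_cv_curve_u_shaped_on_sparse_truth(self):
        """Held-out NLL at the grid extremes exceeds the minimum when the
        truth is sparse: too much penalty kills real structure, too
        little overfits."""
        c1 = np.zeros((2, 2))
        c1[0] = [1.3, -0.6]
        truth = GLVMCoefficients(
            c0=-1.6, c1=c1, c2s=np.zeros((2, 3)), ch=np.array([-1.0, 0.3])
        )
        sess, _, cfg, ff, fb = make_toy_session(
            n_inputs=2, n_segments=10, segment_bins=400, seed=15, truth=truth
        )
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        _, cv = cross_validate_lambda(d, y)
        assert cv.mean_nll[0] > cv.mean_nll.min()
        assert cv.mean_nll[-1] > cv.mean_nll.min()

    def test_too_few_segments(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(n_segments=1, seed=16)
        d = build_design(sess, ff, fb, 0)
        with pytest.raises(ValueError, match="folds"):
            cross_validate_lambda(d, sess.outputs[0].astype(float), n_folds=2)


class TestKernels:
    def test_zero_coefficients_zero_kernels(self, small_bases):
        ff, fb = small_bases
        co = GLVMCoefficients(0.0, np.zeros((2, 2)), np.zeros((2, 3)), np.zeros(2))
        k = reconstruct_kernels(co, ff, fb)
        assert np.abs(k.k1).max() == 0 and np.abs(k.k2s).max() == 0 and np.abs(k.h).max() == 0

    def test_unit_coefficient_reproduces_basis_row(self, small_bases):
        ff, fb = small_bases
        c1 = np.zeros((1, 2))
        c1[0, 1] = 1.0
        co = GLVMCoefficients(0.0, c1, np.zeros((1, 3)), np.zeros(2))
        k = reconstruct_kernels(co, ff, fb)
        np.testing.assert_allclose(k.k1[0], ff.values[1], atol=1e-12)

    def test_round_trip_recovers_coefficients(self, small_bases):
        ff, fb = small_bases
        rng = np.random.default_rng(17)
        co = GLVMCoefficients(
            c0=0.3,
            c1=rng.normal(size=(2, 2)),
            c2s=rng.normal(size=(2, 3)),
            ch=rng.normal(size=2),
        )
        k = reconstruct_kernels(co, ff, fb)
        back = project_kernels(k, ff, fb)
        np.testing.assert_allclose(back.c1, co.c1, atol=1e-8)
        np.testing.assert_allclose(back.c2s, co.c2s, atol=1e-8)
        np.testing.assert_allclose(back.ch, co.ch, atol=1e-8)

    def test_second_order_kernel_symmetric(self, small_bases):
        ff, fb = small_bases
        rng = np.random.default_rng(18)
        co = GLVMCoefficients(0.0, np.zeros((1, 2)), rng.normal(size=(1, 3)), np.zeros(2))
        k = reconstruct_kernels(co, ff, fb)
        np.testing.assert_allclose(k.k2s[0], k.k2s[0].T, atol=1e-14)


class TestPredict:
    def test_zero_coefficients_half_probability(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=19)
        co = GLVMCoefficients(0.0, np.zeros((2, 2)), np.zeros((2, 3)), np.zeros(2))
        tr = predict_intensity(co, sess, ff, fb)
        assert np.abs(tr.p - 0.5).max() < 1e-14

    def test_intercept_only_matches_normal_cdf(self, small_bases):
        ff, fb = small_bases
        sess, *_ = make_toy_session(seed=20)
        co = GLVMCoefficients(-5.0, np.zeros((2, 2)), np.zeros((2, 3)), np.zeros(2))
        tr = predict_intensity(co, sess, ff, fb)
        assert tr.p[0] == pytest.approx(ndtr(-5.0), rel=1e-12)
        assert tr.p[0] == pytest.approx(2.87e-7, rel=1e-2)

    def test_matches_brute_force_kernel_sums(self, small_bases):
        """u(t) computed feature-wise must match the direct double sum
        over kernel lags for a sparse single-input train."""
        ff, fb = small_bases
        sess = _blank_session(1, 1, 400)
        spike_times = [50, 60, 200]
        sess.inputs[0, spike_times] = 1
        rng = np.random.default_rng(21)
        co = GLVMCoefficients(
            -1.0, rng.normal(size=(1, 2)), rng.normal(size=(1, 3)), np.zeros(2)
        )
        tr = predict_intensity(co, sess, ff, fb)
        k = reconstruct_kernels(co, ff, fb)
        Mk = ff.memory_bins
        x = sess.inputs[0]
        u_brute = np.full(400, k.k0)
        for t in range(400):
            for tau in range(0, min(t, Mk) + 1):
                u_brute[t] += k.k1[0, tau] * x[t - tau]
            for t1 in range(0, min(t, Mk) + 1):
                if not x[t - t1]:
                    continue
                for t2 in range(0, min(t, Mk) + 1):
                    if x[t - t2]:
                        u_brute[t] += k.k2s[0, t1, t2]
        np.testing.assert_allclose(tr.u, u_brute, atol=1e-10)

    def test_teacher_forced_feedback_changes_probability(self, small_bases):
        ff, fb = small_bases
        sess, truth, *_ = make_toy_session(seed=22)
        tr_free = predict_intensity(truth, sess, ff, fb)
        tr_tf = predict_intensity(truth, sess, ff, fb, observed_output=sess.outputs[0])
        assert np.abs(tr_tf.a).max() > 0
        assert not np.allclose(tr_free.p, tr_tf.p)


class TestSimulate:
    def test_degenerate_low_probability_gives_empty_trains(self, small_bases):
        ff, fb = small_bases
        sess = _blank_session(1, 2, 300)
        co = GLVMCoefficients(-9.0, np.zeros((1, 2)), np.zeros((1, 3)), np.zeros(2))
        Y, _ = simulate_output(co, sess, ff, fb, n_realizations=20, seed=0)
        assert Y.sum() == 0

    def test_rate_matches_constant_probability(self, small_bases):
        """With no feedback and constant p = 0.2 the empirical rate over
        1000 realizations stays within 3 binomial standard errors."""
        ff, fb = small_bases
        T = 500
        sess = _blank_session(1, 1, T)
        co = GLVMCoefficients(float(ndtri(0.2)), np.zeros((1, 2)), np.zeros((1, 3)),
                              np.zeros(2))
        Y, mean_p = simulate_output(co, sess, ff, fb, n_realizations=1000, seed=1)
        se = np.sqrt(0.2 * 0.8 / (1000 * T))
        assert abs(Y.mean() - 0.2) < 3 * se
        assert np.abs(mean_p - 0.2).max() < 1e-12

    def test_refractory_feedback_suppresses_short_isis(self, small_bases):
        ff, fb = small_bases
        T = 4000
        sess = _blank_session(1, 1, T)
        base = float(ndtri(0.2))
        no_fb = GLVMCoefficients(base, np.zeros((1, 2)), np.zeros((1, 3)), np.zeros(2))
        refr = GLVMCoefficients(base, np.zeros((1, 2)), np.zeros((1, 3)),
                                np.array([-8.0, 4.0]))

        def isi_frac_one(co):
            Y, _ = simulate_output(co, sess, ff, fb, n_realizations=30, seed=2)
            isis = np.concatenate([np.diff(np.flatnonzero(row)) for row in Y])
            return np.mean(isis == 1)

        assert isi_frac_one(refr) < 0.5 * isi_frac_one(no_fb)

    def test_seeded_reproducibility(self, small_bases):
        ff, fb = small_bases
        sess, truth, *_ = make_toy_session(seed=23)
        Y1, P1 = simulate_output(truth, sess, ff, fb, 3, seed=9)
        Y2, P2 = simulate_output(truth, sess, ff, fb, 3, seed=9)
        np.testing.assert_array_equal(Y1, Y2)
        np.testing.assert_array_equal(P1, P2)


class TestMIMO:
    def test_single_output_wraps_miso_fit(self):
        sess, truth, cfg, ff, fb = make_toy_session(seed=24)
        cfg.n_lambda = 4
        cfg.adaptive = False
        model = fit_mimo(sess, cfg)
        assert model.n_outputs == 1
        d = build_design(sess, ff, fb, 0)
        y = sess.outputs[0].astype(float)
        direct = fit_miso_glvm(d, y, model.fits[0].lam, tol=cfg.tol,
                               max_iter=cfg.max_iter)
        np.testing.assert_allclose(
            model.fits[0].coeffs.to_vector(), direct.to_vector(), atol=1e-6
        )

    def test_serialization_round_trip(self, tmp_path):
        from hippomimo import load_mimo_model, save_mimo_model

        sess, truth, cfg, ff, fb = make_toy_session(seed=25)
        cfg.n_lambda = 3
        model = fit_mimo(sess, cfg)
        save_mimo_model(model, tmp_path / "m.json")
        back = load_mimo_model(tmp_path / "m.json")
        np.testing.assert_allclose(
            back.fits[0].coeffs.to_vector(), model.fits[0].coeffs.to_vector()
        )
        np.testing.assert_allclose(back.ff_basis.values, model.ff_basis.values)

    def test_no_outputs_rejected(self):
        sess, *_ = make_toy_session(seed=26)
        sess.outputs = np.zeros((0, sess.n_bins), np.int8)
        with pytest.raises(ValueError, match="output"):
            fit_mimo(sess)
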