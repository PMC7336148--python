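"""Minimum-norm family: kernel construction, the three solvers, oracles.

The wMNE kernel is checked against a generic quadratic-minimizer oracle
(scipy optimization of the Tikhonov functional), dSPM and sLORETA against
per-source brute-force evaluation of their normalization formulas, and
sLORETA against its defining zero-localization-error property on noiseless
point sources.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from dmsi.forward import GainMatrix
from dmsi.inverse_linear import (
    DSPMSolver,
    MNESolver,
    SLORETASolver,
    build_wmne_kernel,
    compute_depth_weights,
    solve_dspm,
    solve_mne,
    solve_sloreta,
)
from dmsi.preprocess import NoiseCovariance

from conftest import identity_cov, make_study


def random_system(rng, n_ch=5, n_src=8):
    G = GainMatrix(rng.standard_normal((n_ch, n_src)), [f"C{i}" for i in range(n_ch)])
    A = rng.standard_normal((n_ch, n_ch))
    C = NoiseCovariance(A @ A.T + n_ch * np.eye(n_ch))
    return G, C


class TestDepthWeights:
    def test_norm_ratio_rule(self):
        """Columns with norms 1 and 2 get weights in ratio 2:1 at exponent 0.5."""
        G = GainMatrix(np.array([[1.0, 0.0], [0.0, 2.0]]), ["A", "B"])
        w = compute_depth_weights(G, depth_exponent=0.5, clip_percentile=100)
        assert w[0] / w[1] == pytest.approx(2.0)
        assert w.mean() == pytest.approx(1.0)

    def test_exponent_zero_disables_weighting(self, rng):
        G, _ = random_system(rng)
        w = compute_depth_weights(G, depth_exponent=0.0)
        np.testing.assert_allclose(w, 1.0)


class TestWMNE:
    def test_scalar_case(self):
        """g=2, R=1, C=1, lambda=1 -> estimate 0.4 m (rg/(g^2 r + lambda c))."""
        G = GainMatrix(np.array([[2.0]]), ["A"])
        C = identity_cov(1)
        # lambda = trace(GRG')/(trace(C) snr^2) = 4/snr^2 -> snr=2 gives lambda=1
        kernel = build_wmne_kernel(G, C, depth_exponent=0.5, snr=2.0)
        assert kernel.regularization_lambda == pytest.approx(1.0)
        study = make_study([3.0])
        out = solve_mne(kernel, study)
        assert out.amplitudes[0] == pytest.approx(0.4 * 3.0)

    def test_matches_quadratic_minimizer_oracle(self, rng):
        """W m equals the argmin of the whitened Tikhonov functional."""
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C, depth_exponent=0.5, snr=3.0)
        m = rng.standard_normal(5)
        lam, R = kernel.regularization_lambda, kernel.depth_weights
        Cinv = np.linalg.inv(C.values)

        def objective(J):
            r = m - G.values @ J
            return r @ Cinv @ r + lam * np.sum(J**2 / R)

        res = minimize(objective, np.zeros(8), method="BFGS", tol=1e-14)
        direct = kernel.kernel @ m
        np.testing.assert_allclose(direct, res.x, atol=1e-6)

    def test_zero_data_gives_zero_map(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        out = solve_mne(kernel, make_study(np.zeros(5)))
        assert np.all(out.amplitudes == 0)

    def test_scaling_data_scales_map(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        m = rng.standard_normal(5)
        a = solve_mne(kernel, make_study(m)).amplitudes
        b = solve_mne(kernel, make_study(-2.5 * m)).amplitudes
        np.testing.assert_allclose(b, 2.5 * a, atol=1e-12)

    def test_depth_weighting_changes_map_unless_equal_norms(self, rng):
        G, C = random_system(rng)
        m = rng.standard_normal(5)
        k0 = build_wmne_kernel(G, C, depth_exponent=0.0)
        k5 = build_wmne_kernel(G, C, depth_exponent=0.5)
        assert not np.allclose(
            solve_mne(k0, make_study(m)).amplitudes,
            solve_mne(k5, make_study(m)).amplitudes,
        )
        # equal-norm columns: weighting has no effect
        Geq = GainMatrix(
            G.values / np.linalg.norm(G.values, axis=0, keepdims=True), G.channel_names
        )
        k0 = build_wmne_kernel(Geq, C, depth_exponent=0.0)
        k5 = build_wmne_kernel(Geq, C, depth_exponent=0.5)
        np.testing.assert_allclose(
            solve_mne(k0, make_study(m)).amplitudes,
            solve_mne(k5, make_study(m)).amplitudes,
            atol=1e-12,
        )

    def test_invariant_to_matched_gain_and_data_rescale(self, rng):
        G, C = random_system(rng)
        m = rng.standard_normal(5)
        s = 37.5
        a = solve_mne(build_wmne_kernel(G, C), make_study(m)).amplitudes
        Gs = GainMatrix(s * G.values, G.channel_names)
        b = solve_mne(build_wmne_kernel(Gs, C), make_study(s * m)).amplitudes
        np.testing.assert_allclose(a, b, rtol=1e-10)


class TestDSPM:
    def test_identity_cov_unit_rows_equal_mne(self, rng):
        G, _ = random_system(rng)
        C = identity_cov(5)
        kernel = build_wmne_kernel(G, C)
        W = kernel.kernel / np.linalg.norm(kernel.kernel, axis=1, keepdims=True)
        kernel.kernel = W  # unit-norm rows: denominator is exactly 1
        m = rng.standard_normal(5)
        study = make_study(m)
        np.testing.assert_allclose(
            solve_dspm(kernel, C, study).amplitudes,
            solve_mne(kernel, study).amplitudes,
            atol=1e-12,
        )

    def test_matches_direct_formula_oracle(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        m = rng.standard_normal(5)
        out = solve_dspm(kernel, C, make_study(m)).amplitudes
        oracle = np.array(
            [
                abs(w @ m) / np.sqrt(w @ C.values @ w)
                for w in kernel.kernel
            ]
        )
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_scaling_data_scales_map(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        m = rng.standard_normal(5)
        a = solve_dspm(kernel, C, make_study(m)).amplitudes
        b = solve_dspm(kernel, C, make_study(3.0 * m)).amplitudes
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-12)


class TestSLORETA:
    def test_matches_dense_matrix_oracle(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        m = rng.standard_normal(5)
        out = solve_sloreta(kernel, G, make_study(m)).amplitudes
        S = kernel.kernel @ G.values @ np.diag(kernel.depth_weights)
        oracle = np.abs(kernel.kernel @ m) / np.sqrt(np.diag(S))
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_zero_localization_error_noiseless(self, mesh500, small_sensors):
        """Noiseless point sources are localized exactly (non-radial subset)."""
        from dmsi.forward import spherical_meg_gain

        G = spherical_meg_gain(mesh500, small_sensors)
        C = identity_cov(len(small_sensors), scale=1e-30)  # effectively noiseless
        kernel = build_wmne_kernel(G, C, depth_exponent=0.5, snr=3.0)
        norms = np.linalg.norm(G.values, axis=0)
        eligible = np.flatnonzero(norms > np.percentile(norms, 10))
        rng = np.random.default_rng(11)
        picks = rng.choice(eligible, size=40, replace=False)
        hits = 0
        for i in picks:
            study = make_study(G.values[:, i])
            out = solve_sloreta(kernel, G, study)
            hits += out.argmax() == i
        assert hits >= 0.95 * len(picks)

    def test_argmax_invariant_to_data_scale(self, rng):
        G, C = random_system(rng, n_ch=6, n_src=20)
        kernel = build_wmne_kernel(G, C)
        m = rng.standard_normal(6)
        a = solve_sloreta(kernel, G, make_study(m))
        b = solve_sloreta(kernel, G, make_study(1e3 * m))
        assert a.argmax() == b.argmax()


class TestEstimatorAPI:
    def test_fit_transform_matches_functions(self, rng):
        G, C = random_system(rng)
        m = rng.standard_normal(5)
        study = make_study(m)
        kernel = build_wmne_kernel(G, C, depth_exponent=0.5, snr=3.0)
        for est, fn in (
            (MNESolver(), lambda: solve_mne(kernel, study)),
            (DSPMSolver(), lambda: solve_dspm(kernel, C, study)),
            (SLORETASolver(), lambda: solve_sloreta(kernel, G, study)),
        ):
            got = est.fit(G, C).transform(study)
            np.testing.assert_allclose(got.amplitudes, fn().amplitudes, atol=1e-12)
            assert got.method_label == est.method_label

    def test_get_set_params_round_trip(self):
        est = MNESolver(depth_exponent=0.3, snr=2.0)
        params = est.get_params()
        assert params == {"depth_exponent": 0.3, "snr": 2.0}
        est.set_params(snr=5.0)
        assert est.snr == 5.0

    def test_unfitted_transform_raises(self, rng):
        with pytest.raises(RuntimeError, match="not fitted"):
            MNESolver().transform(make_study([1.0]))

    def test_channel_mismatch_rejected(self, rng):
        G, C = random_system(rng)
        kernel = build_wmne_kernel(G, C)
        with pytest.raises(ValueError, match="channels"):
            solve_mne(kernel, make_study(np.ones(7)))


def test_maxima_coincide_with_equal_norm_columns_noiseless(rng):
    """With C = sigma^2 I and equal-norm gain columns, the three maps share
    their maximum on noiseless single-source data."""
    G0 = rng.standard_normal((8, 30))
    G = GainMatrix(G0 / np.linalg.norm(G0, axis=0, keepdims=True), [f"C{i}" for i in range(8)])
    C = identity_cov(8, scale=1e-28)
    kernel = build_wmne_kernel(G, C)
    src = 13
    study = make_study(G.values[:, src])
    labels = {
        solve_mne(kernel, study).argmax(),
        solve_dspm(kernel, C, study).argmax(),
        solve_sloreta(kernel, G, study).argmax(),
    }
    assert labels == {src}
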