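import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from fmri_seqbench.events import EventTable, generate_paradigm
from fmri_seqbench.glm import (
    HRFSpec,
    build_design_matrix,
    canonical_hrf,
    compcor_regressors,
    contrast_tmap,
    estimate_ar1,
    fit_glm,
    hrf_derivative,
    make_contrast,
)


def _dense_double_gamma(dt=0.001, length=32.0):
    """Independent dense evaluation of the double-gamma expression."""
    t = np.arange(0.0, length, dt)
    h = sstats.gamma.pdf(t, 6.0) - sstats.gamma.pdf(t, 16.0) / 6.0
    return t, h / h.max()


class TestHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf()[0] == 0.0

    def test_peak_time_between_4_and_6_seconds(self):
        t_dense, h_dense = _dense_double_gamma()
        assert 4.0 <= t_dense[np.argmax(h_dense)] <= 6.0
        spec = HRFSpec()
        h = canonical_hrf(spec)
        assert 4.0 <= spec.times[np.argmax(h)] <= 6.0

    def test_single_sign_change(self):
        h = canonical_hrf()
        signs = np.sign(h[np.abs(h) > 1e-9])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1  # positive lobe then undershoot

    def test_peak_normalized(self):
        assert canonical_hrf().max() == pytest.approx(1.0)

    def test_derivative_telescopes_to_zero(self):
        spec = HRFSpec()
        h = canonical_hrf(spec)
        d = hrf_derivative(spec)
        assert abs(np.sum(d) * spec.dt - (h[-1] - h[0])) < 1e-3

    def test_derivative_zero_crossing_at_peak(self):
        spec = HRFSpec()
        h = canonical_hrf(spec)
        d = hrf_derivative(spec)
        peak = np.argmax(h)
        crossings = np.where(np.diff(np.sign(d)) != 0)[0]
        assert np.min(np.abs(crossings - peak)) <= 1

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            HRFSpec(peak_delay=-1.0)
        with pytest.raises(ValueError):
            HRFSpec(length=5.0)  # shorter than the undershoot


class TestDesignMatrix:
    def test_empty_events_gives_drift_and_constant(self):
        empty = EventTable(pd.DataFrame(
            {"onset": pd.Series(dtype=float),
             "duration": pd.Series(dtype=float),
             "condition": pd.Series(dtype=str)}))
        drift = np.random.default_rng(0).standard_normal((50, 3))
        X = build_design_matrix(empty, 50, 1.2, drift=drift)
        assert X.labels == ["drift_1", "drift_2", "drift_3", "constant"]

    def test_single_event_matches_direct_convolution(self):
        """The task column for one boxcar event equals the convolution
        integral of the HRF, evaluated independently by quadrature."""
        onset, dur, tr, n = 10.0, 2.0, 1.2, 40
        table = EventTable(pd.DataFrame(
            {"onset": [onset], "duration": [dur],
             "condition": ["visual_sentence"]}))
        spec = HRFSpec()
        X = build_design_matrix(table, n, tr, hrf=spec)
        col = X.column("visual_sentence")

        t_dense, h_dense = _dense_double_gamma(dt=0.001)
        expected = np.empty(n)
        for i in range(n):
            t_vol = i * tr
            # integral of h over the window the boxcar has swept past
            lo, hi = t_vol - onset - dur, t_vol - onset
            m = (t_dense >= max(lo, 0.0)) & (t_dense < max(hi, 0.0))
            expected[i] = np.sum(h_dense[m]) * 0.001
        # tolerance reflects the package's 0.1 s convolution grid against
        # the 1 ms oracle
        np.testing.assert_allclose(col, expected, atol=0.05)

    def test_duplicate_regressors_raise_named_error(self):
        table = EventTable(pd.DataFrame({
            "onset": [10.0, 10.0],
            "duration": [2.0, 2.0],
            "condition": ["visual_sentence", "auditory_sentence"],
        }))
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(table, 40, 1.2)

    def test_events_past_run_rejected(self):
        table = EventTable(pd.DataFrame(
            {"onset": [100.0], "duration": [2.0],
             "condition": ["visual_sentence"]}))
        with pytest.raises(ValueError, match="run covers"):
            build_design_matrix(table, 40, 1.2)


class TestCompCor:
    def test_zero_components_empty(self):
        data = np.random.default_rng(0).random((4, 4, 4, 30))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        assert compcor_regressors(data, mask, 0).shape == (30, 0)

    def test_recovers_planted_subspace(self):
        """Two orthogonal sinusoids planted across noise voxels are
        recovered with canonical correlation > 0.99 (noise sd 0.01)."""
        rng = np.random.default_rng(0)
        n_t, n_vox = 200, 60
        t = np.arange(n_t)
        s1 = np.sqrt(2 / n_t) * np.sin(2 * np.pi * 5 * t / n_t)
        s2 = np.sqrt(2 / n_t) * np.cos(2 * np.pi * 9 * t / n_t)
        truth = np.column_stack([s1, s2])
        loadings = rng.standard_normal((2, n_vox))
        series = truth @ loadings + 0.01 * rng.standard_normal((n_t, n_vox))
        data = series.T.reshape(n_vox, 1, 1, n_t)
        mask = np.ones((n_vox, 1, 1), bool)
        comps = compcor_regressors(data, mask, 2)

        qt, _ = np.linalg.qr(truth)
        qc, _ = np.linalg.qr(comps)
        canon = np.linalg.svd(qt.T @ qc, compute_uv=False)
        assert canon.min() > 0.99

    def test_components_orthogonal_zero_mean(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 1, 1, 100))
        mask = np.ones((20, 1, 1), bool)
        comps = compcor_regressors(data, mask, 4)
        gram = comps.T @ comps
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0,
                                   atol=1e-10)
        np.testing.assert_allclose(comps.mean(axis=0), 0, atol=1e-10)

    def test_errors(self):
        data = np.ones((5, 1, 1, 10))
        mask = np.ones((5, 1, 1), bool)
        with pytest.raises(ValueError, match="exceeds"):
            compcor_regressors(data, mask, 50)
        with pytest.raises(ValueError, match="constant"):
            compcor_regressors(data, mask, 2)
        with pytest.raises(ValueError, match="empty"):
            compcor_regressors(data, np.zeros((5, 1, 1), bool), 1)


class TestEstimateAr1:
    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal((200, 500))
        assert estimate_ar1(r) < 0.05

    def test_recovers_planted_rho(self):
        from fmri_seqbench.simulate import _ar1_noise
        rng = np.random.default_rng(3)
        r = _ar1_noise((200,), 500, 0.5, 1.0, rng)
        assert 0.45 <= estimate_ar1(r) <= 0.55

    def test_negative_rho_clipped_to_zero(self):
        from fmri_seqbench.simulate import _ar1_noise
        rng = np.random.default_rng(4)
        eps = rng.standard_normal((100, 500))
        r = eps.copy()
        r[:, 1:] = eps[:, 1:] - 0.3 * eps[:, :-1]  # negative lag-1 corr
        assert estimate_ar1(r) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_ar1(np.zeros((3, 10)))


def _small_design(n=60, seed=0):
    rng = np.random.default_rng(seed)
    events = generate_paradigm(60.0, 1, min_gap=0.5, seed=seed,
                               event_duration=2.0,
                               catalogue=("visual_sentence",
                                          "auditory_sentence"))
    return build_design_matrix(events, n, 1.0)


class TestFitGlm:
    def test_noiseless_exact_interpolation(self):
        X = _small_design()
        rng = np.random.default_rng(5)
        b = rng.standard_normal((10, X.n_regressors))
        Y = b @ X.matrix.T  # (10 voxels, t)
        fit = fit_glm(Y, X, "ols")
        np.testing.assert_allclose(fit.beta, b, atol=1e-10)
        np.testing.assert_allclose(fit.resid_var, 0, atol=1e-16)

    def test_ar1_reduces_to_ols_when_rho_clips_to_zero(self):
        """On white-noise data the pooled lag-1 estimate is at the clip
        boundary, so AR(1) whitening must reproduce OLS identically."""
        X = _small_design()
        rng = np.random.default_rng(2)
        Y = 1.0 + 0.1 * rng.standard_normal((300, X.n_volumes))
        fit_ar = fit_glm(Y, X, "ar1")
        assert fit_ar.rho == 0.0  # OLS residuals are anti-correlated
        fit_ols = fit_glm(Y, X, "ols")
        np.testing.assert_allclose(fit_ar.beta, fit_ols.beta, atol=1e-6)
        t_ar = contrast_tmap(fit_ar, X, make_contrast_mean(X))
        t_ols = contrast_tmap(fit_ols, X, make_contrast_mean(X))
        np.testing.assert_allclose(t_ar.data, t_ols.data, atol=1e-6)

    def test_matches_normal_equations_oracle_on_fixture(self):
        """t-statistics agree with a brute-force normal-equations solver
        on a small printed fixture (12 volumes x 3 regressors)."""
        X_fix = np.array([
            [1.0, 0.0, 1.0], [1.0, 0.2, 1.0], [1.0, 0.7, 1.0],
            [1.0, 1.0, 1.0], [1.0, 0.9, 1.0], [1.0, 0.4, 1.0],
            [1.0, 0.1, 1.0], [1.0, 0.0, 1.0], [1.0, 0.3, 1.0],
            [1.0, 0.8, 1.0], [1.0, 1.0, 1.0], [1.0, 0.5, 1.0],
        ])
        X_fix[:, 0] = np.linspace(-1, 1, 12)  # drift-like column
        y = np.array([2.1, 1.9, 3.0, 3.4, 3.1, 2.4,
                      2.0, 1.8, 2.5, 3.2, 3.6, 2.7])
        from fmri_seqbench.glm import DesignMatrix
        design = DesignMatrix(X_fix, ["drift_1", "task", "constant"], 1.0)
        fit = fit_glm(y.reshape(1, 1, 1, -1), design, "ols")
        c = np.array([0.0, 1.0, 0.0])

        # oracle: explicit normal equations
        xtx_inv = np.linalg.inv(X_fix.T @ X_fix)
        beta = xtx_inv @ X_fix.T @ y
        resid = y - X_fix @ beta
        sigma2 = resid @ resid / (12 - 3)
        t_expected = (c @ beta) / np.sqrt(sigma2 * c @ xtx_inv @ c)

        from fmri_seqbench.glm import ContrastSpec
        t = contrast_tmap(fit, design, ContrastSpec("task", c))
        assert t.data[0, 0, 0] == pytest.approx(t_expected, abs=1e-6)

    def test_whitened_ols_equals_gls_oracle(self):
        """AR(1)-prewhitened OLS equals explicit GLS with the matching
        covariance on a small instance."""
        from fmri_seqbench.simulate import _ar1_noise
        X = _small_design()
        rng = np.random.default_rng(6)
        Y = 2.0 + _ar1_noise((50,), X.n_volumes, 0.5, 0.3, rng)
        fit = fit_glm(Y, X, "ar1")
        rho = fit.rho
        assert rho > 0.2
        n = X.n_volumes
        cov = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        ci = np.linalg.inv(cov)
        gls_beta = np.linalg.solve(X.matrix.T @ ci @ X.matrix,
                                   X.matrix.T @ ci @ Y.T).T
        np.testing.assert_allclose(fit.beta, gls_beta, atol=1e-8)

    def test_t_invariant_to_column_rescaling(self):
        X = _small_design()
        rng = np.random.default_rng(7)
        Y = 1.0 + 0.2 * rng.standard_normal((30, X.n_volumes))
        from fmri_seqbench.glm import ContrastSpec, DesignMatrix
        idx = X.labels.index("visual_sentence")
        c = np.zeros(X.n_regressors)
        c[idx] = 1.0
        t1 = contrast_tmap(fit_glm(Y, X, "ols"), X,
                           ContrastSpec("a", c)).data
        M = X.matrix.copy()
        M[:, idx] *= 4.0
        X2 = DesignMatrix(M, X.labels, X.tr)
        c2 = c.copy()
        c2[idx] = 4.0  # rescale weight with the column
        t2 = contrast_tmap(fit_glm(Y, X2, "ols"), X2,
                           ContrastSpec("a", c2)).data
        np.testing.assert_allclose(t1, t2, rtol=1e-8)

    def test_extended_whitening_reduces_residual_autocorr(self):
        from fmri_seqbench.simulate import _ar1_noise
        X = _small_design(n=200)
        rng = np.random.default_rng(8)
        Y = 5.0 + _ar1_noise((100,), 200, 0.6, 0.5, rng)
        fit = fit_glm(Y, X, "extended")
        assert fit.ar_coefficients is not None
        assert len(fit.ar_coefficients) == 3
        assert fit.dof == 200 - X.n_regressors

    def test_mean_signal_t_positive_in_brain(self):
        X = _small_design()
        rng = np.random.default_rng(9)
        Y = 100.0 + rng.standard_normal((200, X.n_volumes))
        t = contrast_tmap(fit_glm(Y, X, "ols"), X, "mean_signal")
        assert (t.data > 0).all()

    def test_all_zero_contrast_rejected(self):
        from fmri_seqbench.glm import ContrastSpec
        with pytest.raises(ValueError):
            ContrastSpec("zero", np.zeros(4))


def make_contrast_mean(X):
    return make_contrast("mean_signal", X)


class TestWhiteningCalibration:
    def test_ar1_whitening_decorrelates_residuals(self):
        """Whitened residual lag-1 autocorrelation falls below 0.05 when
        the generating noise is AR(1) with rho <= 0.6."""
        from fmri_seqbench.glm import _ar1_whitener
        from fmri_seqbench.simulate import _ar1_noise
        X = _small_design(n=300)
        rng = np.random.default_rng(10)
        for rho_sim in (0.3, 0.6):
            Y = _ar1_noise((200,), 300, rho_sim, 1.0, rng)
            fit = fit_glm(Y, X, "ar1")
            W = _ar1_whitener(fit.rho, 300)
            resid = (W @ Y.T) - (W @ X.matrix) @ fit.beta.T
            resid = resid.T
            r1 = abs(np.sum(resid[:, :-1] * resid[:, 1:])
                     / np.sum(resid * resid))
            assert r1 < 0.05
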