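"""Canonical correlation machinery: real, complex, partial and lagged."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mftfcca.cca_core import cca, cca_complex, lagged_cca, partial_cca
from mftfcca.preprocessing import stft_tfr, zscore_tfr
from mftfcca.timeseries import TimeSeriesSet


def _random_data(seed, n=500, p=4, q=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    W = rng.standard_normal((p, q))
    Y = X @ W + 0.5 * rng.standard_normal((n, q))
    return X, Y


class TestRealCCA:
    def test_perfect_linear_dependence(self, rng):
        X = rng.standard_normal((200, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        assert cca(X, y, reg=0.0).cc == pytest.approx(1.0, abs=1e-8)

    def test_univariate_target_equals_regression_r2(self, rng):
        X = rng.standard_normal((300, 4))
        y = X @ np.array([0.5, 0.2, -0.3, 0.0]) + rng.standard_normal(300)
        res = cca(X, y, reg=0.0)
        # independent oracle: ordinary least squares
        Xc = np.column_stack([np.ones(300), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        r2 = 1 - resid.var() / y.var()
        assert res.cc**2 == pytest.approx(r2, abs=1e-10)

    def test_independent_noise_cc_shrinks_with_n(self, rng):
        small = cca(rng.standard_normal((60, 5)), rng.standard_normal((60, 1)), reg=0.0).cc
        big = cca(rng.standard_normal((6000, 5)), rng.standard_normal((6000, 1)), reg=0.0).cc
        assert big < small
        assert big < 0.1

    def test_matches_sklearn_on_random_data(self):
        sklearn_cca = pytest.importorskip("sklearn.cross_decomposition").CCA
        X, Y = _random_data(0)
        ours = cca(X, Y, reg=0.0).cc
        model = sklearn_cca(n_components=1).fit(X, Y)
        u, v = model.transform(X, Y)
        theirs = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        # sklearn's NIPALS iteration is only approximately the eigensolution
        assert ours == pytest.approx(theirs, abs=1e-3)
        assert ours >= theirs - 1e-6  # the eigensolution is the maximizer

    def test_beats_brute_force_grid_on_2x2(self, rng):
        X = rng.standard_normal((400, 2))
        Y = 0.5 * X @ rng.standard_normal((2, 2)) + rng.standard_normal((400, 2))
        best = 0.0
        angles = np.linspace(0, np.pi, 181)
        for ta in angles:
            xu = X @ np.array([np.cos(ta), np.sin(ta)])
            for tb in angles:
                yv = Y @ np.array([np.cos(tb), np.sin(tb)])
                best = max(best, abs(np.corrcoef(xu, yv)[0, 1]))
        assert cca(X, Y, reg=0.0).cc >= best - 1e-3

    def test_invariant_under_invertible_transforms(self, rng):
        X, Y = _random_data(1)
        base = cca(X, Y, reg=0.0).cc
        A = rng.standard_normal((X.shape[1], X.shape[1])) + 3 * np.eye(X.shape[1])
        B = rng.standard_normal((Y.shape[1], Y.shape[1])) + 3 * np.eye(Y.shape[1])
        assert cca(X @ A, Y @ B, reg=0.0).cc == pytest.approx(base, abs=1e-8)

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_range(self, seed):
        X, Y = _random_data(seed, n=120)
        a = cca(X, Y, reg=0.0).cc
        b = cca(Y, X, reg=0.0).cc
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b, abs=1e-8)

    def test_rank_deficiency_advises_regularization(self, rng):
        X = rng.standard_normal((100, 3))
        X = np.column_stack([X, X[:, 0]])  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="reg"):
            cca(X, rng.standard_normal(100), reg=0.0)
        cca(X, rng.standard_normal(100), reg=1e-6)  # regularized path works

    def test_mismatched_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="sample counts"):
            cca(rng.standard_normal((50, 2)), rng.standard_normal((60, 2)))


class TestComplexCCA:
    def test_real_input_agrees_with_real_cca(self, rng):
        X, Y = _random_data(2, q=1)
        a = cca_complex(X.astype(complex), Y, mode="complex_then_abs", reg=0.0).cc
        b = cca_complex(X.astype(complex), Y, mode="abs_then_cca", reg=0.0).cc
        c = cca(X, Y, reg=0.0).cc
        assert a == pytest.approx(c, abs=1e-8)
        # abs-mode rectifies the columns; only the sign-invariant part remains
        assert 0.0 <= b <= 1.0

    def test_phase_rotation_invariance(self, rng):
        n = 300
        X = rng.standard_normal((n, 3)) + 1j * rng.standard_normal((n, 3))
        y = (X[:, 0]).real + 0.3 * rng.standard_normal(n)
        base = cca_complex(X, y, reg=0.0).cc
        Xr = X.copy()
        Xr[:, 1] *= np.exp(1j * 1.1)
        assert cca_complex(Xr, y, reg=0.0).cc == pytest.approx(base, abs=1e-9)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown mode"):
            cca_complex(rng.standard_normal((10, 2)), rng.standard_normal(10), mode="zzz")


class TestPartialCCA:
    def test_irrelevant_conditioner_preserves_cc(self, rng):
        X, Y = _random_data(3, n=4000)
        Z = rng.standard_normal((4000, 2))
        plain = cca(X, Y, reg=0.0).cc
        part = partial_cca(X, Y, Z, reg=0.0).cc
        assert part == pytest.approx(plain, abs=0.02)

    def test_fully_explained_target_vanishes(self, rng):
        X = rng.standard_normal((500, 3))
        Z = rng.standard_normal((500, 2))
        Y = Z @ np.array([[1.0], [-0.5]])
        assert partial_cca(X, Y, Z, reg=0.0).cc < 0.15

    def test_constant_conditioner_reduces_to_cca(self, rng):
        X, Y = _random_data(4)
        Z = np.ones((X.shape[0], 1))
        a = partial_cca(X, Y, Z, reg=0.0).cc
        b = cca(X, Y, reg=0.0).cc
        assert a == pytest.approx(b, abs=1e-8)


class TestLaggedCCA:
    @pytest.fixture
    def tfr_and_y(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(400)
        ts = TimeSeriesSet([{"x": x, "y": y}], {"x": 200.0, "y": 40.0})
        tfr = zscore_tfr(stft_tfr(ts, "x", 0.15, 40.0))
        return tfr, [y]

    def test_zero_lag_reproduces_direct_cca(self, tfr_and_y):
        tfr, y = tfr_and_y
        res = lagged_cca(tfr, y, 0.0, reg=1e-3)
        X = tfr.values[0]
        yv = y[0][tfr.align_offset : tfr.align_offset + tfr.n_bins]
        yv = (yv - yv.mean()) / yv.std()
        direct = cca_complex(X[: len(yv)], yv, reg=1e-3)
        assert res.cc == pytest.approx(direct.cc, abs=1e-10)

    def test_white_noise_profile_flat(self, tfr_and_y):
        tfr, y = tfr_and_y
        ccs = [lagged_cca(tfr, y, lag, reg=1e-3).cc for lag in (-0.3, -0.1, 0.1, 0.3)]
        assert max(ccs) - min(ccs) < 0.15

    def test_excessive_lag_rejected(self, tfr_and_y):
        tfr, y = tfr_and_y
        with pytest.raises(ValueError, match="aligned samples"):
            lagged_cca(tfr, y, 9.5)

    def test_loadings_flag_an_informative_frequency(self, rng):
        # y is the decimated 10-Hz narrowband part of x: the canonical
        # loading profile must peak near 10 Hz
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8.0, 12.0], btype="bandpass", fs=200.0, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(8000))
        x = x + 0.2 * rng.standard_normal(8000)
        y = x[::5]
        ts = TimeSeriesSet([{"x": x, "y": y}], {"x": 200.0, "y": 40.0})
        tfr = zscore_tfr(stft_tfr(ts, "x", 0.4, 40.0))
        res = lagged_cca(tfr, [y], 0.0, reg=1e-3)
        peak_freq = tfr.freqs[int(np.argmax(res.coef_magnitude))]
        assert abs(peak_freq - 10.0) <= 2.0
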