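"""Analytic and estimated spectral Granger causality, MF-VAR baseline."""

import numpy as np
import pytest

from mftfcca.spectral_gc import (
    _var_from_autocov,
    analytic_sgc,
    conditional_analytic_sgc,
    fit_var,
    mf_var_gc,
    order_scan,
)
from mftfcca.timeseries import TimeSeriesSet
from mftfcca.var_simulator import (
    VARModel,
    make_bidirectional_var41,
    make_chain_system,
    make_stokes_var3,
    make_unidirectional_xy,
    make_unidirectional_yx,
    simulate_var,
)

FREQS = np.linspace(0.0, 100.0, 1001)


class TestAnalyticSGC:
    def test_decoupled_model_has_zero_sgc(self):
        A = np.zeros((2, 2, 2))
        A[0] = np.diag([0.5, -0.3])
        m = VARModel(A, fs=100.0)
        for s, t in ((0, 1), (1, 0)):
            assert analytic_sgc(m, s, t, FREQS).value.max() <= 1e-12

    @pytest.mark.parametrize(
        "factory,null_dir",
        [(make_unidirectional_xy, ("y", "x")), (make_unidirectional_yx, ("x", "y"))],
    )
    def test_null_direction_of_triangular_systems(self, factory, null_dir):
        spec = analytic_sgc(factory(), *null_dir, FREQS)
        assert spec.value.max() <= 1e-10

    def test_xy_system_peaks_near_80hz(self):
        spec = analytic_sgc(make_unidirectional_xy(), "x", "y", FREQS)
        f, v = spec.peak()
        assert f == pytest.approx(80.0, abs=1.0)
        # secondary causal band around 4 Hz exceeds its surroundings
        g4 = spec.value[np.argmin(np.abs(FREQS - 4.0))]
        g10 = spec.value[np.argmin(np.abs(FREQS - 10.0))]
        assert g4 > g10

    def test_var41_directions_peak_at_design_frequencies(self):
        m = make_bidirectional_var41()
        yx = analytic_sgc(m, "y", "x", FREQS)
        assert yx.peak()[0] == pytest.approx(15.0, abs=1.0)

    def test_scale_invariance(self):
        m = make_unidirectional_xy()
        scaled = VARModel(m.coeffs, noise_cov=4.0 * np.eye(2), fs=m.fs,
                          channel_names=m.channel_names)
        np.testing.assert_allclose(
            analytic_sgc(m, "x", "y", FREQS).value,
            analytic_sgc(scaled, "x", "y", FREQS).value,
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "factory", [make_unidirectional_xy, make_unidirectional_yx, make_bidirectional_var41]
    )
    def test_geweke_identity(self, factory):
        """Frequency-integrated SGC equals the time-domain GC ratio.

        The time-domain value is computed independently from the exact
        autocovariance sequence: the target's marginal innovation variance
        (high-order Yule-Walker) against its full-model innovation variance.
        """
        model = factory()
        fine = np.linspace(0.0, model.fs / 2, 4096)
        for s, t in ((0, 1), (1, 0)):
            spec = analytic_sgc(model, s, t, fine)
            p = 256
            gam = model.autocovariance(2 * p)
            sub = gam[:, t : t + 1, t : t + 1]
            _, sig_marg = _var_from_autocov(sub, p)
            f_time = float(np.log(sig_marg[0, 0] / model.noise_cov[t, t]))
            if f_time < 1e-8:
                assert abs(spec.time_domain_gc) < 1e-6
            else:
                assert spec.time_domain_gc == pytest.approx(f_time, rel=1e-3)


class TestConditionalSGC:
    def test_decoupled_third_channel_recovers_bivariate(self):
        m = make_unidirectional_xy()
        A = np.zeros((4, 3, 3))
        A[:, :2, :2] = m.coeffs
        A[0, 2, 2] = 0.5
        full = VARModel(A, fs=200.0, channel_names=["x", "y", "z"])
        fr = np.linspace(0, 100, 201)
        cond = conditional_analytic_sgc(full, "x", "y", "z", freqs=fr)
        biv = analytic_sgc(m, "x", "y", fr)
        np.testing.assert_allclose(cond.value, biv.value, atol=1e-6)

    def test_chain_mediated_path_vanishes_conditionally(self):
        ch = make_chain_system()
        fr = np.linspace(0, 100, 201)
        assert conditional_analytic_sgc(ch, "x1", "y", "x2", freqs=fr).value.max() < 1e-6

    def test_chain_direct_paths_remain(self):
        ch = make_chain_system()
        fr = np.linspace(0, 100, 201)
        assert conditional_analytic_sgc(ch, "x2", "y", "x1", freqs=fr).value.max() > 0.1
        x12 = conditional_analytic_sgc(ch, "x1", "x2", "y", freqs=fr)
        assert x12.value.max() > 1.0
        assert x12.peak()[0] == pytest.approx(80.0, abs=2.0)


class TestFitVar:
    def test_parameter_recovery_on_trivariate_benchmark(self):
        model = make_stokes_var3()
        ts = simulate_var(model, 50, 10.0, seed=71)
        fit = fit_var(ts, order=3)
        assert np.abs(fit.coeffs - model.coeffs).max() < 0.05
        assert np.abs(fit.noise_cov - np.eye(3)).max() < 0.1

    def test_white_noise_fits_to_zero_and_low_order(self, rng):
        data = rng.standard_normal((4, 1000, 2))
        fit = fit_var(data, order=2)
        assert np.abs(fit.coeffs).max() < 0.06
        scan = order_scan(data, 4)
        bics = [scan[p]["bic"] for p in sorted(scan)]
        assert bics[0] == min(bics)

    def test_fitted_sgc_converges_to_analytic(self):
        model = make_bidirectional_var41()
        fr = np.linspace(0.0, 40.0, 161)
        truth = analytic_sgc(model, "y", "x", fr).value
        dists = []
        for n_trials in (6, 24):
            ts = simulate_var(model, n_trials, 10.0, seed=72)
            fit = fit_var(ts, order=41)
            est = analytic_sgc(fit, "y", "x", fr).value
            dists.append(np.linalg.norm(est - truth))
        assert dists[1] < dists[0]
        # fitted model reproduces the 15-Hz Y->X causal peak
        ts = simulate_var(model, 24, 10.0, seed=72)
        est = analytic_sgc(fit_var(ts, order=41), "y", "x", fr)
        assert est.peak()[0] == pytest.approx(15.0, abs=2.0)


class TestMFVAR:
    def _mf_ts(self, rng, n_trials=10, n=1000, k=5, couple=False):
        trials = []
        for _ in range(n_trials):
            x = rng.standard_normal(n)
            if couple:
                x = np.convolve(rng.standard_normal(n), [1, 0.6, 0.3], "same")
            y = rng.standard_normal(n // k)
            if couple:
                y = y * 0.3 + x[::k]
            trials.append({"x": x, "y": y})
        return TimeSeriesSet(trials, {"x": 200.0, "y": 40.0})

    def test_stacked_dimension_and_rate_ratio(self, rng):
        res = mf_var_gc(self._mf_ts(rng), "x", "y", order=1)
        assert res["hf_to_lf"].ratio == 5
        assert res["hf_to_lf"].df == 5  # one lag x five fast components

    def test_type_one_error_controlled_on_decoupled_data(self):
        rng = np.random.default_rng(55)
        rejections = 0
        for _ in range(12):
            res = mf_var_gc(self._mf_ts(rng), "x", "y", order=1)
            rejections += sum(r.p_value < 0.05 for r in res.values())
        assert rejections <= 3  # 24 tests at alpha=0.05

    def test_detects_fast_to_slow_coupling(self):
        rng = np.random.default_rng(56)
        res = mf_var_gc(self._mf_ts(rng, couple=True), "x", "y", order=1)
        assert res["hf_to_lf"].p_value < 1e-4

    def test_detects_simulated_var_coupling_at_small_lag(self):
        from mftfcca.preprocessing import decimate

        ts = simulate_var(make_unidirectional_xy(), 10, 10.0, seed=77)
        ts = decimate(ts, "y", 2)  # small rate discrepancy, small lags
        res = mf_var_gc(ts, "x", "y", order=2)
        assert res["hf_to_lf"].p_value < 0.01

    def test_non_integer_ratio_rejected(self, rng):
        ts = TimeSeriesSet(
            [{"x": rng.standard_normal(300), "y": rng.standard_normal(200)}],
            {"x": 150.0, "y": 100.0},
        )
        with pytest.raises(ValueError, match="integer"):
            mf_var_gc(ts, "x", "y")
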