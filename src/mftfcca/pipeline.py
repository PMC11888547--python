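"""End-to-end mixed-frequency time-frequency CCA (MF-TFCCA).

The procedure, for a fast channel X and a slow channel Y:

1. STFT of X with hop equal to one Y sample period, z-scored per frequency,
   giving a complex TFR aligned to Y's clock.
2. Lagged CCA between the TFR and Y over a grid of signed lags on Y's
   sample grid. Negative lags mean the X window precedes the Y sample, so a
   significant canonical correlation (CC) beyond -window_len/2 is evidence
   for X -> Y; beyond +window_len/2 for Y -> X. Within +/- window_len/2 the
   (center-aligned) window still overlaps the sample and direction is
   ambiguous.
3. Phase-randomized surrogates of both channels give a null CC envelope per
   lag; a direction is called when at least two consecutive lags beyond the
   window boundary exceed the upper envelope.
4. The CCA weight magnitudes |u| over frequency at the profile peak expose
   the driving frequency; band-stopping a candidate band in X and measuring
   the relative CC change ("filter-one-frequency-out") attributes the CC to
   bands: an informative band yields a clearly negative relative gain.

A conditional variant partials a third channel out of the CCA, and a
mixed-rate lagged cross-correlation (xcorr) baseline is included. The lag
convention of ``xcorr_profile`` is the mirror image of the lag-CC one:
``xcorr`` correlates X(t) with Y(t + lag), so X -> Y coupling with delay d
peaks at +d there, while the lag-CC profile places X -> Y evidence at
negative lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cca_core import CCAResult, lagged_cca
from .preprocessing import TFR, bandstop_filter, stft_tfr, zscore_tfr
from .timeseries import TimeSeriesSet

__all__ = [
    "LagCCProfile",
    "DrivingFrequencyReport",
    "SurrogateEnsemble",
    "phase_randomize",
    "lag_cc_profile",
    "conditional_lag_cc_profile",
    "driving_frequency_report",
    "significance_test",
    "xcorr_profile",
]

DEFAULT_N_SURROGATES = 100
ENVELOPE_PERCENTILES = (2.5, 97.5)


@dataclass
class SurrogateEnsemble:
    """Null CC samples from phase-randomized surrogate pairs."""

    n_surrogates: int
    cc_null: np.ndarray
    p_value: float | None = None
    test: str = "t"

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("need at least one surrogate")
        self.cc_null = np.asarray(self.cc_null, dtype=float)


@dataclass
class LagCCProfile:
    """Canonical correlation versus signed lag, with its surrogate envelope."""

    lags: np.ndarray
    cc: np.ndarray
    window_len: float
    trial_cc: np.ndarray | None = None  # (n_lags, n_trials)
    null_cc: np.ndarray | None = None  # (n_surrogates, n_lags)
    null_mean: np.ndarray | None = None
    null_lo: np.ndarray | None = None
    null_hi: np.ndarray | None = None
    coef_magnitude: np.ndarray | None = None  # (n_lags, n_freqs)
    freqs: np.ndarray | None = None
    direction_call: str | None = None
    p_values: np.ndarray | None = None

    def peak(self, side: str = "both") -> tuple[float, float]:
        """(lag, cc) of the profile maximum on one side ('neg'/'pos'/'both')."""
        if side == "neg":
            mask = self.lags < 0
        elif side == "pos":
            mask = self.lags > 0
        else:
            mask = np.ones_like(self.lags, dtype=bool)
        idx = np.flatnonzero(mask)
        i = idx[int(np.argmax(self.cc[idx]))]
        return float(self.lags[i]), float(self.cc[i])

    def coef_at(self, lag: float) -> np.ndarray:
        """Mean CCA coefficient magnitudes at the grid lag nearest ``lag``."""
        if self.coef_magnitude is None:
            raise ValueError("profile was computed without coefficient storage")
        i = int(np.argmin(np.abs(self.lags - lag)))
        return self.coef_magnitude[i]


def phase_randomize(
    ts: TimeSeriesSet, seed: int | np.random.Generator
) -> TimeSeriesSet:
    """Phase-randomized surrogate of every channel and trial.

    The Fourier magnitude spectrum is preserved exactly; phases of the
    non-DC, non-Nyquist bins are replaced by i.i.d. uniform draws (conjugate
    symmetry maintained by the real inverse transform).
    """
    rng = np.random.default_rng(seed)
    trials = []
    for trial in ts.trials:
        new = {}
        for name in sorted(trial):
            x = trial[name]
            n = len(x)
            spec = np.fft.rfft(x)
            phases = rng.uniform(0, 2 * np.pi, size=len(spec))
            surro_spec = np.abs(spec) * np.exp(1j * phases)
            # DC and Nyquist bins must stay real: keep them as-is
            surro_spec[0] = spec[0]
            if n % 2 == 0:
                surro_spec[-1] = spec[-1]
            new[name] = np.fft.irfft(surro_spec, n=n)
        trials.append(new)
    return TimeSeriesSet(trials, dict(ts.fs))


def _lag_grid(lag_range: float | tuple[float, float], fs_slow: float) -> np.ndarray:
    if np.isscalar(lag_range):
        lo, hi = -float(lag_range), float(lag_range)
    else:
        lo, hi = lag_range
    step = 1.0 / fs_slow
    k0 = int(np.ceil(lo / step))
    k1 = int(np.floor(hi / step))
    return np.arange(k0, k1 + 1) * step


def _z_bins_for_conditioning(
    ts: TimeSeriesSet,
    z: str,
    tfr: TFR,
    target_fs: float,
    z_role: str,
    n_fft: int | None,
) -> list[np.ndarray]:
    """Conditioning matrix per trial, one row per TFR time bin.

    The conditioner travels with the source's window positions: partialling
    asks whether the TFR still explains Y once Z's concurrent content is
    removed.
    """
    if z_role == "tfr":
        ztfr = zscore_tfr(
            stft_tfr(ts, z, tfr.window_len, target_fs, n_fft=n_fft)
        )
        nb = min(ztfr.n_bins, tfr.n_bins)
        return [ztfr.values[t, :nb, :] for t in range(ztfr.n_trials)]
    if z_role != "raw":
        raise ValueError(f"unknown z_role {z_role!r}")
    fs_z = ts.fs[z]
    out = []
    for zx in ts.channel(z):
        # sample Z at the TFR window centers
        idx = np.clip(np.round(tfr.times * fs_z).astype(int), 0, len(zx) - 1)
        zv = zx[idx]
        zv = (zv - zv.mean()) / (zv.std() or 1.0)
        out.append(zv[:, None])
    return out


def _profile_core(
    ts: TimeSeriesSet,
    x: str,
    y: str,
    lags: np.ndarray,
    window_len: float,
    mode: str,
    reg: float | None,
    n_fft: int | None,
    z: str | None,
    z_role: str,
    min_overlap: int,
    store_coefs: bool,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Per-trial CC for every lag; optionally the mean loading per lag."""
    target_fs = ts.fs[y]
    tfr = zscore_tfr(stft_tfr(ts, x, window_len, target_fs, n_fft=n_fft))
    y_trials = ts.channel(y)
    if z is None:
        return _profile_core_fast(
            tfr, y_trials, lags, target_fs, mode, reg, min_overlap, store_coefs
        ) + (tfr.freqs,)
    z_bins = _z_bins_for_conditioning(ts, z, tfr, target_fs, z_role, n_fft)
    trial_cc = np.empty((len(lags), ts.n_trials))
    coefs = np.empty((len(lags), len(tfr.freqs))) if store_coefs else None
    for i, lag in enumerate(lags):
        res = lagged_cca(
            tfr, y_trials, lag, mode=mode, reg=reg, Z=z_bins, min_overlap=min_overlap
        )
        trial_cc[i] = res.trial_cc
        if store_coefs:
            coefs[i] = res.coef_magnitude
    return trial_cc, coefs, tfr.freqs


def _profile_core_fast(
    tfr,
    y_trials: list[np.ndarray],
    lags: np.ndarray,
    target_fs: float,
    mode: str,
    reg: float | None,
    min_overlap: int,
    store_coefs: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Vectorized lag sweep for the univariate-target case.

    The within-set covariance of the (z-scored) TFR and the slow channel's
    variance are estimated once per trial over the full trial (stationarity
    assumption); only the cross-covariance is recomputed per lag. This is
    algebraically the same generalized-eigenproblem solution as
    :func:`mftfcca.cca_core.lagged_cca` up to the edge bins excluded from a
    shifted overlap, and is cross-checked against it in the test suite.
    """
    from scipy.linalg import cho_factor, cho_solve

    from .cca_core import DEFAULT_REG_SCALE, _aligned_slices

    n_trials = len(y_trials)
    n_freq = len(tfr.freqs)
    trial_cc = np.empty((len(lags), n_trials))
    coefs = np.zeros((len(lags), n_freq)) if store_coefs else None
    lag_steps = [int(round(lag * target_fs)) for lag in lags]
    for t in range(n_trials):
        X = np.abs(tfr.values[t]) if mode == "abs_then_cca" else tfr.values[t]
        if mode == "abs_then_cca":
            X = X - X.mean(axis=0, keepdims=True)
            sd = X.std(axis=0)
            X = X / np.where(sd > 0, sd, 1.0)
        n = X.shape[0]
        sxx = X.conj().T @ X / (n - 1)
        rg = (
            DEFAULT_REG_SCALE * float(np.real(np.trace(sxx)) / n_freq)
            if reg is None
            else float(reg)
        )
        factor = cho_factor(sxx + rg * np.eye(n_freq), lower=True)
        yv = np.asarray(y_trials[t], dtype=float)
        yv = (yv - yv.mean()) / (yv.std() or 1.0)
        for i, s in enumerate(lag_steps):
            ks, yi = _aligned_slices(tfr, len(yv), s)
            m = len(yi)
            if m < min_overlap:
                raise ValueError(
                    f"only {m} aligned samples at lag {lags[i]:+.3f}s "
                    f"(need >= {min_overlap})"
                )
            c = X[ks].conj().T @ yv[yi] / (m - 1)
            cc2 = float(np.real(c.conj() @ cho_solve(factor, c)))
            trial_cc[i, t] = min(np.sqrt(max(cc2, 0.0)), 1.0)
            if store_coefs:
                coefs[i] += np.abs(c)
    if store_coefs:
        coefs /= n_trials
    return trial_cc, coefs


def _call_direction(
    lags: np.ndarray,
    cc: np.ndarray,
    null_cc: np.ndarray,
    window_len: float,
) -> str:
    """Directionality from familywise-calibrated excursions per side.

    The TFR bins are centered on their windows, so a window stops
    overlapping the slow sample once |lag| > window_len / 2: that is the
    direction-ambiguity boundary (the dashed lines of the profile plots).
    Because neighbouring lags are strongly correlated (overlapping
    windows), per-lag envelopes badly over-call; instead each side is
    tested against the null distribution of its *maximum* surrogate CC
    (max-statistic familywise control at 2.5% per side).
    """
    boundary = window_len / 2
    alpha_side = (100.0 - ENVELOPE_PERCENTILES[1]) / 100.0  # 2.5% per side
    calls = {}
    for side, mask in (("neg", lags < -boundary), ("pos", lags > boundary)):
        if not np.any(mask):
            calls[side] = False
            continue
        null_max = null_cc[:, mask].max(axis=1)
        # exact-conservative permutation p-value of the side's maximum CC
        p_side = (1.0 + np.sum(null_max >= cc[mask].max())) / (1.0 + len(null_max))
        calls[side] = bool(p_side <= alpha_side)
    if calls["neg"] and calls["pos"]:
        return "bidirectional"
    if calls["neg"]:
        return "x_to_y"
    if calls["pos"]:
        return "y_to_x"
    return "none"


def lag_cc_profile(
    ts: TimeSeriesSet,
    x: str,
    y: str,
    lag_range: float | tuple[float, float],
    window_len: float,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    mode: str = "complex_then_abs",
    reg: float | None = None,
    n_fft: int | None = None,
    seed: int | np.random.Generator = 0,
    min_overlap: int = 50,
    _z: str | None = None,
    _z_role: str = "raw",
) -> LagCCProfile:
    """Lag-CC curve between fast channel ``x`` and slow channel ``y``.

    The lag grid covers ``lag_range`` (seconds, symmetric scalar or a
    (lo, hi) pair) at the slow channel's sample period. The surrogate
    envelope is the 2.5/97.5 percentile band of the trial-mean CC over
    ``n_surrogates`` phase-randomized copies of both channels; set
    ``n_surrogates=0`` to skip it (no direction call is made then).
    """
    fs_slow = ts.fs[y]
    lags = _lag_grid(lag_range, fs_slow)
    sub = ts.subset([c for c in ts.channel_names if c in {x, y, _z}])
    trial_cc, coefs, freqs = _profile_core(
        sub, x, y, lags, window_len, mode, reg, n_fft, _z, _z_role,
        min_overlap, store_coefs=True,
    )
    cc = trial_cc.mean(axis=1)
    prof = LagCCProfile(
        lags=lags,
        cc=cc,
        window_len=window_len,
        trial_cc=trial_cc,
        coef_magnitude=coefs,
        freqs=freqs,
    )
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        null = np.empty((n_surrogates, len(lags)))
        null_trials = []
        for s in range(n_surrogates):
            surro = phase_randomize(sub, rng)
            tcc, _, _ = _profile_core(
                surro, x, y, lags, window_len, mode, reg, n_fft, _z, _z_role,
                min_overlap, store_coefs=False,
            )
            null[s] = tcc.mean(axis=1)
            null_trials.append(tcc)
        prof.null_cc = null
        prof.null_mean = null.mean(axis=0)
        prof.null_lo = np.percentile(null, ENVELOPE_PERCENTILES[0], axis=0)
        prof.null_hi = np.percentile(null, ENVELOPE_PERCENTILES[1], axis=0)
        # per-lag one-sided t-test: per-trial CC vs pooled per-trial surrogate CC
        pooled = np.concatenate(null_trials, axis=1)  # (n_lags, n_surr*n_trials)
        pvals = np.empty(len(lags))
        for i in range(len(lags)):
            pvals[i] = significance_test(trial_cc[i], pooled[i], test="t")
        prof.p_values = pvals
        prof.direction_call = _call_direction(lags, cc, null, window_len)
    return prof


def conditional_lag_cc_profile(
    ts: TimeSeriesSet,
    x: str,
    y: str,
    z: str,
    lag_range: float | tuple[float, float],
    window_len: float,
    z_role: str = "raw",
    **kwargs,
) -> LagCCProfile:
    """Lag-CC profile of (x, y) with channel ``z`` partialled out.

    ``z_role='raw'`` conditions on Z's samples at the window centers;
    ``z_role='tfr'`` conditions on Z's own z-scored TFR.
    """
    return lag_cc_profile(
        ts, x, y, lag_range, window_len, _z=z, _z_role=z_role, **kwargs
    )


@dataclass
class DrivingFrequencyReport:
    """Driving-frequency evidence at one profile lag."""

    freqs: np.ndarray
    coef_magnitude: np.ndarray
    peaks: list[tuple[float, float]]  # (frequency Hz, magnitude), sorted desc
    cc_gain_per_band: list[tuple[tuple[float, float], float]] = field(
        default_factory=list
    )
    peak_lag: float = 0.0
    cc_original: float = 0.0


def _detect_peaks(
    freqs: np.ndarray, mag: np.ndarray, rel_height: float = 0.5
) -> list[tuple[float, float]]:
    """Local maxima of the 3-bin-smoothed magnitude above rel_height * max.

    Ties are broken toward the lower frequency.
    """
    kernel = np.ones(3) / 3
    sm = np.convolve(mag, kernel, mode="same")
    peaks = []
    thr = rel_height * sm.max()
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] >= thr and sm[i] > left and sm[i] >= right:
            peaks.append((float(freqs[i]), float(sm[i])))
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return peaks


def driving_frequency_report(
    ts: TimeSeriesSet,
    x: str,
    y: str,
    peak_lag: float,
    window_len: float,
    bands: list[tuple[float, float]] | None = None,
    mode: str = "complex_then_abs",
    reg: float | None = None,
    n_fft: int | None = None,
    min_overlap: int = 50,
) -> DrivingFrequencyReport:
    """CCA-coefficient spectrum at one lag plus filter-one-frequency-out gains.

    For each band the source channel is band-stopped, the CC recomputed at
    the same lag, and the relative gain (cc_filtered - cc) / cc reported;
    genuinely informative bands give a clearly negative gain.
    """
    target_fs = ts.fs[y]
    tfr = zscore_tfr(stft_tfr(ts, x, window_len, target_fs, n_fft=n_fft))
    y_trials = ts.channel(y)
    res = lagged_cca(tfr, y_trials, peak_lag, mode=mode, reg=reg, min_overlap=min_overlap)
    peaks = _detect_peaks(tfr.freqs, res.coef_magnitude)
    gains: list[tuple[tuple[float, float], float]] = []
    for band in bands or []:
        if band[0] < tfr.freqs[0] or band[1] > tfr.freqs[-1]:
            raise ValueError(f"band {band} outside the TFR frequency range")
        filtered = bandstop_filter(ts, x, band)
        ftfr = zscore_tfr(stft_tfr(filtered, x, window_len, target_fs, n_fft=n_fft))
        fres = lagged_cca(
            ftfr, y_trials, peak_lag, mode=mode, reg=reg, min_overlap=min_overlap
        )
        gains.append((band, (fres.cc - res.cc) / res.cc))
    return DrivingFrequencyReport(
        freqs=tfr.freqs,
        coef_magnitude=res.coef_magnitude,
        peaks=peaks,
        cc_gain_per_band=gains,
        peak_lag=peak_lag,
        cc_original=res.cc,
    )


def significance_test(
    observed_cc: np.ndarray,
    null: SurrogateEnsemble | np.ndarray,
    test: str = "t",
) -> float:
    """One-sided p-value for observed CC exceeding the surrogate null."""
    obs = np.asarray(observed_cc, dtype=float).ravel()
    null_cc = null.cc_null if isinstance(null, SurrogateEnsemble) else null
    null_cc = np.asarray(null_cc, dtype=float).ravel()
    if test == "t":
        if len(obs) < 2:
            raise ValueError("t-test needs >= 2 observed values")
        return float(stats.ttest_ind(obs, null_cc, alternative="greater",
                                     equal_var=False).pvalue)
    if test == "ks":
        if len(obs) < 5 or len(null_cc) < 5:
            raise ValueError("KS test needs >= 5 samples per group")
        # 'less' tests whether the observed CDF lies below the null CDF,
        # i.e. observed values are stochastically larger
        return float(stats.ks_2samp(obs, null_cc, alternative="less").pvalue)
    raise ValueError(f"unknown test {test!r}")


def xcorr_profile(
    ts: TimeSeriesSet,
    x: str,
    y: str,
    max_lag: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged normalized lagged cross-correlation r(lag).

    ``r(lag) = corr(X(t), Y(t + lag))``: a positive-lag peak means X leads
    (X -> Y delay shows up at +delay), a negative-lag peak means Y leads.
    For mixed rates the lag grid is the *fine* (fast-channel) sample grid.
    """
    fs_x, fs_y = ts.fs[x], ts.fs[y]
    fs_fine = max(fs_x, fs_y)
    ratio_x = fs_fine / fs_x
    ratio_y = fs_fine / fs_y
    if abs(ratio_x - round(ratio_x)) > 1e-9 or abs(ratio_y - round(ratio_y)) > 1e-9:
        raise ValueError("sampling rates must be integer multiples of each other")
    kx, ky = int(round(ratio_x)), int(round(ratio_y))
    max_steps = int(round(max_lag * fs_fine))
    lags = np.arange(-max_steps, max_steps + 1)
    acc = np.zeros(len(lags))
    for xs, ys in zip(ts.channel(x), ts.channel(y)):
        nx, ny = len(xs), len(ys)
        if max_steps >= min(nx * kx, ny * ky):
            raise ValueError("max_lag exceeds the trial length")
        xs = (xs - xs.mean()) / (xs.std() or 1.0)
        ys = (ys - ys.mean()) / (ys.std() or 1.0)
        for i, d in enumerate(lags):
            # pair X at fine index j*ky - d with Y at fine index j*ky
            j = np.arange(ny)
            xf = j * ky - d
            valid = (xf >= 0) & (xf < nx * kx) & (xf % kx == 0)
            xi = xf[valid] // kx
            yi = j[valid]
            if len(xi) < 3:
                acc[i] += 0.0
                continue
            xv, yv = xs[xi], ys[yi]
            denom = xv.std() * yv.std()
            if denom == 0:
                continue
            acc[i] += float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / denom)
    return lags / fs_fine, acc / ts.n_trials
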