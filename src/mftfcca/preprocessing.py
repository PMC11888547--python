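"""Rate conversion, short-time Fourier TFRs, and per-frequency standardization.

The mixed-frequency pipeline converts the fast channel X into a complex
time-frequency representation (TFR) whose time axis is aligned with the slow
channel Y: the STFT hop equals one sample period of Y, so the moving windows
overlap by ``window_len - 1/target_fs`` and the TFR has (up to edge trimming)
one time bin per Y sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .timeseries import TimeSeriesSet

__all__ = [
    "TFR",
    "decimate",
    "stft_tfr",
    "zscore_tfr",
    "tfr_magnitude",
    "bandstop_filter",
]


@dataclass
class TFR:
    """Complex time-frequency matrix of one channel, per trial.

    values has shape (n_trials, n_time_bins, n_freqs). ``times`` holds the
    window-center times of the bins; ``align_offset`` is the number of
    leading samples of the aligned low-rate channel that fall before the
    first full window and must be dropped before pairing.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    source_fs: float
    window_len: float
    hop: float
    align_offset: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] < 0 or self.freqs[-1] > self.source_fs / 2 + 1e-9:
            raise ValueError("freqs must lie in [0, source_fs/2]")
        if self.values.shape[1] != len(self.times) or self.values.shape[2] != len(self.freqs):
            raise ValueError("values shape inconsistent with times/freqs")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "TFR":
        return TFR(
            values,
            self.times,
            self.freqs,
            self.source_fs,
            self.window_len,
            self.hop,
            self.align_offset,
            self.channel,
        )


def _antialias_sos(fs: float, cutoff: float):
    # order-8 zero-phase Butterworth; effective order doubles under filtfilt
    return signal.butter(8, cutoff, btype="low", fs=fs, output="sos")


def decimate(ts: TimeSeriesSet, channel: str, factor: int) -> TimeSeriesSet:
    """Low-pass filter one channel below the new Nyquist, then keep every
    ``factor``-th sample. The anti-alias cutoff is 0.8x the new Nyquist.
    """
    if int(factor) != factor or factor < 2:
        raise ValueError("decimation factor must be an integer >= 2")
    factor = int(factor)
    fs = ts.fs[channel]
    new_fs = fs / factor
    sos = _antialias_sos(fs, 0.8 * (new_fs / 2))  # 0.8 * new Nyquist
    out = []
    for x in ts.channel(channel):
        filtered = signal.sosfiltfilt(sos, x)
        out.append(filtered[::factor])
    return ts.with_channel(channel, out, new_fs)


def stft_tfr(
    ts: TimeSeriesSet,
    channel: str,
    window_len: float,
    target_fs: float,
    n_fft: int | None = None,
    window: str = "hann",
) -> TFR:
    """Moving-window Fourier transform with hop = one target-rate sample.

    Each frame covers ``window_len`` seconds of the source channel; frames
    advance by ``1/target_fs`` so consecutive windows overlap by
    ``window_len - 1/target_fs``. Frames are placed only where the full
    window fits, and ``align_offset`` records how many leading target-rate
    samples precede the first window center.

    ``n_fft`` defaults to 4x the window sample count (zero padding for a
    finer frequency grid).
    """
    fs = ts.fs[channel]
    if target_fs > fs + 1e-9:
        raise ValueError("target_fs must not exceed the source sampling rate")
    w = int(round(window_len * fs))
    if w < 2:
        raise ValueError("window shorter than two source samples")
    hop = int(round(fs / target_fs))
    if hop < 1:
        raise ValueError("hop shorter than one source sample")
    if hop > w:
        raise ValueError("hop larger than the window; windows would not overlap")
    if n_fft is None:
        n_fft = 4 * w
    if n_fft < w:
        raise ValueError("n_fft must be >= window sample count")
    if window == "hann":
        taper = signal.windows.hann(w, sym=False)
    elif window in ("rect", "rectangular", "boxcar"):
        taper = np.ones(w)
    else:
        taper = signal.get_window(window, w, fftbins=True)

    mats = []
    n_frames = None
    for x in ts.channel(channel):
        if len(x) < w:
            raise ValueError("window longer than the trial")
        nf = (len(x) - w) // hop + 1
        if n_frames is None:
            n_frames = nf
        nf = min(nf, n_frames)
        idx = np.arange(w)[None, :] + hop * np.arange(nf)[:, None]
        frames = x[idx] * taper
        mats.append(np.fft.rfft(frames, n=n_fft, axis=1))
    values = np.stack(mats)
    freqs = np.fft.rfftfreq(n_fft, d=1 / fs)
    centers = (np.arange(n_frames) * hop + (w - 1) / 2) / fs
    # number of target-rate samples before the first window center
    align_offset = int(round(centers[0] * target_fs))
    return TFR(
        values,
        centers,
        freqs,
        source_fs=fs,
        window_len=window_len,
        hop=1 / target_fs,
        align_offset=align_offset,
        channel=channel,
    )


def zscore_tfr(tfr: TFR) -> TFR:
    """Standardize every frequency column to zero mean and unit variance.

    Applied per trial. Complex columns keep their phase: the mean complex
    value is removed and the column is scaled by one real factor, the
    standard deviation of the complex samples. Zero-variance columns are set
    to zero with a warning.
    """
    if tfr.n_bins < 2:
        raise ValueError("need at least two time bins per frequency")
    vals = tfr.values
    mean = vals.mean(axis=1, keepdims=True)
    centered = vals - mean
    std = np.sqrt(np.mean(np.abs(centered) ** 2, axis=1, keepdims=True))
    degenerate = std < 1e-300
    if np.any(degenerate):
        warnings.warn("zero-variance frequency column(s) left at zero", RuntimeWarning)
        std = np.where(degenerate, 1.0, std)
        centered = np.where(degenerate, 0.0, centered)
    return tfr.copy_with(centered / std)


def tfr_magnitude(tfr: TFR) -> TFR:
    """Elementwise modulus of the TFR (real-valued output)."""
    return tfr.copy_with(np.abs(tfr.values))


def bandstop_filter(ts: TimeSeriesSet, channel: str, band: tuple[float, float]) -> TimeSeriesSet:
    """Zero-phase spectral band-stop on one channel.

    Implemented as Fourier-domain surgery (the rfft bins inside the band are
    zeroed), which is exactly zero-phase, exactly transparent outside the
    band and idempotent -- the properties the filter-one-frequency-out
    attribution step relies on. Removing a band that carries causal
    information must reduce the canonical correlation.
    """
    low, high = band
    fs = ts.fs[channel]
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs/2}) or ill-ordered")
    out = []
    for x in ts.channel(channel):
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(len(x), d=1 / fs)
        spec[(freqs >= low) & (freqs <= high)] = 0.0
        out.append(np.fft.irfft(spec, n=len(x)))
    return ts.with_channel(channel, out, fs)
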