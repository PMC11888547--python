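"""Multi-trial, multichannel time-series container with per-channel sampling rates.

The central in-memory object of the package. Channels may be sampled at
different rates (mixed frequency, MF), in which case their per-trial sample
counts differ in the ratio of the rates. Each trial is stored as a mapping
``channel name -> 1-D float array`` so that channels of unequal length can
coexist within one trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["TimeSeriesSet"]


@dataclass
class TimeSeriesSet:
    """Multi-trial recording, one array per channel per trial.

    Parameters
    ----------
    trials
        Sequence of trials; each trial maps channel name to a 1-D array.
    fs
        Sampling rate in Hz per channel.

    Channels sharing a sampling rate must have identical sample counts within
    a trial; channels with different rates must have counts in the ratio of
    the rates (to within one sample).
    """

    trials: list[dict[str, np.ndarray]]
    fs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = [
            {name: np.asarray(x, dtype=float).ravel() for name, x in trial.items()}
            for trial in self.trials
        ]
        if not self.trials:
            raise ValueError("TimeSeriesSet needs at least one trial")
        names = set(self.trials[0])
        for t, trial in enumerate(self.trials):
            if set(trial) != names:
                raise ValueError(f"trial {t} has channels {set(trial)}, expected {names}")
        missing = names - set(self.fs)
        if missing:
            raise ValueError(f"missing sampling rate for channels {sorted(missing)}")
        for name, rate in self.fs.items():
            if not rate > 0:
                raise ValueError(f"non-positive sampling rate for channel {name!r}")
        self._validate_sample_ratios()

    def _validate_sample_ratios(self) -> None:
        for t, trial in enumerate(self.trials):
            items = sorted(trial.items())
            for i, (na, xa) in enumerate(items):
                for nb, xb in items[i + 1 :]:
                    ra, rb = self.fs[na], self.fs[nb]
                    expected = len(xa) * rb / ra
                    if abs(len(xb) - expected) > 1.0 + 1e-9:
                        raise ValueError(
                            f"trial {t}: channels {na!r} ({len(xa)} samples @ {ra} Hz) and "
                            f"{nb!r} ({len(xb)} samples @ {rb} Hz) violate the rate ratio"
                        )

    # -- accessors ---------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.trials[0])

    def channel(self, name: str) -> list[np.ndarray]:
        """All trials of one channel, as a list of 1-D arrays."""
        return [trial[name] for trial in self.trials]

    def times(self, name: str, trial: int = 0) -> np.ndarray:
        """Sample times (s) of one channel in one trial."""
        n = len(self.trials[trial][name])
        return np.arange(n) / self.fs[name]

    def with_channel(self, name: str, data: Iterable[np.ndarray], fs: float) -> "TimeSeriesSet":
        """Return a copy with one channel replaced (or added)."""
        data = list(data)
        if len(data) != self.n_trials:
            raise ValueError("replacement must supply one array per trial")
        trials = []
        for trial, x in zip(self.trials, data):
            new = dict(trial)
            new[name] = np.asarray(x, dtype=float).ravel()
            trials.append(new)
        rates = dict(self.fs)
        rates[name] = float(fs)
        return TimeSeriesSet(trials, rates)

    def subset(self, names: Sequence[str]) -> "TimeSeriesSet":
        trials = [{n: trial[n] for n in names} for trial in self.trials]
        return TimeSeriesSet(trials, {n: self.fs[n] for n in names})

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        fs: float | Mapping[str, float],
        channel_names: Sequence[str] | None = None,
    ) -> "TimeSeriesSet":
        """Build from an equal-rate array of shape (trials, samples, channels)."""
        data = np.asarray(data, dtype=float)
        if data.ndim == 2:
            data = data[None]
        n_ch = data.shape[2]
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(n_ch)]
        if np.isscalar(fs) or isinstance(fs, (int, float)):
            rates = {name: float(fs) for name in channel_names}
        else:
            rates = {name: float(fs[name]) for name in channel_names}
        trials = [
            {name: data[t, :, i] for i, name in enumerate(channel_names)}
            for t in range(data.shape[0])
        ]
        return cls(trials, rates)

    def to_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack equal-rate channels into shape (trials, samples, channels)."""
        if names is None:
            names = self.channel_names
        rates = {self.fs[n] for n in names}
        if len(rates) != 1:
            raise ValueError("to_array requires channels with a common sampling rate")
        return np.stack(
            [np.stack([trial[n] for n in names], axis=-1) for trial in self.trials]
        )
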