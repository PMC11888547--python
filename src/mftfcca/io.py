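"""Reading and writing time-series sets, configuration, and result records.

On-disk layout for a :class:`~mftfcca.timeseries.TimeSeriesSet`:

* one delimited-text file per trial and sampling-rate group (channels that
  share a rate share a file; header row = channel names), plus a YAML
  sidecar ``meta.yaml`` recording the rate of every channel, the trial
  count, and the file map;
* alternatively a single ``.npz`` container for bulk use.

Result objects (profiles, reports) serialize to plain dict records that are
written as YAML and/or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import DrivingFrequencyReport, LagCCProfile
from .timeseries import TimeSeriesSet

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "RunConfig",
    "profile_record",
    "report_record",
    "write_record",
]

SIDECAR_NAME = "meta.yaml"


def _rate_groups(ts: TimeSeriesSet) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for name in ts.channel_names:
        key = f"{ts.fs[name]:g}Hz"
        groups.setdefault(key, []).append(name)
    return groups


def write_timeseries(ts: TimeSeriesSet, path: str | Path, fmt: str = "csv") -> Path:
    """Serialize a time-series set to ``path`` (directory for csv, file for npz)."""
    path = Path(path)
    if fmt == "npz":
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name in ts.channel_names:
            arrays[f"data_{name}"] = np.stack(ts.channel(name))
        arrays["_fs_json"] = np.frombuffer(
            json.dumps(ts.fs).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)
        return path
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    path.mkdir(parents=True, exist_ok=True)
    groups = _rate_groups(ts)
    files: dict[str, list[str]] = {}
    for key, names in groups.items():
        files[key] = []
        for t in range(ts.n_trials):
            fname = f"trial{t:03d}_{key}.csv"
            df = pd.DataFrame({n: ts.trials[t][n] for n in names})
            df.to_csv(path / fname, index=False)
            files[key].append(fname)
    sidecar = {
        "n_trials": ts.n_trials,
        "fs": {name: float(ts.fs[name]) for name in ts.channel_names},
        "files": files,
    }
    (path / SIDECAR_NAME).write_text(yaml.safe_dump(sidecar))
    return path


def read_timeseries(path: str | Path) -> TimeSeriesSet:
    """Load a set written by :func:`write_timeseries` (csv directory or npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            fs = json.loads(bytes(npz["_fs_json"]).decode())
            names = [k[5:] for k in npz.files if k.startswith("data_")]
            n_trials = npz[f"data_{names[0]}"].shape[0]
            trials = [
                {name: npz[f"data_{name}"][t] for name in names}
                for t in range(n_trials)
            ]
        return TimeSeriesSet(trials, {k: float(v) for k, v in fs.items()})
    sidecar_path = path / SIDECAR_NAME if path.is_dir() else path
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no sidecar found at {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    for key in ("n_trials", "fs", "files"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    base = sidecar_path.parent
    trials: list[dict[str, np.ndarray]] = [dict() for _ in range(meta["n_trials"])]
    for _, fnames in meta["files"].items():
        if len(fnames) != meta["n_trials"]:
            raise ValueError("file count does not match n_trials")
        for t, fname in enumerate(fnames):
            df = pd.read_csv(base / fname)
            for col in df.columns:
                trials[t][col] = df[col].to_numpy(dtype=float)
    return TimeSeriesSet(trials, {k: float(v) for k, v in meta["fs"].items()})


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    x: str
    y: str
    z: str | None = None
    system: str | None = None  # simulator name, or None when reading files
    input_path: str | None = None
    n_trials: int = 100
    duration: float = 20.0
    decimate_channel: str | None = None
    decimate_factor: int = 1
    window_len: float = 0.15
    lag_range: float = 0.5
    n_surrogates: int = 100
    mode: str = "complex_then_abs"
    reg: float | None = None
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.system is None and self.input_path is None:
            raise ValueError("config needs either a simulator system or an input path")
        if self.system is not None and self.seed is None:
            raise ValueError("simulation runs require a seed")
        if self.window_len <= 0 or self.lag_range <= 0:
            raise ValueError("window_len and lag_range must be positive")
        if self.mode not in ("complex_then_abs", "abs_then_cca"):
            raise ValueError(f"unknown CCA mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def profile_record(prof: LagCCProfile) -> dict:
    """Plain-dict (YAML/JSON-safe) record of a lag-CC profile."""
    rec = {
        "lags_s": prof.lags.tolist(),
        "cc": prof.cc.tolist(),
        "window_len_s": prof.window_len,
        "direction_call": prof.direction_call,
    }
    for key in ("null_mean", "null_lo", "null_hi", "p_values"):
        val = getattr(prof, key)
        rec[key] = None if val is None else np.asarray(val).tolist()
    return rec


def report_record(rep: DrivingFrequencyReport) -> dict:
    return {
        "peak_lag_s": rep.peak_lag,
        "cc_original": rep.cc_original,
        "freqs_hz": rep.freqs.tolist(),
        "coef_magnitude": rep.coef_magnitude.tolist(),
        "peaks": [{"freq_hz": f, "magnitude": m} for f, m in rep.peaks],
        "cc_gain_per_band": [
            {"band_hz": list(band), "relative_gain": g}
            for band, g in rep.cc_gain_per_band
        ],
    }


def write_record(record: dict, path: str | Path) -> None:
    """Write a record as YAML (and a JSON twin for machine consumption)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(record, sort_keys=False))
    path.with_suffix(".json").write_text(json.dumps(record, indent=1))
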