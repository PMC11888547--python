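"""Nonlinear benchmark systems.

Four generators with qualitatively different coupling mechanisms:

* phase-amplitude coupling (PAC): a slow oscillation X0 modulates the
  envelope of a fast carrier, so the causal information toward Y lives in
  the *spectral power* of the observed X, not in its raw fluctuations;
* memoryless amplitude modulation (sigmoid or cosine squashing of one
  channel);
* the two-species coupled Logistic map (chaotic, discrete time);
* the coupled Rossler-Lorenz system (continuous-time chaos, the Rossler
  x2 component driving the Lorenz y2 equation through C * x2^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeriesSet
from .var_simulator import VARModel, simulate_var

__all__ = [
    "PACConfig",
    "LogisticConfig",
    "RosslerLorenzConfig",
    "simulate_pac",
    "amplitude_modulate",
    "simulate_logistic",
    "logistic_unidirectional",
    "logistic_bidirectional",
    "simulate_rossler_lorenz",
]


@dataclass(frozen=True)
class PACConfig:
    """Phase-amplitude coupling: slow phase carrier f0, fast amplitude carrier fa."""

    f0: float = 4.0
    fa: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.fa:
            raise ValueError("need 0 < f0 < fa")


def simulate_pac(
    base_model: VARModel,
    cfg: PACConfig = PACConfig(),
    n_trials: int = 100,
    duration: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> TimeSeriesSet:
    """Simulate (X0, Y) from a bivariate VAR, then emit X = (X0 + c) sin(2 pi fa t).

    The offset c = -min X0 is computed per trial so the envelope is
    non-negative; the causal X0 <-> Y structure is thereby hidden in the
    amplitude of the fa-carrier.
    """
    if base_model.n_vars != 2:
        raise ValueError("base model must be bivariate (X0, Y)")
    if cfg.fa >= base_model.fs / 2:
        raise ValueError(
            f"amplitude carrier {cfg.fa} Hz at/above Nyquist ({base_model.fs / 2} Hz)"
        )
    raw = simulate_var(base_model, n_trials, duration, seed)
    x_name, y_name = base_model.channel_names
    t = raw.times(x_name)
    carrier = np.sin(2 * np.pi * cfg.fa * t)
    modulated = []
    for x0 in raw.channel(x_name):
        const = -x0.min()
        modulated.append((x0 + const) * carrier)
    return raw.with_channel(x_name, modulated, base_model.fs)


def amplitude_modulate(
    ts: TimeSeriesSet,
    channel: str,
    kind: str = "sigmoid",
    gain: float = 2.0,
    scale: float = np.pi,
) -> TimeSeriesSet:
    """Apply a memoryless nonlinearity samplewise to one channel.

    kind "sigmoid": 1 / (1 + exp(-gain * x)); kind "cosine": cos(scale * x).
    """
    if kind == "sigmoid":
        fn = lambda x: 1.0 / (1.0 + np.exp(-gain * x))  # noqa: E731
    elif kind == "cosine":
        fn = lambda x: np.cos(scale * x)  # noqa: E731
    else:
        raise ValueError(f"unknown modulation kind {kind!r}")
    if not (np.isfinite(gain) and np.isfinite(scale)):
        raise ValueError("modulation parameters must be finite")
    out = [fn(x) for x in ts.channel(channel)]
    return ts.with_channel(channel, out, ts.fs[channel])


@dataclass(frozen=True)
class LogisticConfig:
    """Coupled two-species logistic map.

    X(t+1) = X(t) [rx - rx X(t) - gxy Y(t)],
    Y(t+1) = Y(t) [ry - ry Y(t) - gyx X(t)].
    """

    rx: float = 3.7
    ry: float = 3.8
    gamma_xy: float = 0.0
    gamma_yx: float = 0.0
    n_steps: int = 1000
    transient: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.rx <= 4 and 0 < self.ry <= 4):
            raise ValueError("self-regulation rates must be in (0, 4]")
        if self.gamma_xy < 0 or self.gamma_yx < 0:
            raise ValueError("coupling constants must be >= 0")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")


def logistic_unidirectional(n_steps: int = 1000, transient: int = 100) -> LogisticConfig:
    """X -> Y only (gamma_xy = 0, gamma_yx = 0.32)."""
    return LogisticConfig(gamma_xy=0.0, gamma_yx=0.32, n_steps=n_steps, transient=transient)


def logistic_bidirectional(n_steps: int = 1000, transient: int = 100) -> LogisticConfig:
    """Bidirectional coupling (gamma_xy = 0.02, gamma_yx = 0.1)."""
    return LogisticConfig(gamma_xy=0.02, gamma_yx=0.1, n_steps=n_steps, transient=transient)


def simulate_logistic(
    cfg: LogisticConfig,
    seed: int | np.random.Generator = 0,
    n_trials: int = 1,
    fs: float = 1.0,
) -> TimeSeriesSet:
    """Iterate the coupled map from uniform [0,1] initial conditions.

    The first ``cfg.transient`` points are discarded. Divergence (|state|
    exceeding 10) raises with the offending step index.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        x, y = rng.uniform(0, 1, size=2)
        total = cfg.n_steps + cfg.transient
        xs = np.empty(total)
        ys = np.empty(total)
        for i in range(total):
            xs[i], ys[i] = x, y
            x_new = x * (cfg.rx - cfg.rx * x - cfg.gamma_xy * y)
            y_new = y * (cfg.ry - cfg.ry * y - cfg.gamma_yx * x)
            if abs(x_new) > 10 or abs(y_new) > 10:
                raise FloatingPointError(f"logistic map diverged at step {i + 1}")
            x, y = x_new, y_new
        trials.append({"x": xs[cfg.transient :], "y": ys[cfg.transient :]})
    return TimeSeriesSet(trials, {"x": fs, "y": fs})


@dataclass(frozen=True)
class RosslerLorenzConfig:
    """Rossler (timescale alpha) unidirectionally driving Lorenz via C * x2^2."""

    alpha: float = 6.0
    C: float = 2.0
    fs: float = 100.0
    duration: float = 60.0
    transient: float = 10.0
    substeps: int = 20  # RK4 steps per output sample

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.duration > self.transient >= 0:
            raise ValueError("need duration > transient >= 0")


def _rossler_lorenz_rhs(state: np.ndarray, alpha: float, C: float) -> np.ndarray:
    x1, x2, x3, y1, y2, y3 = state
    return np.array(
        [
            -alpha * (x2 + x3),
            alpha * (x1 + 0.2 * x2),
            alpha * (0.2 + x3 * (x1 - 5.7)),
            10.0 * (-y1 + y2),
            28.0 * y1 - y2 - y1 * y3 + C * x2**2,
            y1 * y2 - (8.0 / 3.0) * y3,
        ]
    )


def simulate_rossler_lorenz(
    cfg: RosslerLorenzConfig = RosslerLorenzConfig(),
    seed: int | np.random.Generator = 0,
    n_trials: int = 1,
) -> TimeSeriesSet:
    """Integrate the six coupled ODEs with fixed-step classical RK4.

    The integrator step is ``1 / (substeps * fs)`` and the trajectory is
    stride-sampled at ``fs``; the fixed step keeps runs bit-reproducible.
    Initial values are drawn from the seed (uniform in [-1, 1] around the
    Lorenz/Rossler operating ranges). The first ``transient`` seconds are
    dropped.
    """
    rng = np.random.default_rng(seed)
    h = 1.0 / (cfg.substeps * cfg.fs)
    n_out = int(round(cfg.duration * cfg.fs))
    n_skip = int(round(cfg.transient * cfg.fs))
    names = ["x1", "x2", "x3", "y1", "y2", "y3"]
    trials = []
    for _ in range(n_trials):
        state = rng.uniform(-1, 1, size=6) + np.array([0, 0, 0, 1, 1, 20.0])
        traj = np.empty((n_out, 6))
        for i in range(n_out):
            for _ in range(cfg.substeps):
                k1 = _rossler_lorenz_rhs(state, cfg.alpha, cfg.C)
                k2 = _rossler_lorenz_rhs(state + 0.5 * h * k1, cfg.alpha, cfg.C)
                k3 = _rossler_lorenz_rhs(state + 0.5 * h * k2, cfg.alpha, cfg.C)
                k4 = _rossler_lorenz_rhs(state + h * k3, cfg.alpha, cfg.C)
                state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(state)):
                raise FloatingPointError(
                    f"non-finite state at t={i / cfg.fs:.3f} s of the integration"
                )
            traj[i] = state
        traj = traj[n_skip:]
        trials.append({name: traj[:, j] for j, name in enumerate(names)})
    return TimeSeriesSet(trials, {name: cfg.fs for name in names})
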