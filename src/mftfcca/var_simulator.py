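"""Vector-autoregressive benchmark systems and their simulation.

A :class:`VARModel` is defined by the recursion

    theta_t = sum_{tau=1..r} A_tau theta_{t-tau} + e_t,

with ``e_t`` white Gaussian noise. The diagonal blocks of the ``A_tau`` are
built from complex-conjugate pole pairs: a pole with modulus ``r_i`` and
frequency ``f_i`` contributes the AR(2) factor

    1 - 2 r_i cos(theta_i) z + r_i^2 z^2,   theta_i = 2 pi f_i / fs,

so a channel with two pole pairs is an AR(4) oscillator with resonances at
f_1 and f_2. Off-diagonal entries inject directed (Granger-causal) influence
from one channel into another at specific lags. The module ships the factory
functions for the benchmark systems used throughout the package: two
unidirectional bivariate VAR(4) systems, a bidirectional VAR(41) system with
distinct causal lags per direction, trivariate chain and parallel VAR(4)
systems, and a generic trivariate VAR(3) oscillator network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeriesSet

__all__ = [
    "PolePair",
    "VARModel",
    "simulate_var",
    "make_unidirectional_xy",
    "make_unidirectional_yx",
    "make_bidirectional_var41",
    "make_chain_system",
    "make_parallel_system",
    "make_stokes_var3",
]


@dataclass(frozen=True)
class PolePair:
    """Complex-conjugate pole pair of an AR oscillator.

    modulus in (0, 1) sets the resonance sharpness; frequency (Hz) sets the
    oscillation, and must lie below the Nyquist rate of the model it is
    instantiated against.
    """

    modulus: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0 < self.modulus < 1:
            raise ValueError(f"pole modulus must be in (0,1), got {self.modulus}")
        if self.frequency < 0:
            raise ValueError("pole frequency must be non-negative")

    def angle(self, fs: float) -> float:
        if self.frequency >= fs / 2:
            raise ValueError(
                f"pole frequency {self.frequency} Hz is at/above Nyquist for fs={fs} Hz"
            )
        return 2 * np.pi * self.frequency / fs


def ar_coeffs_from_poles(poles: list[PolePair], fs: float) -> np.ndarray:
    """AR coefficients a_1..a_{2m} of the product of AR(2) pole factors.

    Returns the plus-sign convention coefficients: x_t = sum a_k x_{t-k} + e_t.
    """
    poly = np.array([1.0])
    for p in poles:
        th = p.angle(fs)
        poly = np.convolve(poly, [1.0, -2 * p.modulus * np.cos(th), p.modulus**2])
    return -poly[1:]


@dataclass
class VARModel:
    """Stable VAR(r) model: coefficients, innovation covariance, sampling rate."""

    coeffs: np.ndarray  # shape (order, n_vars, n_vars)
    noise_cov: np.ndarray | None = None
    fs: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (order, n, n)")
        n = self.coeffs.shape[1]
        if self.noise_cov is None:
            self.noise_cov = np.eye(n)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n)]
        if len(self.channel_names) != n:
            raise ValueError("channel_names length mismatch")
        rad = self.spectral_radius()
        if rad >= 1.0:
            raise ValueError(
                f"unstable VAR model: companion spectral radius {rad:.4f} >= 1"
            )

    @property
    def n_vars(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion(self) -> np.ndarray:
        r, n, _ = self.coeffs.shape
        comp = np.zeros((n * r, n * r))
        comp[:n, :] = self.coeffs.transpose(1, 0, 2).reshape(n, n * r)
        if r > 1:
            comp[n:, :-n] = np.eye(n * (r - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def autocovariance(self, n_lags: int) -> np.ndarray:
        """Stationary autocovariance Gamma_k, k = 0..n_lags, shape (n_lags+1, n, n).

        Solved exactly from the companion-form discrete Lyapunov equation.
        """
        from scipy.linalg import solve_discrete_lyapunov

        r, n, _ = self.coeffs.shape
        comp = self.companion()
        V = np.zeros_like(comp)
        V[:n, :n] = self.noise_cov
        P = solve_discrete_lyapunov(comp, V)
        P = (P + P.T) / 2
        gammas = np.empty((n_lags + 1, n, n))
        state = P
        gammas[0] = state[:n, :n]
        for k in range(1, n_lags + 1):
            state = comp @ state
            gammas[k] = state[:n, :n]
        return gammas


def simulate_var(
    model: VARModel,
    n_trials: int,
    duration: float,
    seed: int | np.random.Generator,
    burn_in: int = 500,
) -> TimeSeriesSet:
    """Simulate independent Gaussian-driven trials of a stable VAR model.

    Parameters
    ----------
    duration
        Trial length in seconds; the output has ``round(duration * fs)``
        samples per channel after ``burn_in`` initial samples are discarded.
    seed
        Integer seed or a Generator; trials are reproducible bit-for-bit.
    """
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    n_samples = int(round(duration * model.fs))
    r, n, _ = model.coeffs.shape
    if n_samples < r:
        raise ValueError("duration too short for the model order")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.noise_cov)
    total = n_samples + burn_in
    # all trials advance in lockstep (vectorized over the trial axis)
    e = rng.standard_normal((n_trials, total, n)) @ chol.T
    x = np.zeros((n_trials, total + r, n))
    coeffs_t = model.coeffs.transpose(0, 2, 1)  # A_tau^T for right-multiplication
    for i in range(total):
        acc = e[:, i, :].copy()
        for tau in range(1, r + 1):
            acc += x[:, r + i - tau, :] @ coeffs_t[tau - 1]
        x[:, r + i, :] = acc
    return TimeSeriesSet.from_array(
        x[:, r + burn_in :, :], model.fs, model.channel_names
    )


# ---------------------------------------------------------------------------
# Factory systems
# ---------------------------------------------------------------------------

_FS_BENCH = 200.0

# Shared oscillator definitions of the bivariate unidirectional systems:
# X resonates at 80 Hz (r=0.9) and 4 Hz (r=0.8); Y at 15 Hz (r=0.85) and
# 2 Hz (r=0.7).
_X_POLES = [PolePair(0.9, 80.0), PolePair(0.8, 4.0)]
_Y_POLES = [PolePair(0.85, 15.0), PolePair(0.7, 2.0)]


def _bivariate_var4(cross: dict[tuple[int, int, int], float]) -> VARModel:
    A = np.zeros((4, 2, 2))
    A[:, 0, 0] = ar_coeffs_from_poles(_X_POLES, _FS_BENCH)
    A[:, 1, 1] = ar_coeffs_from_poles(_Y_POLES, _FS_BENCH)
    for (tau, i, j), val in cross.items():
        A[tau - 1, i, j] = val
    return VARModel(A, fs=_FS_BENCH, channel_names=["x", "y"])


def make_unidirectional_xy() -> VARModel:
    """Bivariate VAR(4) in which X drives Y (lags 1-3, entries -0.4, 0.7, -0.1)."""
    return _bivariate_var4({(1, 1, 0): -0.4, (2, 1, 0): 0.7, (3, 1, 0): -0.1})


def make_unidirectional_yx() -> VARModel:
    """Bivariate VAR(4) in which Y drives X (lags 1-3, entries 0.05, -0.05, 0.1)."""
    return _bivariate_var4({(1, 0, 1): 0.05, (2, 0, 1): -0.05, (3, 0, 1): 0.1})


#: 11-tap band-pass impulse response carrying the Y->X influence of the
#: bidirectional VAR(41) system, spread over lags 31..41.
BIDIRECTIONAL_BANDPASS_TAPS = [
    0.000, 0.001, -0.014, -0.039, 0.026, 0.098, 0.026, -0.039, -0.014, 0.001, 0.000,
]


def make_bidirectional_var41() -> VARModel:
    """Bivariate VAR(41) with X->Y at a 0.1 s lag and Y->X at a 0.15 s lag.

    X oscillates at 4 Hz (r=0.8) and Y at 15 Hz (r=0.9); both resonances sit
    in the low-frequency band so the bidirectional coupling survives
    down-sampling of Y. The X->Y influence enters through lags 21-23
    (-0.175, 0.35, -0.175); the Y->X influence through the band-pass taps at
    lags 31-41.
    """
    fs = _FS_BENCH
    A = np.zeros((41, 2, 2))
    A[:2, 0, 0] = ar_coeffs_from_poles([PolePair(0.8, 4.0)], fs)
    A[:2, 1, 1] = ar_coeffs_from_poles([PolePair(0.9, 15.0)], fs)
    A[20, 1, 0] = -0.175
    A[21, 1, 0] = 0.35
    A[22, 1, 0] = -0.175
    for i, tap in enumerate(BIDIRECTIONAL_BANDPASS_TAPS):
        A[30 + i, 0, 1] = tap
    return VARModel(A, fs=fs, channel_names=["x", "y"])


_TRI_POLES = {
    "x1": [PolePair(0.95, 80.0), PolePair(0.7, 5.0)],
    "x2": [PolePair(0.85, 15.0)],
    "y": [PolePair(0.85, 10.0), PolePair(0.7, 2.0)],
}


def _trivariate_var4(cross: dict[tuple[int, int, int], float]) -> VARModel:
    A = np.zeros((4, 3, 3))
    for i, name in enumerate(["x1", "x2", "y"]):
        a = ar_coeffs_from_poles(_TRI_POLES[name], _FS_BENCH)
        A[: len(a), i, i] = a
    for (tau, i, j), val in cross.items():
        A[tau - 1, i, j] = val
    return VARModel(A, fs=_FS_BENCH, channel_names=["x1", "x2", "y"])


def make_chain_system() -> VARModel:
    """Trivariate VAR(4) chain X1 -> X2 -> Y (X1->X2 strong, X2->Y moderate)."""
    return _trivariate_var4(
        {
            (1, 1, 0): -0.7, (2, 1, 0): 1.5, (3, 1, 0): 1.0,  # X1 -> X2
            (1, 2, 1): -0.3, (2, 2, 1): 0.4, (3, 2, 1): -0.3,  # X2 -> Y
        }
    )


def make_parallel_system() -> VARModel:
    """Trivariate VAR(4) parallel system X1 -> Y (weak) and X2 -> Y (strong)."""
    return _trivariate_var4(
        {
            (1, 2, 0): -0.4, (2, 2, 0): 0.7, (3, 2, 0): -0.1,  # X1 -> Y
            (1, 2, 1): -0.8, (2, 2, 1): 1.5, (3, 2, 1): -1.0,  # X2 -> Y
        }
    )


def make_stokes_var3() -> VARModel:
    """Trivariate VAR(3) oscillator chain x1 -> x2 -> x3 at 120 Hz.

    Oscillators at 40, 10 and 50 Hz with moduli 0.9, 0.7 and 0.8; couplings
    x1->x2 (-0.356 at lags 1 and 3, 0.7136 at lag 2) and x2->x3 (-0.3098 at
    lags 1 and 3, 0.5 at lag 2).
    """
    fs = 120.0
    poles = [PolePair(0.9, 40.0), PolePair(0.7, 10.0), PolePair(0.8, 50.0)]
    A = np.zeros((3, 3, 3))
    for i, p in enumerate(poles):
        A[:2, i, i] = ar_coeffs_from_poles([p], fs)
    A[0, 1, 0] = -0.356
    A[1, 1, 0] = 0.7136
    A[2, 1, 0] = -0.356
    A[0, 2, 1] = -0.3098
    A[1, 2, 1] = 0.5
    A[2, 2, 1] = -0.3098
    return VARModel(A, fs=fs, channel_names=["x1", "x2", "x3"])
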