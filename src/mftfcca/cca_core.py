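"""Regularized, lagged and partial canonical correlation analysis.

CCA between variable sets X (samples x p) and Y (samples x q) maximizes
corr(Xu, Yv) over weight vectors u, v. It is solved here through the
generalized eigenproblem on the (optionally ridge-regularized) covariance
blocks: with S_xx, S_yy the within-set and S_xy the between-set covariance,
the leading eigenvalue of

    (S_xx + reg I)^{-1} S_xy (S_yy + reg I)^{-1} S_yx

is the squared canonical correlation rho^2 and its eigenvector is u. The
complex variant uses Hermitian (conjugate-transpose) covariances, which
makes rho invariant to per-column phase rotations of X. Partial CCA first
removes the linear influence of a conditioning set Z from every covariance
block: S_{uv|z} = S_uv - S_uz S_zz^{-1} S_zv.

The lagged variant pairs the time-frequency representation of a fast channel
with a shifted slow channel; by convention a *negative* lag means the TFR
window precedes the slow sample (evidence for X driving Y) and a positive
lag means the slow sample precedes the window (Y driving X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocessing import TFR

__all__ = ["CCAResult", "cca", "cca_complex", "partial_cca", "lagged_cca"]

#: ridge scale applied to the mean covariance diagonal when reg is None
DEFAULT_REG_SCALE = 1e-3


@dataclass
class CCAResult:
    """Leading canonical pair: correlation, weights, per-frequency magnitudes."""

    cc: float
    u: np.ndarray
    v: np.ndarray
    coef_magnitude: np.ndarray
    n_samples: int
    regularization: float
    trial_cc: np.ndarray | None = field(default=None, repr=False)
    trial_coef_magnitude: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.cc <= 1 + 1e-9:
            raise ValueError(f"canonical correlation {self.cc} outside [0, 1]")
        self.cc = float(min(self.cc, 1.0))


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    return a.conj().T @ b / (n - 1)


def _resolve_reg(reg: float | None, sxx: np.ndarray, syy: np.ndarray) -> tuple[float, float]:
    if reg is not None:
        if reg < 0:
            raise ValueError("regularization must be >= 0")
        return float(reg), float(reg)
    rx = DEFAULT_REG_SCALE * float(np.real(np.trace(sxx)) / sxx.shape[0])
    ry = DEFAULT_REG_SCALE * float(np.real(np.trace(syy)) / syy.shape[0])
    return rx, ry


def _fix_phase(u: np.ndarray) -> np.ndarray:
    k = int(np.argmax(np.abs(u)))
    pivot = u[k]
    if np.abs(pivot) > 0:
        u = u * (np.conj(pivot) / np.abs(pivot))
    if np.iscomplexobj(u) and np.allclose(u.imag, 0):
        u = u.real.astype(float) if not np.isrealobj(u) else u
    return u


def _cca_from_cov(
    sxx: np.ndarray,
    sxy: np.ndarray,
    syy: np.ndarray,
    reg: float | None,
    n_samples: int,
) -> CCAResult:
    rx, ry = _resolve_reg(reg, sxx, syy)
    p, q = sxy.shape
    sxx_r = sxx + rx * np.eye(p)
    syy_r = syy + ry * np.eye(q)
    try:
        lx = np.linalg.cholesky(sxx_r)
        ly = np.linalg.cholesky(syy_r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "rank-deficient within-set covariance; pass reg > 0 to regularize"
        ) from exc
    # K = Lx^{-1} Sxy Ly^{-H}; singular values of K are the canonical correlations
    k = linalg.solve_triangular(lx, sxy, lower=True)
    k = linalg.solve_triangular(ly, k.conj().T, lower=True).conj().T
    uu, svals, vh = np.linalg.svd(k)
    cc = float(min(svals[0], 1.0))
    u = linalg.solve_triangular(lx.conj().T, uu[:, 0], lower=False)
    v = linalg.solve_triangular(ly.conj().T, vh[0].conj(), lower=False)
    u = _fix_phase(u / np.linalg.norm(u))
    v = _fix_phase(v / np.linalg.norm(v))
    # canonical loadings: |corr| of each first-set variable with the second
    # set's canonical variate -- the interpretable per-frequency profile
    # (raw whitened weights u are kept but are dominated by cancellation
    # artifacts whenever neighbouring columns are collinear, e.g. on a
    # zero-padded STFT grid)
    var_yv = float(np.real(v.conj() @ syy @ v))
    diag_x = np.clip(np.real(np.diag(sxx)), 1e-300, None)
    loadings = np.abs(sxy @ v) / np.sqrt(diag_x * max(var_yv, 1e-300))
    return CCAResult(
        cc=cc,
        u=u,
        v=v,
        coef_magnitude=np.minimum(loadings, 1.0),
        n_samples=n_samples,
        regularization=rx,
    )


def cca(X: np.ndarray, Y: np.ndarray, reg: float | None = None) -> CCAResult:
    """Leading canonical correlation between two real variable sets.

    With a univariate Y and ``reg=0``, ``cc**2`` equals the coefficient of
    determination of the least-squares regression of Y on X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"sample counts differ: {X.shape[0]} vs {Y.shape[0]}")
    Xc, Yc = _center(X), _center(Y)
    return _cca_from_cov(_cov(Xc, Xc), _cov(Xc, Yc), _cov(Yc, Yc), reg, X.shape[0])


def cca_complex(
    X: np.ndarray,
    Y: np.ndarray,
    mode: str = "complex_then_abs",
    reg: float | None = None,
) -> CCAResult:
    """CCA between a complex set X and a real set Y.

    mode "complex_then_abs": Hermitian-covariance CCA with complex weights;
    ``coef_magnitude`` holds the canonical loading moduli and the
    correlation is the modulus of the leading canonical value. mode
    "abs_then_cca": replace X by its elementwise modulus and run real CCA.
    """
    if mode == "abs_then_cca":
        return cca(np.abs(X), np.asarray(Y, dtype=float), reg)
    if mode != "complex_then_abs":
        raise ValueError(f"unknown mode {mode!r}")
    X = np.atleast_2d(np.asarray(X, dtype=complex))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"sample counts differ: {X.shape[0]} vs {Y.shape[0]}")
    Xc, Yc = _center(X), _center(Y.astype(complex))
    res = _cca_from_cov(_cov(Xc, Xc), _cov(Xc, Yc), _cov(Yc, Yc), reg, X.shape[0])
    return res


def partial_cca(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    reg: float | None = None,
) -> CCAResult:
    """CCA between X and Y after removing the linear influence of Z.

    All variables are standardized column-wise first; constant columns of Z
    are dropped (they carry no conditioning information).
    """
    X = np.atleast_2d(np.asarray(X))
    Y = np.atleast_2d(np.asarray(Y))
    Z = np.atleast_2d(np.asarray(Z))
    for name, a in (("X", X), ("Y", Y), ("Z", Z)):
        if a.shape[0] == 1:
            a = a.T
        if name == "X":
            X = a
        elif name == "Y":
            Y = a
        else:
            Z = a
    n = X.shape[0]
    if Y.shape[0] != n or Z.shape[0] != n:
        raise ValueError("X, Y, Z must share the sample count")

    def _standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=0, keepdims=True)
        scale = np.sqrt(np.mean(np.abs(a) ** 2, axis=0, keepdims=True))
        keep = scale.ravel() > 1e-12
        return a[:, keep] / scale[:, keep]

    Xs, Ys = _standardize(X), _standardize(Y)
    Zs = _standardize(Z)
    if Zs.shape[1] == 0:  # conditioning set was constant: plain CCA
        if np.iscomplexobj(Xs):
            return cca_complex(Xs, Ys.real, reg=reg)
        return cca(Xs.real, Ys.real, reg)

    szz = _cov(Zs, Zs)
    # a ridge on the conditioning covariance keeps the Schur complement
    # positive semi-definite under near-collinear Z
    rz = (
        DEFAULT_REG_SCALE * float(np.real(np.trace(szz)) / szz.shape[0])
        if reg is None
        else float(reg)
    )
    try:
        szz_inv = np.linalg.inv(szz + rz * np.eye(szz.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular conditioning covariance; pass reg > 0"
        ) from exc

    def _partial(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return _cov(a, b) - _cov(a, Zs) @ szz_inv @ _cov(Zs, b)

    Ysc = Ys.astype(complex) if np.iscomplexobj(Xs) else Ys
    return _cca_from_cov(_partial(Xs, Xs), _partial(Xs, Ysc), _partial(Ysc, Ysc), reg, n)


def _aligned_slices(
    tfr: TFR, n_y: int, lag_steps: int
) -> tuple[slice, np.ndarray]:
    """Index ranges pairing TFR bins with slow-channel samples at a lag.

    TFR bin k is aligned (at lag 0) with slow sample ``k + align_offset``; at
    a lag of ``lag_steps`` slow samples the pairing becomes
    ``k -> k + align_offset - lag_steps``.
    """
    off = tfr.align_offset - lag_steps
    k0 = max(0, -off)
    k1 = min(tfr.n_bins, n_y - off)
    if k1 <= k0:
        return slice(0, 0), np.empty(0, dtype=int)
    return slice(k0, k1), np.arange(k0, k1) + off


def lagged_cca(
    X_tfr: TFR,
    Y: list[np.ndarray] | np.ndarray,
    lag: float,
    mode: str = "complex_then_abs",
    reg: float | None = None,
    Z: list[np.ndarray] | None = None,
    min_overlap: int = 50,
) -> CCAResult:
    """Canonical correlation between a TFR and a lag-shifted slow channel.

    Negative ``lag`` (seconds) means the TFR history precedes Y (X drives Y
    evidence); positive lag means Y precedes the TFR window. Multi-trial
    input yields the across-trial mean correlation; the per-trial values are
    kept in ``trial_cc`` and the per-trial weight magnitudes (averaged into
    ``coef_magnitude``) in ``trial_coef_magnitude``. The slow channel (and
    any conditioning series Z) is standardized per trial. When ``Z`` is
    given, the per-trial solve uses partial CCA.
    """
    y_trials = [np.asarray(y, dtype=float).ravel() for y in (
        [Y] if isinstance(Y, np.ndarray) and np.ndim(Y) == 1 else Y
    )]
    if len(y_trials) != X_tfr.n_trials:
        raise ValueError("trial count mismatch between TFR and Y")
    target_fs = 1.0 / X_tfr.hop
    lag_steps = int(round(lag * target_fs))

    vals = np.abs(X_tfr.values) if mode == "abs_then_cca" else X_tfr.values
    if mode not in ("complex_then_abs", "abs_then_cca"):
        raise ValueError(f"unknown mode {mode!r}")

    ccs, mags = [], []
    u0 = v0 = None
    n_used = 0
    reg_used = 0.0
    for t, y in enumerate(y_trials):
        ks, ys_idx = _aligned_slices(X_tfr, len(y), lag_steps)
        if len(ys_idx) < min_overlap:
            raise ValueError(
                f"only {len(ys_idx)} aligned samples at lag {lag:+.3f}s "
                f"(need >= {min_overlap})"
            )
        Xm = vals[t, ks, :]
        yv = y[ys_idx]
        yv = (yv - yv.mean()) / (yv.std() or 1.0)
        if Z is not None:
            # conditioning rows are aligned with the TFR bins and are not
            # lag-shifted: they travel with the source windows
            zv = np.asarray(Z[t])
            zmat = zv[ks] if zv.ndim == 1 else zv[ks, :]
            res = partial_cca(Xm, yv[:, None], zmat, reg=reg)
        elif np.iscomplexobj(Xm):
            res = cca_complex(Xm, yv, mode="complex_then_abs", reg=reg)
        else:
            res = cca(Xm.real, yv, reg)
        ccs.append(res.cc)
        mags.append(res.coef_magnitude)
        if u0 is None:
            u0, v0 = res.u, res.v
            reg_used = res.regularization
        n_used += len(ys_idx)

    mags = np.asarray(mags)
    return CCAResult(
        cc=float(np.mean(ccs)),
        u=u0,
        v=v0,
        coef_magnitude=mags.mean(axis=0),
        n_samples=n_used,
        regularization=reg_used,
        trial_cc=np.asarray(ccs),
        trial_coef_magnitude=mags,
    )
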