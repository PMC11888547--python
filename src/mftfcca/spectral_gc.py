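"""Spectral Granger causality: analytic ground truth and estimated baselines.

For a stable VAR(r) with coefficient matrices ``A_tau`` and innovation
covariance ``Sigma``, the transfer function is

    H(f) = (I - sum_tau A_tau exp(-2 pi i f tau / fs))^{-1}

and the spectral density S(f) = H Sigma H*. Geweke's frequency-domain
causality from a source channel to a target channel is

    f_{s->t}(f) = ln( S_tt(f) / (S_tt(f) - |H'_ts(f)|^2 Sigma'_ss) ),

where the prime denotes the rotation that decorrelates the source
innovation from the remaining innovations (a no-op for diagonal noise).
Integrating over frequency recovers the time-domain Granger causality
(Geweke's identity): F = (2/fs) * integral_0^{fs/2} f(f) df.

The conditional variant (source -> target given a third channel) follows
Geweke's partitioned construction: the reduced model of (target, cond) is
recovered from the full model's autocovariance sequence by solving the
multivariate Yule-Walker equations at high order, and the causal fraction of
the reduced innovation's spectrum attributable to the source innovation is
measured through Q(f) = diag(G(f)^{-1}, I) H'(f).

Also here: multi-trial least-squares VAR estimation, and the mixed-frequency
VAR baseline that stacks the m fast samples of each slow period with the
slow sample and Wald-tests the cross-coefficient blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries import TimeSeriesSet
from .var_simulator import VARModel

__all__ = [
    "SGCSpectrum",
    "analytic_sgc",
    "conditional_analytic_sgc",
    "fit_var",
    "order_scan",
    "mf_var_gc",
    "MFVARResult",
]

DEFAULT_N_FREQS = 512


@dataclass
class SGCSpectrum:
    """Frequency-resolved Granger causality for one direction."""

    freqs: np.ndarray
    value: np.ndarray
    direction: tuple[str, str]
    time_domain_gc: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.value = np.asarray(self.value, dtype=float)

    def peak(self) -> tuple[float, float]:
        """(frequency, value) of the spectral maximum."""
        i = int(np.argmax(self.value))
        return float(self.freqs[i]), float(self.value[i])


def _default_freqs(fs: float, n: int = DEFAULT_N_FREQS) -> np.ndarray:
    return np.linspace(0.0, fs / 2, n)


def _transfer(model: VARModel, freqs: np.ndarray) -> np.ndarray:
    """H(f) for each frequency, shape (len(freqs), n, n)."""
    r, n, _ = model.coeffs.shape
    taus = np.arange(1, r + 1)
    out = np.empty((len(freqs), n, n), dtype=complex)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f * taus / model.fs)
        Af = np.eye(n, dtype=complex) - np.tensordot(z, model.coeffs, axes=(0, 0))
        try:
            out[i] = np.linalg.inv(Af)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular transfer matrix at {f:.3f} Hz"
            ) from exc
    return out


def _block_ldl(sigma: np.ndarray, sizes: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Block LDL^T: sigma = L D L^T with unit-diagonal block-lower L.

    Eliminates correlations in block order, so the *last* block's innovation
    is orthogonalized against all earlier ones.
    """
    n = sigma.shape[0]
    edges = np.cumsum([0] + sizes)
    L = np.eye(n)
    D = sigma.copy()
    for k in range(len(sizes)):
        a, b = edges[k], edges[k + 1]
        for j in range(k + 1, len(sizes)):
            c, d = edges[j], edges[j + 1]
            coef = D[c:d, a:b] @ np.linalg.inv(D[a:b, a:b])
            L[c:d, a:b] += coef @ L[a:b, a:b]
            D[c:d, :] -= coef @ D[a:b, :]
            D[:, c:d] = D[c:d, :].T.copy()
    # zero out off-diagonal remnants
    Dc = np.zeros_like(D)
    for k in range(len(sizes)):
        a, b = edges[k], edges[k + 1]
        Dc[a:b, a:b] = D[a:b, a:b]
    return L, Dc


def _resolve_index(model: VARModel, channel: int | str) -> int:
    if isinstance(channel, str):
        return model.channel_names.index(channel)
    return int(channel)


def analytic_sgc(
    model: VARModel,
    source: int | str,
    target: int | str,
    freqs: np.ndarray | None = None,
) -> SGCSpectrum:
    """Unconditional (pairwise) spectral GC computed from known coefficients.

    For a bivariate model this is the exact Geweke decomposition. For larger
    models the remaining channels are simply ignored in the normalization
    (use :func:`conditional_analytic_sgc` for the conditional quantity).
    """
    s = _resolve_index(model, source)
    t = _resolve_index(model, target)
    if s == t:
        raise ValueError("source and target must differ")
    if freqs is None:
        freqs = _default_freqs(model.fs)
    freqs = np.asarray(freqs, dtype=float)
    if model.n_vars > 2:
        sub = _marginal_model(model, [t, s])
        # after marginalization, target is index 0 and source index 1
        H = _transfer(sub, freqs)
        sigma = sub.noise_cov
        ti, si = 0, 1
        names = (model.channel_names[s], model.channel_names[t])
        fs = sub.fs
    else:
        H = _transfer(model, freqs)
        sigma = model.noise_cov
        ti, si = t, s
        names = (model.channel_names[s], model.channel_names[t])
        fs = model.fs
    # decorrelate the source innovation from the target innovation
    order = [ti, si]
    perm = np.ix_(order, order)
    L, D = _block_ldl(sigma[perm], [1, 1])
    vals = np.empty(len(freqs))
    for i in range(len(freqs)):
        Hp = H[i][:, order][order, :] @ L
        S = (Hp @ D @ Hp.conj().T).real
        stt = S[0, 0]
        causal = (np.abs(Hp[0, 1]) ** 2) * D[1, 1]
        vals[i] = np.log(stt / max(stt - causal, 1e-300))
    td = float(2.0 / fs * np.trapezoid(vals, freqs))
    return SGCSpectrum(freqs, np.maximum(vals, 0.0), names, td)


def _marginal_model(model: VARModel, keep: list[int], p_out: int = 128) -> VARModel:
    """VAR approximation of the marginal process of a channel subset.

    The subset of a VAR is ARMA; it is re-approximated as a high-order VAR
    through its exact autocovariance sequence.
    """
    n_lags = max(4 * model.order, p_out) + p_out
    gammas = model.autocovariance(n_lags)
    sub = gammas[:, np.ix_(keep)[0][:, None], np.asarray(keep)[None, :]]
    B, sigma = _var_from_autocov(sub, p_out)
    return VARModel(
        B,
        noise_cov=sigma,
        fs=model.fs,
        channel_names=[model.channel_names[i] for i in keep],
    )


def _var_from_autocov(gammas: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve the multivariate Yule-Walker equations for a VAR(p).

    gammas: shape (K+1, m, m) with K >= p; Gamma_k = E[w_t w_{t-k}^T].
    Returns (B of shape (p, m, m), residual covariance).
    """
    m = gammas.shape[1]
    if gammas.shape[0] <= p:
        raise ValueError("need autocovariances up to lag p")
    G = np.empty((p * m, p * m))
    for j in range(p):
        for k in range(p):
            d = k - j
            G[j * m : (j + 1) * m, k * m : (k + 1) * m] = (
                gammas[d] if d >= 0 else gammas[-d].T
            )
    R = np.hstack([gammas[k] for k in range(1, p + 1)])  # m x (p m)
    B_stack = np.linalg.solve(G.T, R.T).T  # solves B G = R
    sigma = gammas[0] - sum(
        B_stack[:, j * m : (j + 1) * m] @ gammas[j + 1].T for j in range(p)
    )
    sigma = (sigma + sigma.T) / 2
    B = np.stack([B_stack[:, j * m : (j + 1) * m] for j in range(p)])
    return B, sigma


def conditional_analytic_sgc(
    model: VARModel,
    source: int | str,
    target: int | str,
    conditioning: int | str | list[int | str] | None = None,
    freqs: np.ndarray | None = None,
    reduced_order: int = 128,
) -> SGCSpectrum:
    """Conditional spectral GC source -> target | conditioning, analytically.

    ``reduced_order`` is the VAR order used to represent the (target,
    conditioning) sub-process recovered from the full model's
    autocovariance sequence.
    """
    s = _resolve_index(model, source)
    t = _resolve_index(model, target)
    if conditioning is None:
        conditioning = [i for i in range(model.n_vars) if i not in (s, t)]
    if not isinstance(conditioning, list):
        conditioning = [conditioning]
    cond = [_resolve_index(model, c) for c in conditioning]
    if s in cond or t in cond or s == t:
        raise ValueError("source, target and conditioning must be disjoint")
    if freqs is None:
        freqs = _default_freqs(model.fs)
    freqs = np.asarray(freqs, dtype=float)

    order = [t] + cond + [s]  # target first, source last
    nz = len(cond)
    sizes = [1, nz, 1] if nz else [1, 1]

    sigma = model.noise_cov[np.ix_(order, order)]
    L, D = _block_ldl(sigma, sizes)

    # reduced model of (target, cond) from the exact autocovariance
    n_lags = max(4 * model.order, reduced_order) + reduced_order
    gammas = model.autocovariance(n_lags)
    keep = [t] + cond
    sub = gammas[:, np.ix_(keep)[0][:, None], np.asarray(keep)[None, :]]
    B, sigma_r = _var_from_autocov(sub, reduced_order)
    m = 1 + nz

    H = _transfer(model, freqs)
    taus_r = np.arange(1, reduced_order + 1)
    vals = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        Hp = H[i][np.ix_(order, order)] @ L
        zr = np.exp(-2j * np.pi * f * taus_r / model.fs)
        Gf = np.eye(m, dtype=complex) - np.tensordot(zr, B, axes=(0, 0))
        # Gf is the reduced model's *inverse* transfer; Q maps full-model
        # innovations onto the reduced innovations eta = Gf w_sub
        Q_top = Gf @ Hp[:m, :]
        qxx = Q_top[0, 0]
        intrinsic = (np.abs(qxx) ** 2) * D[0, 0]
        vals[i] = np.log(max(sigma_r[0, 0], 1e-300) / max(intrinsic, 1e-300))
    td = float(2.0 / model.fs * np.trapezoid(vals, freqs))
    names = (model.channel_names[s], model.channel_names[t])
    return SGCSpectrum(freqs, vals, names, td)


# ---------------------------------------------------------------------------
# Estimation from data
# ---------------------------------------------------------------------------


def _stack_regression(
    data: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pool lagged regressors across trials without cross-trial leakage.

    data: (trials, samples, channels). Returns (X, Y) with X of shape
    (N, order*channels) ordered lag-major: [w_{t-1}, w_{t-2}, ...].
    """
    n_trials, n_samples, n = data.shape
    if n_samples <= order:
        raise ValueError("trials shorter than the model order")
    Xs, Ys = [], []
    for tr in range(n_trials):
        w = data[tr]
        Y = w[order:]
        X = np.hstack([w[order - k : n_samples - k] for k in range(1, order + 1)])
        Xs.append(X)
        Ys.append(Y)
    return np.vstack(Xs), np.vstack(Ys)


def fit_var(
    ts: TimeSeriesSet | np.ndarray,
    order: int,
    trials: list[int] | None = None,
    channel_names: list[str] | None = None,
    demean: bool = True,
) -> VARModel:
    """Multi-trial least-squares VAR estimate.

    Regressors are pooled across trials with no lag leakage across trial
    boundaries. All channels must share one sampling rate.
    """
    if isinstance(ts, TimeSeriesSet):
        data = ts.to_array(channel_names)
        names = channel_names or ts.channel_names
        fs = ts.fs[names[0]]
    else:
        data = np.asarray(ts, dtype=float)
        if data.ndim == 2:
            data = data[None]
        names = channel_names or [f"ch{i}" for i in range(data.shape[2])]
        fs = 1.0
    if trials is not None:
        data = data[list(trials)]
    if demean:
        data = data - data.mean(axis=1, keepdims=True)
    X, Y = _stack_regression(data, order)
    cond = np.linalg.cond(X.T @ X)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"ill-conditioned regressor matrix (cond={cond:.2e}); "
            "reduce the order or supply more data"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma = resid.T @ resid / dof
    n = data.shape[2]
    coeffs = np.stack([B[k * n : (k + 1) * n].T for k in range(order)])
    fs_out = fs if isinstance(ts, TimeSeriesSet) else fs
    return VARModel(coeffs, noise_cov=sigma, fs=fs_out, channel_names=list(names))


def order_scan(
    ts: TimeSeriesSet | np.ndarray,
    max_order: int,
    channel_names: list[str] | None = None,
) -> dict[int, dict[str, float]]:
    """AIC/BIC over candidate VAR orders 1..max_order (pooled trials)."""
    out: dict[int, dict[str, float]] = {}
    if isinstance(ts, TimeSeriesSet):
        data = ts.to_array(channel_names)
    else:
        data = np.asarray(ts, dtype=float)
        if data.ndim == 2:
            data = data[None]
    data = data - data.mean(axis=1, keepdims=True)
    n = data.shape[2]
    for p in range(1, max_order + 1):
        X, Y = _stack_regression(data, p)
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
        N = X.shape[0]
        sigma = resid.T @ resid / N
        _, logdet = np.linalg.slogdet(sigma)
        k = p * n * n
        out[p] = {
            "aic": float(logdet + 2 * k / N),
            "bic": float(logdet + k * np.log(N) / N),
        }
    return out


@dataclass
class MFVARResult:
    """Wald test of one causal direction in the stacked mixed-frequency VAR."""

    direction: tuple[str, str]
    statistic: float
    df: int
    p_value: float
    order: int
    ratio: int


def _stack_mf(
    x_hf: list[np.ndarray], x_lf: list[np.ndarray], m: int
) -> np.ndarray:
    """Stacked slow-clock vector [x_H(t,1)..x_H(t,m), x_L(t)] per trial."""
    stacked = []
    for xh, xl in zip(x_hf, x_lf):
        n_lf = min(len(xl), len(xh) // m)
        block = xh[: n_lf * m].reshape(n_lf, m)
        stacked.append(np.column_stack([block, xl[:n_lf]]))
    return np.stack(stacked)


def mf_var_gc(
    ts: TimeSeriesSet,
    hf_channel: str,
    lf_channel: str,
    order: int = 1,
) -> dict[str, MFVARResult]:
    """Mixed-frequency VAR Granger test between a fast and a slow channel.

    The m fast samples of each slow period are stacked with the slow sample
    into an (m+1)-vector on the slow clock; a VAR(order) is fitted by pooled
    multi-trial least squares and each direction is tested by a joint Wald
    zero-restriction on the cross-coefficient block (chi-square reference).
    """
    fs_h, fs_l = ts.fs[hf_channel], ts.fs[lf_channel]
    ratio = fs_h / fs_l
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"sampling-rate ratio {ratio} is not an integer")
    m = int(round(ratio))
    data = _stack_mf(ts.channel(hf_channel), ts.channel(lf_channel), m)
    data = data - data.mean(axis=1, keepdims=True)
    X, Y = _stack_regression(data, order)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    N, k = X.shape
    dof = max(N - k, 1)
    sigma = resid.T @ resid / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    d = m + 1
    # coefficient (i, j, lag) lives at B[lag*d + j, i]
    results: dict[str, MFVARResult] = {}
    for name, rows, cols in (
        ("hf_to_lf", [d - 1], list(range(m))),
        ("lf_to_hf", list(range(m)), [d - 1]),
    ):
        sel_b = []
        cov_blocks = []
        reg_idx = [lag * d + j for lag in range(order) for j in cols]
        for i in rows:
            sel_b.append(B[reg_idx, i])
        b = np.concatenate(sel_b)
        # cov of vec over selected (equation, regressor) pairs
        cov = np.kron(sigma[np.ix_(rows, rows)], xtx_inv[np.ix_(reg_idx, reg_idx)])
        try:
            w = float(b @ np.linalg.solve(cov, b))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("singular Wald covariance") from exc
        df = len(b)
        p = float(stats.chi2.sf(w, df))
        direction = (hf_channel, lf_channel) if name == "hf_to_lf" else (lf_channel, hf_channel)
        results[name] = MFVARResult(direction, w, df, p, order, m)
    return results
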