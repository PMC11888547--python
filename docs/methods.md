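# Methods

## Model and estimator

Let X(t) be sampled at rate F_x and Y(t) at F_y with F_x ≥ F_y (HF and LF
channels). MF-TFCCA measures directed spectral dependence by correlating
the short-time Fourier representation of X with the raw samples of Y.

**TFR.** X̃(t, ω) = STFT(X) with window length W_l seconds (Hann taper by
default; rectangular available) and hop 1/F_y, i.e. overlap W_l − 1/F_y.
Frames are placed only where the full window fits and are indexed by their
*center* time; `align_offset` records how many leading LF samples precede
the first center. The FFT length defaults to 4× the window sample count —
zero padding that interpolates the frequency grid finely enough to place a
4 Hz peak when the raw resolution of a 200 ms window would be 5 Hz. Each
frequency column is then standardized per trial (complex mean removed, one
real scale = the standard deviation of the complex samples, preserving
phase); this prewhitens across frequency but deliberately not across time.

**CCA.** For variable sets X (n×p) and Y (n×q), the leading canonical pair
solves the generalized eigenproblem on the covariance blocks; we compute it
via Cholesky whitening and an SVD of L_x⁻¹ S_xy L_y⁻ᴴ, which is numerically
stable and returns ρ = σ₁ directly. Complex data use Hermitian covariances;
ρ is then invariant to per-column phase rotations, which is why the
complex mode is blind to phase–amplitude coupling while the magnitude mode
(`abs_then_cca`) detects it. Ridge regularization defaults to
1e-3 × mean covariance diagonal per set; with z-scored columns this is a
relative 1e-3 ridge. Partial CCA standardizes all sets and replaces every
block by its Schur complement S_{uv|z} = S_uv − S_uz S_zz⁻¹ S_zv (the
conditioning covariance carries the same relative ridge so the complement
stays positive semi-definite under collinear Z).

**Reported coefficient spectrum.** The per-frequency quantity attached to
results is the *canonical loading* |corr(X̃(·, ω), Yv)|, not the raw weight
magnitude |u|. On the padded STFT grid neighbouring columns are strongly
collinear, and the whitened weights (S_xx+λI)⁻¹S_xy are dominated by
cancellation artifacts (empirically they pile up at DC regardless of the
true driving band); loadings are the standard interpretable reporting in
applied CCA and recover the informative frequencies. Raw weights remain in
`CCAResult.u`.

**Lag convention.** ρ(Δ) pairs the TFR bin centered at t with the Y sample
at t − Δ: Δ < 0 means the X window precedes the Y sample (X→Y evidence),
Δ > 0 the reverse. Because bins are center-aligned, a window still overlaps
its Y sample for |Δ| ≤ W_l/2; that is the direction-ambiguity boundary
drawn on profile plots. The lag grid is every LF sample period within the
requested range. Note the cross-correlation baseline `xcorr_profile` uses
the mirrored convention r(Δ) = corr(X(t), Y(t+Δ)) — a pure delay d of Y
behind X peaks at +d there — matching how lagged cross-correlograms are
usually drawn.

**Surrogates and inference.** Surrogate pairs replace all Fourier phases
(DC/Nyquist bins kept real) while preserving the amplitude spectrum — and
hence every channel's autocorrelation — exactly. The per-lag 2.5/97.5%
envelope of the surrogate trial-mean CC is attached for display. The
direction call does **not** use the per-lag envelope: neighbouring lags are
strongly correlated through overlapping windows, and an excursion-run rule
on per-lag bands over-calls badly (~75–85% specificity in null
simulations). Instead each side's maximum CC beyond the boundary is tested
with the exact-conservative permutation p-value
p = (1 + #{null_max ≥ obs_max})/(1 + n_surr) at 2.5% per side, giving ≥95%
joint specificity by construction, verified by Monte Carlo in the suite.
Per-lag one-sided t-tests of per-trial CC against pooled surrogate CC are
also attached (a KS variant is available) for users who want pointwise
p-values. Multi-trial CC is computed per trial and averaged; the profile
sweep estimates the within-set covariance once per trial over the whole
trial (stationarity assumption) and only the cross-covariance per lag,
which is cross-checked against the general solver in the tests.

**Conditioning.** For three or more channels the profile partials a third
channel out of both sets. The conditioner travels with the source windows
(it is not lag-shifted with Y): either its raw value at each window center
(`z_role="raw"`, the low-variance choice at small sample sizes) or its own
z-scored TFR (`z_role="tfr"`, appropriate when the mediated influence is
spectral, e.g. the trivariate chain where partialling the mediator's
spectrum visibly shrinks the CC).

**Filter-one-frequency-out.** Band attribution re-runs the CCA at the same
lag after removing a band from the source channel and reports
(cc_filtered − cc)/cc. The band-stop is exact rfft-bin surgery —
zero-phase, exactly transparent outside the band and idempotent; IIR
notches were rejected because their transition bands leave a few percent
RMS non-idempotence that contaminates small gains.

An "autocorrelation-like" normalization of CC (dividing by a
self-predictability factor) is sometimes suggested for calibrating CC
magnitudes across settings; no well-defined formula exists, so it is not
shipped — the surrogate envelope already provides the calibrated reference
scale.

## Ground truth: analytic spectral GC

For a stable VAR(r) with coefficients A_τ (plus-sign recursion
Θ_t = ΣA_τΘ_{t−τ} + e_t) the transfer function is
H(f) = (I − ΣA_τ e^{−2πif τ/fs})⁻¹ and S = HΣH*. Geweke's frequency-domain
causality from source s to target t is
ln S_tt / (S_tt − |H'_ts|² Σ'_ss), where the prime is the rotation that
decorrelates the source innovation from the rest (a block-LDL with the
source eliminated last; a no-op for diagonal noise). Stability is enforced
at construction via the companion-matrix spectral radius. The
frequency-integrated value (2/fs)∫ f(ν)dν is checked against an independent
time-domain computation — the target's marginal innovation variance from a
high-order Yule–Walker solve of the exact autocovariance (companion-form
Lyapunov equation) — to 1e-3 relative (Geweke's identity).

The conditional variant follows the partitioned construction: the reduced
model of (target, conditioning) is recovered from the exact autocovariance
sequence by a block-Toeplitz Yule–Walker solve at order 128 (default), and
Q(f) = diag(G(f), I)·H'(f) maps full-model innovations onto the reduced
innovation; f_{s→t|z} = ln σ²_red / |Q_tt|²Σ'_tt. Augmenting a bivariate
system with a decoupled third channel reproduces the bivariate spectrum to
better than 1e-6, and the chain system's mediated path X1→Y|X2 vanishes.

Pairwise GC inside a larger system marginalizes the remaining channels by
re-approximating the subset process (ARMA in general) as a VAR(128) from
its exact autocovariance.

## Simulators and what they emulate

The VAR factories build each channel's diagonal AR polynomial as a product
of pole-pair factors (modulus r, frequency f → 1 − 2r cosθ z + r²z², θ =
2πf/fs) and place the printed cross-coefficients; every factory is
stability-checked. Gaussian innovations default to identity covariance
(none is printed for these systems; results are qualitative under unit
noise). Simulation starts from zeros and discards a 500-sample burn-in —
ample for the slowest factory pole (0.95, decay < 10⁻¹¹ over the burn-in).
Trials advance in lockstep from a single seeded generator; identical seeds
are bit-reproducible.

Two caveats connect these systems to real data. First, an AR(2) "oscillator
at f Hz" only exhibits a spectral *peak* at f when the pole is sharp enough
(cos ω* = (1+r²)cosθ/2r < 1); the 4 Hz/r=0.8 and 2 Hz/r=0.7 poles used by
the bivariate benchmarks do not, so their spectra — and any cross-spectral
quantity they drive — decay monotonically from DC. Second, the benchmark
couplings are short FIR taps whose own frequency response reweights the
source spectrum; the effective driving band is the product of the two and
can sit far from the nominal oscillator frequency. Passing tests on these
systems therefore demonstrate correct estimation of *that* ground truth,
not that every labeled oscillator frequency is recoverable; real recordings
with genuinely peaked rhythms are the easier case for frequency
identification.

The nonlinear generators: PAC multiplies a slow VAR channel (offset per
trial by −min X0 so the envelope is non-negative; the envelope equation's
slow factor is identified with the simulated X0) onto a 90 Hz carrier —
causal content moves entirely into spectral power. Amplitude modulation
applies a sigmoid (gain 2 by default) or cosine (scale π) samplewise.
The logistic map uses r_x=3.7, r_y=3.8, couplings (0, 0.32) or
(0.02, 0.1), uniform initial conditions and a 100-step transient discard,
and raises on divergence. The Rössler–Lorenz pair (α=6, C=2, coupling
C·x2² into the Lorenz ẏ2) integrates with fixed-step classical RK4 at
1/(20·fs) and stride-samples at 100 Hz; the fixed step keeps trajectories
bit-reproducible across platforms, and halving it changes the first 5 s by
under 1e-3 relative RMS.

## Baselines

`fit_var` pools lagged regressors across trials (no cross-trial leakage)
into one least-squares problem; residual covariance uses the
degrees-of-freedom-corrected denominator; an AIC/BIC order scan is
provided. `mf_var_gc` stacks the m fast samples of each slow period with
the slow sample into an (m+1)-vector on the slow clock, fits a pooled
VAR(r), and Wald-tests each direction's cross-coefficient block against a
χ² reference (the classical asymptotic choice; no bootstrap).

## Numerical choices and problem sizes

Decimation low-passes with an order-8 zero-phase Butterworth at 0.8× the
new Nyquist before keeping every K-th sample. CCA eigen-ties are broken by
SVD ordering; weight phase is fixed by making the largest-|u| entry
real-positive. Degenerate inputs: zero-variance TFR columns are zeroed with
a warning; constant conditioners reduce partial CCA to plain CCA; unstable
models, non-positive-definite noise, rate-ratio violations and
out-of-Nyquist bands raise immediately.

Unit and property tests run the full machinery on reduced problem sizes
(typically 6–50 trials of 10 s, 40–100 surrogates, chosen so the whole
suite completes in a few minutes on one CPU); the benchmark-protocol tests
and the acceptance script use the full 100 trials × 20 s conditions. The
null-specificity and MF-VAR type-I checks are seeded Monte Carlo runs with
binomially sensible acceptance margins at their scale.

## Known limitations

- Directionality inference assumes the causal lag structure is visible on
  the LF clock; influences faster than F_y/2 are invisible by Nyquist.
- z-scoring prewhitens frequency but not time: strong source
  autocorrelation can push reverse-side CC above the null at coarse
  decimation (observed at rate ratio 8 on the unidirectional benchmark),
  yielding bidirectional over-calls. Prewhitening in time before analysis
  is the practical remedy.
- Partialling a full TFR conditioner with few samples inflates the
  conditional CC (many-regressor Schur complement); prefer `z_role="raw"`
  or more trials in that regime.
- The linear CCA core cannot represent couplings whose information is in
  neither the complex STFT nor its magnitude (e.g. phase-only codes).
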