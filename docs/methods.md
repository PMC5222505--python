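# Methods

## Estimators

### Response-weighted stimulus covariance

Given an aligned stimulus `s` (T bins × D dimensions) and response `r`
(T bins), and a causal lag window of `L = τ+1` taps, the core estimator is

    C_ij = 1/(T−τ) · Σ_{t=τ+1..T} r_t · s_{t−i} · s_{t−j},   i, j ∈ {0..τ}

(1-based time in the formula; the code is 0-based). For D > 1 the matrix
is organized block-wise per ordered pair of stimulus dimensions. The sum
starts at the first bin with a complete lag window — there is no zero
padding — and the denominator is the number of summed bins, `T−τ`, never
`T−τ−1`; at the recording lengths this estimator is used for, the
distinction is negligible, and the unbiased-denominator variant would
break the exact algebraic identities below.

**Layout.** All lag-expanded vectors and matrices use one convention,
`dim_major_lag_minor`: flattened index `d·L + i` for dimension `d`, lag
`i`. The string is stamped on every covariance object and output file.
The block ordering of such matrices is a free convention; this package
fixes its own and labels it rather than leaving it implicit.

**Backends.** Two implementations exist under one contract: a naive
reference that sums each entry directly (a compiled loop when numba is
available, pure Python otherwise), and an accelerated backend that
builds the `(T−τ) × (D·L)` lagged design matrix `X` once and computes
`X^T diag(r) X / (T−τ)` through BLAS. Both accumulate in double
precision; `backend_equivalence` measures their discrepancy, which is
at machine-precision level (observed ≲ 1e-15 relative) rather than the
1e-10 the contract demands. Outputs are explicitly symmetrized
(`(M + M^T)/2`), so stored matrices are exactly symmetric.

### Wiener rescaling

For Gaussian white-noise input with standard deviation σ sampled every
Δt, and a *mean-subtracted* response, `C` is proportional to the
second-order Wiener kernel:

    K² = C / (2 σ⁴ Δt²)

The zero-mean condition is a validity requirement, not a convention, so
the covariance object records whether the response was demeaned and the
rescaling refuses inputs computed without it (a `ContractError`).
Demeaning subtracts the mean over the summed bins `τ+1..T` only, so the
flagged object is internally consistent. The stimulus itself is never
demeaned or rescaled: the estimator operates on raw samples and σ is
supplied by the caller (the simulator knows it exactly; for recorded
data, estimate it from the stimulus).

### Spike-triggered statistics

With `r` the integer spike count per bin (not demeaned, per the
spike-triggered convention) and `x_t` the lagged stimulus window:

* STA: `a = 1/n_r · Σ r_t x_t`, `n_r = Σ r_t`, both sums over full
  windows only (`t = τ+1..T`). A spike train with no spikes in that
  range is a degenerate input (`DegenerateInputError`), not a silent
  zero.
* Raw STC: `C0 = (T−τ)/n_r · C − S`, where `S` is the stimulus
  covariance — computed through the same estimator with a unit
  response, so the reduction `r ≡ 1 ⇒ C0 = 0` holds exactly, bit for
  bit.
* STA-subtracted: `C1 = C0 − a a^T`.
* STA-projected: `C2 = (I − A') C0 (I − A')^T`, `A' = a a^T/(a^T a)`;
  `C2 a = 0` by construction.

The pre-simplification forms (windows recentred on the STA for `C1`;
the STA direction regressed out of every window, in both the weighted
and unweighted covariance, for `C2`) are implemented independently in
the test suite and agree with the matrix-transform forms to ≤ 1e-10
relative on random spike trains.

## Eigenanalysis and significance

Eigendecomposition sorts eigenvalues descending (stable for ties) and
fixes each eigenvector's sign so its largest-magnitude component is
positive, first index winning ties — eigenvectors of symmetric matrices
are defined only up to sign, and a deterministic convention makes runs
and file outputs comparable.

### Time-shift null

To ask whether an eigenvalue reflects genuine stimulus-response
structure, the response is circularly shifted relative to the stimulus
by `n_shifts` distinct offsets drawn uniformly (seeded) from
`{min_shift .. T−min_shift}` with `min_shift > τ`, and the chosen matrix
variant is recomputed per shift. Circular shifting preserves each
signal's own autocorrelation while destroying their relationship, so
the shifted spectra sample the null hypothesis "stimulus and response
are unrelated" with the right noise correlation structure. Wrap-around
joins the recording's tail to its head; for the stationary signals this
package targets the few affected windows are immaterial, and the
alternative (truncation) would change the sample count per shift.
The default ensemble size is 1,000 shifts; heavy use cases run tens of
thousands, and the demonstration analyses here use 200, which is enough
to place a 2.5% quantile.

### Significance rules

Two band constructions are provided (both two-sided at level α, both
using outward-rounded empirical quantiles so the strict exceedance test
is exchangeably exact rather than slightly anti-conservative):

* `extreme` (default): one family-wise band for the whole spectrum,
  `[q_{α/2}(min-eigenvalue of each null draw), q_{1−α/2}(max-eigenvalue)]`.
  An observed eigenvalue outside it is more extreme than the null
  matrices ever get, so the number of flagged eigenvalues estimates the
  number of genuine filter directions.
* `rank`: a separate band per rank from the same-rank null eigenvalues.

The rank rule is exactly calibrated under the global null — and the
calibration study below uses it — but it systematically over-flags when
filters are actually present: once signal occupies the top ranks, the
remaining observed noise eigenvalues are extremes over the
signal-orthogonal complement, while the null's same-rank values are
interior order statistics of the full noise spectrum, so mid-rank noise
exceeds per-rank bands far more often than α. The family-wise extreme
band does not have this defect, which is why it is the default for
filter counting and subspace recovery.

### Subspace recovery

`filter_subspace_check` projects each true filter onto the span of the
supplied vectors by least squares and reports the cosine similarity
between the filter and its projection. For the STA-projected variant
the STA is appended to the significant eigenvectors before the check,
since the projection removed exactly that direction and the STA serves
as the second recovered filter; for `C0`/`C1` it is not.

## Synthetic model cells

### Pure second-order Volterra responder

`r_t = x_t^T G² x_t` with `G²` a seeded random symmetric kernel,
symmetrized as `(M+M^T)/2` and normalized to unit Frobenius norm —
full-rank, hence a demanding recovery target. Driven by unit-variance
Gaussian white noise with the response demeaned, the Wiener estimate
`K²` is a consistent estimate of `G²` (the system has no other orders),
and the relative Frobenius error falls as ~1/√T: measured means are
≈ 0.056 at T = 2¹⁶ and ≈ 0.027 at T = 2¹⁸ (D = 1, τ = 15, five seeds),
a ratio of ≈ 0.48.

### Two-filter rectified LNP spiker

Two linear filters act on the stimulus window; each output is half-wave
rectified; the rectified drives are summed and scaled by a gain into an
expected spike count per bin; counts are Poisson draws (and may exceed
1 per bin). The expected rate has the closed form
`gain · σ · Σ_k ||f_k|| / √(2π)` (half-normal mean), which
`calibrate_gain` inverts; the default target rate is **0.0045 spikes per
bin**, and simulated rates match it to well within Monte-Carlo error.

The filter pair is a deterministic fixture: a gamma-difference biphasic
filter and a damped oscillation, Gram-Schmidt orthonormalized, 8 taps by
default. The filter length is a design choice with a power rationale:
at the target rate and T = 2¹⁸ the analysis sees ~1,180 spikes, the STC
noise floor per entry is ~1/√n_r, and the null band half-width grows
like √L; 8 taps leaves the smallest genuine signal eigenvalue (the
negative STA-subtracted one, ≈ −0.29 in these units) comfortably outside
the null band, whereas 16 taps puts it at the band's edge. In this
regime the analytic expectations are: `C0` has two excess eigenvalues of
+1/2 in the filter plane; `C1` has +1/2 along `f1−f2` and
`1/2 − ||a||² ≈ −0.29` along `f1+f2` (one positive, one negative — the
two-sided test is essential); `C2` retains a single +1/2 eigenvalue with
the STA carrying the other direction. The measured counts (2, 2, 1
significant eigenvalues) and subspace cosines (> 0.95) match.

### What the simulations do and do not emulate

The generators produce ideal white Gaussian stimuli, exactly Poisson
spiking, and stationary responses. Real recordings have correlated
stimuli (which bias the covariance estimators and are explicitly out of
scope to correct), refractoriness and adaptation (non-Poisson count
statistics), and nonstationary gain. Passing tests therefore establish
correctness of the estimators and the significance machinery under the
model assumptions, not robustness to those violations.

## Numerical choices and degenerate inputs

* Double-precision accumulation everywhere regardless of input dtype
  (recordings of 2¹⁸+ bins contribute that many terms per entry).
* Stored covariance matrices must be symmetric to 1e-12 relative;
  `eigendecompose` validates symmetry to 1e-8 relative before
  symmetrizing for the solver.
* Zero spike trains, zero STAs (for the projector), and zero-norm truth
  kernels raise `DegenerateInputError`/`ValidationError` rather than
  returning NaNs.
* All stochastic operations take explicit integer seeds and are
  reproducible from (parameters, seed) alone.

## Problem sizes used in the shipped analyses

The validation analyses run at T = 2¹⁶–2¹⁸ for recovery studies, 200
null shifts for the demonstration significance tests, and 200
Monte-Carlo replicates at T = 4096 for the calibration study. These
sizes put Monte-Carlo error well below the decision thresholds while
keeping a full run in tens of seconds on one CPU core; all are
parameters, not limits.

## Known limitations

* Second order only: no higher-order kernels, no nonlinearity estimation
  after subspace recovery, no information-theoretic filter selection.
* White-stimulus assumption: no decorrelation correction for temporally
  or spatially correlated stimuli.
* The shift null assumes stationarity; strongly nonstationary responses
  make the null ensemble too narrow.
* The per-rank significance rule should not be used to count filters
  (see above); it is retained for calibration work and comparison.
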