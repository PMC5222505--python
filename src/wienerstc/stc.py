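"""Spike-triggered average/covariance analysis and shift-null significance.

Starting from the response-weighted stimulus covariance ``C`` (see
:mod:`wienerstc.kernel`) computed on raw spike counts, the three STC
matrix variants used in the literature are simple matrix transforms:

* raw:            ``C0 = (T - tau)/n_r * C - S``
* STA-subtracted: ``C1 = C0 - a a^T``
* STA-projected:  ``C2 = (I - A') C0 (I - A')^T``,  ``A' = a a^T / (a^T a)``

where ``a`` is the spike-triggered average, ``n_r`` the total spike count
over the summed window, and ``S`` the plain stimulus covariance.  The
significant eigenvectors of these matrices span the space of linear
filters feeding the cell.

Significance is assessed against a time-shift null: the response is
circularly shifted relative to the stimulus by more than the filter
length, which destroys any stimulus-response relationship while keeping
both signals' own correlation structures, and the chosen STC variant is
recomputed per shift.  An observed eigenvalue is called significant when
it falls outside a two-sided empirical band of the shifted spectra —
by default the family-wise band spanned by the null extremes (see
:func:`null_quantile_band` for that choice and the per-rank alternative).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError, DimensionError, ValidationError
from .kernel import lag_design_matrix, stimulus_covariance
from .types import (
    MODE_SPIKES,
    BlockCovariance,
    EigenReport,
    LagWindow,
    NullEnsemble,
    ResponseSet,
    SpikeTriggeredAverage,
    STCResult,
    StimulusEnsemble,
)

STC_VARIANTS = ("C0", "C1", "C2")
#: Variants accepted by the shift-null machinery; "C" is the raw
#: response-weighted covariance itself (no spike normalization), usable
#: with continuous responses.
NULL_VARIANTS = ("C",) + STC_VARIANTS


def _spike_column(response, column: int = 0) -> np.ndarray:
    if isinstance(response, ResponseSet):
        if response.mode != MODE_SPIKES:
            raise ValidationError(
                "spike-triggered statistics require spike-count responses"
            )
        return response.column(column)
    r = np.asarray(response, dtype=float).ravel()
    if np.any(r < 0) or not np.array_equal(r, np.round(r)):
        raise ValidationError("spike counts must be non-negative integers")
    return r


def spike_triggered_average(
    stimulus: StimulusEnsemble,
    spikes,
    lags: LagWindow,
    column: int = 0,
) -> SpikeTriggeredAverage:
    """The STA:  ``a = 1/n_r * sum_t r_t x_t``  over full windows.

    ``x_t`` is the lagged stimulus window vector and ``n_r = sum_t r_t``
    the total spike count; both sums run over ``t = tau+1..T`` only, so a
    unit response reduces the raw STC exactly to zero.  Raises
    :class:`DegenerateInputError` when there are no spikes.
    """
    r = _spike_column(spikes, column)
    if r.size != stimulus.T:
        raise DimensionError(
            f"stimulus has T={stimulus.T} but spikes have T={r.size}"
        )
    lags.check_against(stimulus.T)
    w = r[lags.tau :]
    n_r = float(w.sum())
    if n_r == 0:
        raise DegenerateInputError("no spikes in the summed window; STA undefined")
    X = lag_design_matrix(stimulus.values, lags.tau)
    return SpikeTriggeredAverage(a=X.T @ w / n_r, n_r=n_r)


def stc_raw(
    C: BlockCovariance, S: BlockCovariance, T: int, tau: int, n_r: float
) -> np.ndarray:
    """Raw STC matrix ``C0 = (T - tau)/n_r * C - S``.

    ``C`` must be the response-weighted covariance of the raw (not
    demeaned) spike counts; ``S`` the stimulus covariance from the same
    stimulus and lag window.
    """
    if C.demeaned:
        raise ValidationError(
            "C0 is defined on raw spike counts; C was computed with demeaning"
        )
    if C.matrix.shape != S.matrix.shape:
        raise DimensionError(
            f"C has shape {C.matrix.shape} but S has shape {S.matrix.shape}"
        )
    if n_r <= 0:
        raise DegenerateInputError("n_r must be positive to form C0")
    return (T - tau) / n_r * C.matrix - S.matrix


def stc_sta_subtracted(C0: np.ndarray, sta: SpikeTriggeredAverage) -> np.ndarray:
    """STA-subtracted STC:  ``C1 = C0 - a a^T``."""
    C0 = np.asarray(C0, dtype=float)
    a = sta.a
    if C0.shape != (a.size, a.size):
        raise DimensionError(f"C0 shape {C0.shape} does not match STA length {a.size}")
    return C0 - np.outer(a, a)


def stc_sta_projected(C0: np.ndarray, sta: SpikeTriggeredAverage) -> np.ndarray:
    """STA-projected STC:  ``C2 = (I - A') C0 (I - A')^T``.

    ``A' = a a^T / (a^T a)`` projects onto the STA direction, so ``C2``
    annihilates it: ``C2 a = 0``.  Undefined for a zero STA.
    """
    C0 = np.asarray(C0, dtype=float)
    a = sta.a
    if C0.shape != (a.size, a.size):
        raise DimensionError(f"C0 shape {C0.shape} does not match STA length {a.size}")
    nrm2 = float(a @ a)
    if nrm2 == 0:
        raise DegenerateInputError("zero STA: the projector A' is undefined")
    P = np.eye(a.size) - np.outer(a, a) / nrm2
    C2 = P @ C0 @ P.T
    return (C2 + C2.T) / 2.0


def compute_stc(
    stimulus: StimulusEnsemble,
    spikes,
    lags: LagWindow,
    column: int = 0,
    backend: str = "accelerated",
) -> STCResult:
    """All three STC variants plus the STA, in one pass."""
    from .kernel import response_weighted_covariance  # local import, no cycle

    r = _spike_column(spikes, column)
    resp = ResponseSet(r, mode=MODE_SPIKES)
    sta = spike_triggered_average(stimulus, resp, lags)
    C = response_weighted_covariance(
        stimulus, resp, lags, demean_response=False, backend=backend
    )[0]
    S = stimulus_covariance(stimulus, lags, backend=backend)
    C0 = stc_raw(C, S, stimulus.T, lags.tau, sta.n_r)
    C1 = stc_sta_subtracted(C0, sta)
    C2 = stc_sta_projected(C0, sta)
    return STCResult(C0=C0, C1=C1, C2=C2, sta=sta)


# ---------------------------------------------------------------------------
# Eigenanalysis


def eigendecompose(M: np.ndarray, rtol: float = 1e-8) -> EigenReport:
    """Descending eigendecomposition of a symmetric matrix.

    Eigenvalues are sorted descending (ties kept in original ascending-
    solver order, stably); each eigenvector's sign is fixed so that its
    largest-magnitude component is positive, first index winning ties.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("eigendecompose needs a square matrix")
    scale = max(1.0, float(np.abs(M).max()))
    if np.abs(M - M.T).max() > rtol * scale:
        raise ValidationError("matrix is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return EigenReport(eigenvalues=vals, eigenvectors=vecs)


def _variant_matrix(
    X: np.ndarray,
    w: np.ndarray,
    S: np.ndarray,
    n_bins: int,
    variant: str,
) -> np.ndarray:
    """One STC-variant matrix from a pre-built design matrix and weights."""
    C = (X * w[:, None]).T @ X / n_bins
    C = (C + C.T) / 2.0
    if variant == "C":
        return C
    n_r = float(w.sum())
    if n_r <= 0:
        raise DegenerateInputError("shifted response has no spikes in window")
    C0 = n_bins / n_r * C - S
    if variant == "C0":
        return C0
    a = X.T @ w / n_r
    if variant == "C1":
        return C0 - np.outer(a, a)
    if variant == "C2":
        nrm2 = float(a @ a)
        if nrm2 == 0:
            raise DegenerateInputError("zero STA under shift; C2 undefined")
        P = np.eye(a.size) - np.outer(a, a) / nrm2
        M = P @ C0 @ P.T
        return (M + M.T) / 2.0
    raise ValidationError(f"unknown variant {variant!r}; choose from {NULL_VARIANTS}")


def shift_null_ensemble(
    stimulus: StimulusEnsemble,
    response,
    lags: LagWindow,
    n_shifts: int = 1000,
    min_shift: int | None = None,
    seed: int = 0,
    matrix_variant: str = "C1",
    column: int = 0,
    store_matrices: bool = False,
) -> NullEnsemble:
    """Null spectra from circularly time-shifted responses.

    Draws ``n_shifts`` distinct offsets uniformly (seeded) from
    ``{min_shift .. T - min_shift}``, circularly shifts the response by
    each, recomputes the chosen matrix variant, and records its sorted
    eigenvalue spectrum.  ``min_shift`` must exceed ``tau`` so every shift
    decorrelates beyond the filter window; it defaults to ``tau + 1``.
    Circular shifts preserve both signals' marginal autocorrelation.

    ``matrix_variant`` is one of ``C0``/``C1``/``C2`` (spike counts) or
    ``C`` (the raw response-weighted covariance; works for continuous
    responses too).
    """
    if matrix_variant not in NULL_VARIANTS:
        raise ValidationError(
            f"unknown variant {matrix_variant!r}; choose from {NULL_VARIANTS}"
        )
    if isinstance(response, ResponseSet):
        r = (
            _spike_column(response, column)
            if matrix_variant != "C"
            else response.column(column)
        )
    else:
        r = (
            _spike_column(response, column)
            if matrix_variant != "C"
            else np.asarray(response, dtype=float).ravel()
        )
    T = stimulus.T
    if r.size != T:
        raise DimensionError(f"stimulus has T={T} but response has T={r.size}")
    lags.check_against(T)
    if min_shift is None:
        min_shift = lags.tau + 1
    if min_shift <= lags.tau:
        raise ValidationError(
            f"min_shift={min_shift} must exceed tau={lags.tau} so the shift "
            "decorrelates beyond the filter window"
        )
    if n_shifts < 2:
        raise ValidationError(f"need at least 2 shifts, got {n_shifts}")
    candidates = np.arange(min_shift, T - min_shift + 1)
    if candidates.size < n_shifts:
        raise ValidationError(
            f"only {candidates.size} admissible offsets for n_shifts={n_shifts}"
        )
    rng = np.random.default_rng(seed)
    shifts = rng.choice(candidates, size=n_shifts, replace=False)

    X = lag_design_matrix(stimulus.values, lags.tau)
    n_bins = T - lags.tau
    need_S = matrix_variant != "C"
    S = (
        stimulus_covariance(stimulus, lags).matrix
        if need_S
        else np.zeros((X.shape[1], X.shape[1]))
    )
    spectra = np.empty((n_shifts, X.shape[1]))
    kernels = [] if store_matrices else None
    for k, shift in enumerate(shifts):
        w = np.roll(r, int(shift))[lags.tau :]
        M = _variant_matrix(X, w, S, n_bins, matrix_variant)
        spectra[k] = np.linalg.eigvalsh(M)[::-1]
        if store_matrices:
            kernels.append(M)
    return NullEnsemble(
        shifts=shifts,
        spectra=spectra,
        seed=seed,
        variant=matrix_variant,
        tau=lags.tau,
        kernels=kernels,
    )


SIGNIFICANCE_METHODS = ("extreme", "rank")


def null_quantile_band(
    null: NullEnsemble, alpha: float = 0.05, method: str = "extreme"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided empirical acceptance band from the null spectra.

    ``method="extreme"`` (default) builds one family-wise band for the
    whole spectrum: the upper edge is the ``1 - alpha/2`` quantile of the
    *largest* null eigenvalue per shift, the lower edge the ``alpha/2``
    quantile of the *smallest*.  Any observed eigenvalue outside it is
    more extreme than the null matrices ever get, so the count of flagged
    eigenvalues estimates the number of genuine filter directions.

    ``method="rank"`` builds a separate ``[alpha/2, 1 - alpha/2]`` band
    per rank from the same-rank null eigenvalues.  This is exactly
    calibrated under the global null (no relationship at all), but once
    real filters occupy the top ranks the remaining observed noise
    eigenvalues are extremes over the signal-orthogonal complement while
    the null's same-rank values are interior order statistics, so
    mid-rank noise gets over-flagged.  Use it for calibration studies,
    not for counting filters.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    # Outward-rounded empirical quantiles: with n null draws the strict
    # exceedance test is then exchangeably exact (p <= alpha/2 per tail)
    # rather than slightly anti-conservative under linear interpolation.
    if method == "rank":
        low = np.quantile(null.spectra, alpha / 2.0, axis=0, method="lower")
        high = np.quantile(null.spectra, 1.0 - alpha / 2.0, axis=0, method="higher")
    elif method == "extreme":
        n = null.spectra.shape[1]
        low = np.full(
            n, np.quantile(null.spectra.min(axis=1), alpha / 2.0, method="lower")
        )
        high = np.full(
            n,
            np.quantile(null.spectra.max(axis=1), 1.0 - alpha / 2.0, method="higher"),
        )
    else:
        raise ValidationError(
            f"unknown method {method!r}; choose from {SIGNIFICANCE_METHODS}"
        )
    return low, high


def significant_eigenvalues(
    eigenvalues: np.ndarray,
    null: NullEnsemble,
    alpha: float = 0.05,
    method: str = "extreme",
) -> np.ndarray:
    """Boolean mask of eigenvalues strictly outside the null band.

    See :func:`null_quantile_band` for the two band constructions.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float).ravel()
    if null.spectra.size == 0:
        raise ValidationError("empty null ensemble")
    if eigenvalues.size != null.spectra.shape[1]:
        raise DimensionError(
            f"observed spectrum has {eigenvalues.size} eigenvalues but the null "
            f"has {null.spectra.shape[1]}"
        )
    low, high = null_quantile_band(null, alpha, method)
    return (eigenvalues < low) | (eigenvalues > high)


def evaluate_significance(
    report: EigenReport,
    null: NullEnsemble,
    alpha: float = 0.05,
    method: str = "extreme",
) -> EigenReport:
    """A copy of ``report`` annotated with the null band and significance mask."""
    low, high = null_quantile_band(null, alpha, method)
    mask = significant_eigenvalues(report.eigenvalues, null, alpha, method)
    return EigenReport(
        eigenvalues=report.eigenvalues,
        eigenvectors=report.eigenvectors,
        null_low=low,
        null_high=high,
        significant=mask,
        alpha=alpha,
    )


def filter_subspace_check(vectors, true_filters) -> np.ndarray:
    """Cosine similarity of each true filter to its projection on a span.

    ``vectors`` are the recovered basis (columns, or a list of vectors) —
    typically the significant eigenvectors, with the STA appended for the
    STA-projected variant since the projection removed that direction.
    For each true filter the least-squares best linear combination of the
    vectors is formed and the cosine similarity between filter and
    combination is returned (1 = filter inside the span, 0 = orthogonal).
    """
    cols = [np.asarray(v, dtype=float).ravel() for v in _iter_cols(vectors)]
    if len(cols) == 0 or all(c.size == 0 for c in cols):
        raise ValidationError("empty vector set")
    B = np.column_stack(cols)
    sims = []
    for f in _iter_cols(true_filters):
        f = np.asarray(f, dtype=float).ravel()
        if f.size != B.shape[0]:
            raise DimensionError(
                f"filter length {f.size} does not match vector length {B.shape[0]}"
            )
        coef, *_ = np.linalg.lstsq(B, f, rcond=None)
        proj = B @ coef
        fn, pn = np.linalg.norm(f), np.linalg.norm(proj)
        sims.append(0.0 if fn == 0 or pn == 0 else float(f @ proj / (fn * pn)))
    return np.asarray(sims)


def _iter_cols(obj):
    arr = np.asarray(obj, dtype=float) if not isinstance(obj, (list, tuple)) else obj
    if isinstance(arr, np.ndarray):
        if arr.ndim == 1:
            return [arr]
        return [arr[:, k] for k in range(arr.shape[1])]
    return list(arr)
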