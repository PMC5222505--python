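"""Response-weighted stimulus covariance and the second-order Wiener kernel.

The central estimator is

    C_ij = 1/(T - tau) * sum_{t = tau+1..T} r_t s_{t-i} s_{t-j}

(1-based time, lags i, j in 0..tau): the covariance of the lagged stimulus
weighted by the simultaneous response.  For a multidimensional stimulus the
matrix is organized block-wise per ordered pair of stimulus dimensions
(layout ``dim_major_lag_minor``).  The sum starts at the first bin with a
complete lag window — no zero padding — and the denominator is the number
of summed bins, ``T - tau``.

For Gaussian white-noise input of standard deviation ``sigma`` sampled
every ``dt``, and a mean-subtracted response, ``C`` is proportional to the
second-order Wiener kernel:

    K2 = C / (2 sigma^4 dt^2)

Two backends compute ``C``: a naive per-entry reference that sums the
triple loop directly, and an accelerated backend that builds the lagged
design matrix once and reduces the estimator to a weighted Gram product.
Both accumulate in double precision; they agree to near machine precision
and :func:`backend_equivalence` measures the discrepancy directly.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ContractError, DimensionError, ValidationError
from .types import (
    ROLE_RESPONSE_WEIGHTED,
    ROLE_STIMULUS,
    ROLE_WIENER,
    BlockCovariance,
    LagWindow,
    ResponseSet,
    StimulusEnsemble,
)

try:  # numba only speeds up the reference loop; the package works without it
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only where numba is absent
    _HAVE_NUMBA = False

BACKEND_REFERENCE = "reference"
BACKEND_ACCELERATED = "accelerated"
BACKENDS = (BACKEND_REFERENCE, BACKEND_ACCELERATED)


def lag_design_matrix(values: np.ndarray, tau: int) -> np.ndarray:
    """Build the lag-expanded design matrix of a ``T x D`` signal.

    Row ``k`` corresponds to time bin ``tau + k`` (0-based) and column
    ``d * L + i`` holds the sample of dimension ``d`` at lag ``i``, so each
    row is the full stimulus window preceding (and including) that bin.
    Shape: ``(T - tau, D * L)``.
    """
    values = np.asarray(values, dtype=float)
    T, D = values.shape
    L = tau + 1
    X = np.empty((T - tau, D * L), dtype=float)
    for d in range(D):
        for i in range(L):
            X[:, d * L + i] = values[tau - i : T - i, d]
    return X


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def _weights(r: np.ndarray, tau: int, demean: bool) -> np.ndarray:
    w = np.asarray(r, dtype=float)[tau:]
    if demean:
        w = w - w.mean()
    return w


def _rwc_accelerated(
    values: np.ndarray, r: np.ndarray, tau: int, demean: bool
) -> np.ndarray:
    T = values.shape[0]
    X = lag_design_matrix(values, tau)
    w = _weights(r, tau, demean)
    M = (X * w[:, None]).T @ X / (T - tau)
    return _symmetrize(M)


def _rwc_reference_python(
    values: np.ndarray, r: np.ndarray, tau: int, demean: bool
) -> np.ndarray:
    """Per-entry reference: each C_ij summed directly over time."""
    T, D = values.shape
    L = tau + 1
    w = _weights(r, tau, demean)
    n = D * L
    out = np.zeros((n, n), dtype=float)
    for d1 in range(D):
        for i in range(L):
            p = d1 * L + i
            si = values[tau - i : T - i, d1]
            for d2 in range(D):
                for j in range(L):
                    q = d2 * L + j
                    if q < p:
                        continue
                    sj = values[tau - j : T - j, d2]
                    acc = 0.0
                    for k in range(T - tau):
                        acc += w[k] * si[k] * sj[k]
                    out[p, q] = acc / (T - tau)
                    out[q, p] = out[p, q]
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _rwc_reference_loops(values, w, tau):  # pragma: no cover - compiled
        T, D = values.shape
        L = tau + 1
        n = D * L
        out = np.zeros((n, n))
        for d1 in range(D):
            for i in range(L):
                p = d1 * L + i
                for d2 in range(D):
                    for j in range(L):
                        q = d2 * L + j
                        if q < p:
                            continue
                        acc = 0.0
                        for t in range(tau, T):
                            acc += w[t - tau] * values[t - i, d1] * values[t - j, d2]
                        out[p, q] = acc / (T - tau)
                        out[q, p] = out[p, q]
        return out

    def _rwc_reference(values, r, tau, demean):
        w = _weights(r, tau, demean)
        return _rwc_reference_loops(
            np.ascontiguousarray(values, dtype=np.float64),
            np.ascontiguousarray(w, dtype=np.float64),
            tau,
        )

else:  # pragma: no cover - exercised only where numba is absent
    _rwc_reference = _rwc_reference_python


_BACKEND_FUNCS = {
    BACKEND_REFERENCE: lambda v, r, tau, demean: _rwc_reference(v, r, tau, demean),
    BACKEND_ACCELERATED: _rwc_accelerated,
}


def _validate_pair(
    stimulus: StimulusEnsemble, responses: ResponseSet, lags: LagWindow
) -> None:
    if responses.T != stimulus.T:
        raise DimensionError(
            f"stimulus has T={stimulus.T} but responses have T={responses.T}"
        )
    lags.check_against(stimulus.T)


def response_weighted_covariance(
    stimulus: StimulusEnsemble,
    responses: ResponseSet,
    lags: LagWindow,
    demean_response: bool = False,
    backend: str = BACKEND_ACCELERATED,
) -> list[BlockCovariance]:
    """Estimate the response-weighted stimulus covariance, per response.

    Entry ``(d1*L + i, d2*L + j)`` of each output is

        1/(T - tau) * sum_{t=tau+1..T} r_t s_{t-i, d1} s_{t-j, d2}

    With ``demean_response`` the response is replaced by
    ``r - mean(r)`` (mean over the summed bins ``tau+1..T``) before
    weighting, which is the condition under which the result is
    proportional to the second-order Wiener kernel.  Returns one
    :class:`~wienerstc.types.BlockCovariance` per response column, all
    computed in a single pass over the stimulus windows.
    """
    _validate_pair(stimulus, responses, lags)
    if backend not in _BACKEND_FUNCS:
        raise ValidationError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    func = _BACKEND_FUNCS[backend]
    out = []
    for col in range(responses.R):
        M = func(stimulus.values, responses.column(col), lags.tau, demean_response)
        out.append(
            BlockCovariance(
                matrix=M,
                role=ROLE_RESPONSE_WEIGHTED,
                tau=lags.tau,
                D=stimulus.D,
                normalization=float(stimulus.T - lags.tau),
                demeaned=demean_response,
            )
        )
    return out


def stimulus_covariance(
    stimulus: StimulusEnsemble,
    lags: LagWindow,
    backend: str = BACKEND_ACCELERATED,
) -> BlockCovariance:
    """Plain lagged stimulus covariance ``S``.

    Identical to the response-weighted covariance with every response set
    to 1 and no demeaning (the two formulas coincide for a unit response),
    and computed through exactly that code path so the reduction holds
    bit for bit.
    """
    ones = ResponseSet(np.ones(stimulus.T))
    cov = response_weighted_covariance(
        stimulus, ones, lags, demean_response=False, backend=backend
    )[0]
    cov.role = ROLE_STIMULUS
    return cov


def wiener_kernel(
    cov: BlockCovariance, sigma: float, dt: float
) -> BlockCovariance:
    """Rescale a response-weighted covariance to the second-order Wiener kernel.

    ``K2 = C / (2 sigma^4 dt^2)``.  Valid only when the response had zero
    mean, so ``cov`` must have been computed with ``demean_response``;
    passing a non-demeaned covariance raises :class:`ContractError`.
    """
    if cov.role != ROLE_RESPONSE_WEIGHTED:
        raise ContractError(
            f"Wiener rescaling applies to a response-weighted covariance, "
            f"got role {cov.role!r}"
        )
    if not cov.demeaned:
        raise ContractError(
            "Wiener rescaling requires a demeaned response (<r> = 0); "
            "recompute the covariance with demean_response=True"
        )
    if not sigma > 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    if not dt > 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    return BlockCovariance(
        matrix=cov.matrix / (2.0 * sigma**4 * dt**2),
        role=ROLE_WIENER,
        tau=cov.tau,
        D=cov.D,
        normalization=cov.normalization,
        demeaned=True,
    )


def backend_equivalence(
    stimulus: StimulusEnsemble,
    responses: ResponseSet,
    lags: LagWindow,
    demean_response: bool = False,
) -> float:
    """Max absolute entrywise discrepancy between the two backends.

    Runs both the per-entry reference and the accelerated Gram-product
    implementation on the same inputs and returns the largest absolute
    difference over all response columns.  Meant for modest problem sizes
    where the naive loop is affordable.
    """
    ref = response_weighted_covariance(
        stimulus, responses, lags, demean_response, backend=BACKEND_REFERENCE
    )
    acc = response_weighted_covariance(
        stimulus, responses, lags, demean_response, backend=BACKEND_ACCELERATED
    )
    return max(
        float(np.abs(a.matrix - b.matrix).max()) for a, b in zip(ref, acc)
    )
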