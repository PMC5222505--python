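"""Core data containers for reverse-correlation analysis.

All lag-expanded vectors and matrices in this package share one layout,
``dim_major_lag_minor``: the flattened index for spatial dimension ``d``
and lag ``i`` is ``d * L + i``, where ``L = tau + 1`` is the number of
taps and lag ``i`` refers to the stimulus ``i`` bins before the response
bin.  The layout string is carried on every covariance object and written
to every output file so that downstream consumers never have to guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DimensionError, LagError, ValidationError

#: Canonical layout descriptor: row/column index = d * L + i.
LAYOUT = "dim_major_lag_minor"

MODE_CONTINUOUS = "continuous"
MODE_SPIKES = "spike-counts"

#: Relative tolerance within which stored covariance matrices must be symmetric.
SYMMETRY_RTOL = 1e-12


def _require_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValidationError(f"expected a 1-D or 2-D array, got ndim={arr.ndim}")
    return arr


@dataclass
class StimulusEnsemble:
    """A stimulus recording: ``T`` time bins by ``D`` spatial dimensions.

    Parameters
    ----------
    values
        ``T x D`` array of stimulus samples (a 1-D array is treated as
        ``D = 1``).  For white-noise reverse correlation these are i.i.d.
        Gaussian draws, but any finite real signal is accepted.
    dt
        Sampling interval, in the caller's time units.  Enters only the
        Wiener rescaling.
    sigma
        Nominal stimulus standard deviation.  Supplied by the caller (the
        simulator knows it exactly; for recorded data, estimate it);
        the estimators never demean or rescale the stimulus themselves.
    """

    values: np.ndarray
    dt: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        _require_finite(self.values, "stimulus")
        if self.T < 2:
            raise ValidationError(f"stimulus needs at least 2 samples, got T={self.T}")
        if self.D < 1:
            raise ValidationError("stimulus needs at least one spatial dimension")
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseSet:
    """One or more responses aligned bin-for-bin with a stimulus.

    ``values`` is ``T x R`` (a 1-D array is one response).  ``mode`` is
    either :data:`MODE_CONTINUOUS` (e.g. membrane voltage, calcium
    fluorescence) or :data:`MODE_SPIKES`, in which case every entry must
    be a non-negative integer spike count per bin.  ``warmup`` marks how
    many leading bins were zero-filled by a simulator because their lag
    window is incomplete; estimators start past the window anyway, so the
    flag is informational.
    """

    values: np.ndarray
    mode: str = MODE_CONTINUOUS
    warmup: int = 0

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        _require_finite(self.values, "response")
        if self.mode not in (MODE_CONTINUOUS, MODE_SPIKES):
            raise ValidationError(f"unknown response mode {self.mode!r}")
        if self.mode == MODE_SPIKES:
            v = self.values
            if np.any(v < 0) or not np.array_equal(v, np.round(v)):
                raise ValidationError(
                    "spike-count responses must be non-negative integers"
                )

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def R(self) -> int:
        return self.values.shape[1]

    def column(self, r: int = 0) -> np.ndarray:
        return self.values[:, r]


@dataclass(frozen=True)
class LagWindow:
    """Causal lag window: taps at lags ``0..tau`` inclusive (``L = tau + 1``)."""

    tau: int

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 0:
            raise LagError(f"tau must be a non-negative integer, got {self.tau}")
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def L(self) -> int:
        return self.tau + 1

    def check_against(self, T: int) -> None:
        if self.tau >= T:
            raise LagError(f"tau={self.tau} must be smaller than T={T}")


# Role tags for BlockCovariance.
ROLE_RESPONSE_WEIGHTED = "C"
ROLE_STIMULUS = "S"
ROLE_WIENER = "K2"


@dataclass
class BlockCovariance:
    """A ``(D*L) x (D*L)`` symmetric lagged-covariance matrix.

    The matrix is organized block-wise by ordered pair of stimulus
    dimensions, each block being ``L x L`` over lag pairs — see
    :data:`LAYOUT`.  ``role`` records what the matrix is: the
    response-weighted stimulus covariance ``C``, the plain stimulus
    covariance ``S``, or the Wiener-rescaled kernel ``K2``.
    ``normalization`` is the denominator used (the number of summed time
    bins, ``T - tau``), and ``demeaned`` records whether the response was
    mean-subtracted before weighting — the Wiener rescaling requires it.
    """

    matrix: np.ndarray
    role: str
    tau: int
    D: int
    normalization: float
    demeaned: bool = False
    layout: str = LAYOUT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.D * (self.tau + 1)
        if self.matrix.shape != (n, n):
            raise DimensionError(
                f"matrix shape {self.matrix.shape} != ({n}, {n}) for D={self.D}, "
                f"tau={self.tau}"
            )
        scale = max(1.0, float(np.abs(self.matrix).max()))
        if np.abs(self.matrix - self.matrix.T).max() > SYMMETRY_RTOL * scale:
            raise ValidationError("covariance matrix is not symmetric")
        if self.role not in (ROLE_RESPONSE_WEIGHTED, ROLE_STIMULUS, ROLE_WIENER):
            raise ValidationError(f"unknown role {self.role!r}")

    @property
    def L(self) -> int:
        return self.tau + 1

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def block(self, d1: int, d2: int) -> np.ndarray:
        """The ``L x L`` lag block for the ordered dimension pair (d1, d2)."""
        L = self.L
        return self.matrix[d1 * L : (d1 + 1) * L, d2 * L : (d2 + 1) * L]


@dataclass
class SpikeTriggeredAverage:
    """The STA ``a`` (layout :data:`LAYOUT`) and the spike count ``n_r`` behind it."""

    a: np.ndarray
    n_r: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        if self.n_r < 0:
            raise ValidationError("spike count n_r cannot be negative")


@dataclass
class STCResult:
    """The three STC matrix variants plus the STA they were built from.

    ``C0`` is the raw spike-triggered covariance, ``C1`` the STA-subtracted
    form ``C0 - a a^T``, and ``C2`` the STA-projected form
    ``(I - A') C0 (I - A')^T`` with ``A' = a a^T / (a^T a)``.
    """

    C0: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    sta: SpikeTriggeredAverage
    A: np.ndarray = field(init=False)
    A_prime: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = self.sta.a
        self.A = np.outer(a, a)
        nrm2 = float(a @ a)
        self.A_prime = self.A / nrm2 if nrm2 > 0 else np.zeros_like(self.A)

    def variant(self, name: str) -> np.ndarray:
        try:
            return {"C0": self.C0, "C1": self.C1, "C2": self.C2}[name]
        except KeyError:
            raise ValidationError(f"unknown STC variant {name!r}") from None


@dataclass
class EigenReport:
    """Eigenspectrum of an STC matrix, optionally with a significance call.

    ``eigenvalues`` are sorted descending with matching orthonormal
    ``eigenvectors`` columns; each eigenvector's sign is fixed so that its
    largest-magnitude component is positive.  When a null ensemble has
    been evaluated, ``null_low``/``null_high`` hold the per-rank empirical
    quantile band and ``significant`` flags eigenvalues outside it.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    null_low: Optional[np.ndarray] = None
    null_high: Optional[np.ndarray] = None
    significant: Optional[np.ndarray] = None
    alpha: Optional[float] = None

    @property
    def significant_vectors(self) -> np.ndarray:
        """Columns of ``eigenvectors`` whose eigenvalues were flagged significant."""
        if self.significant is None:
            raise ValidationError("significance has not been evaluated")
        return self.eigenvectors[:, self.significant]


@dataclass
class NullEnsemble:
    """Eigenvalue spectra of kernels recomputed under response time-shifts.

    Circularly shifting the response relative to the stimulus by more than
    the filter length destroys their relationship while preserving each
    signal's own correlation structure, so the shifted kernels sample the
    null distribution 'stimulus and response are unrelated'.
    """

    shifts: np.ndarray
    spectra: np.ndarray  # (n_shifts, D*L), each row sorted descending
    seed: int
    variant: str
    tau: int
    kernels: Optional[list] = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.shifts.size < 2:
            raise ValidationError("a null ensemble needs at least 2 shifts")
        if np.unique(self.shifts).size != self.shifts.size:
            raise ValidationError("null shifts must be distinct")
        if np.any(np.abs(self.shifts) <= self.tau):
            raise ValidationError("every |shift| must exceed tau")

    @property
    def n_shifts(self) -> int:
        return self.shifts.size
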