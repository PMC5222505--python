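"""Synthetic model cells for end-to-end validation of the estimators.

Two generative models are provided, matching the two standard test beds
for second-order reverse correlation:

* a *pure second-order Volterra responder*: the continuous response is a
  quadratic form of the lagged stimulus window, ``r_t = x_t^T G2 x_t``.
  Driven by Gaussian white noise with a demeaned response, the estimated
  Wiener kernel converges to ``G2`` as the recording grows, because the
  system has no components of other orders.

* a *two-filter rectified LNP spiker*: two linear filters act on the
  stimulus window, each output is half-wave rectified, the rectified
  drives are summed and scaled into an expected spike count per bin, and
  spikes are drawn from a Poisson distribution.  This is the classic
  regime where the STA mixes the filters and spike-triggered covariance
  is needed to recover the filter subspace.

All randomness flows through explicit integer seeds via numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ValidationError
from .kernel import lag_design_matrix
from .types import (
    MODE_CONTINUOUS,
    MODE_SPIKES,
    BlockCovariance,
    ResponseSet,
    StimulusEnsemble,
)

#: Expected spikes per bin used for the two-filter demonstration cell.
DEFAULT_MEAN_RATE = 0.0045


@dataclass
class VolterraModel:
    """A purely second-order system: ``r_t = x_t^T G2 x_t``.

    ``G2`` is the ``(D*L) x (D*L)`` symmetric second-order Volterra kernel
    in ``dim_major_lag_minor`` layout; ``x_t`` is the lagged stimulus
    window at bin ``t``.
    """

    G2: np.ndarray

    def __post_init__(self) -> None:
        self.G2 = np.asarray(self.G2, dtype=float)
        if self.G2.ndim != 2 or self.G2.shape[0] != self.G2.shape[1]:
            raise ValidationError("G2 must be a square matrix")
        if not np.all(np.isfinite(self.G2)):
            raise ValidationError("G2 contains non-finite values")
        if not np.allclose(self.G2, self.G2.T, rtol=1e-12, atol=1e-12):
            raise ValidationError("G2 must be symmetric")


@dataclass
class LNPModel:
    """Linear-nonlinear-Poisson cell with per-filter half-wave rectification.

    Expected spikes in bin ``t``:  ``gain * sum_k max(0, f_k . x_t)``
    where ``x_t`` is the lagged stimulus window.  ``gain`` converts summed
    rectified drive into spikes per bin.
    """

    filters: list = field(default_factory=list)
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.filters = [np.asarray(f, dtype=float).ravel() for f in self.filters]
        if len(self.filters) < 1:
            raise ValidationError("LNPModel needs at least one filter")
        n = self.filters[0].size
        if any(f.size != n for f in self.filters):
            raise DimensionError("all filters must have the same length")
        if self.gain < 0:
            raise ValidationError(f"gain must be non-negative, got {self.gain}")

    @property
    def filter_matrix(self) -> np.ndarray:
        """Filters stacked as columns, shape ``(D*L, n_filters)``."""
        return np.column_stack(self.filters)


def gaussian_white_stimulus(
    T: int, D: int, sigma: float = 1.0, dt: float = 1.0, seed: int = 0
) -> StimulusEnsemble:
    """I.i.d. Gaussian stimulus, mean 0, std ``sigma``, per bin per dimension."""
    if T < 2 or D < 1:
        raise ValidationError(f"need T >= 2 and D >= 1, got T={T}, D={D}")
    rng = np.random.default_rng(seed)
    return StimulusEnsemble(rng.normal(0.0, sigma, size=(T, D)), dt=dt, sigma=sigma)


def random_volterra_kernel(D: int, L: int, seed: int = 0) -> VolterraModel:
    """Seeded random symmetric kernel with unit Frobenius norm.

    A Gaussian matrix is symmetrized as ``(M + M^T)/2`` and normalized;
    such full-rank kernels make demanding recovery targets.
    """
    if D < 1 or L < 1:
        raise ValidationError("D and L must be at least 1")
    rng = np.random.default_rng(seed)
    n = D * L
    M = rng.normal(size=(n, n))
    M = (M + M.T) / 2.0
    return VolterraModel(M / np.linalg.norm(M, "fro"))


def volterra_response(
    stimulus: StimulusEnsemble, model: VolterraModel
) -> ResponseSet:
    """Continuous response of a pure second-order system.

    ``r_t = sum_{(d1,i),(d2,j)} G2[(d1,i),(d2,j)] s_{t-i,d1} s_{t-j,d2}``
    for ``t = tau+1..T``; the first ``tau`` bins lack a full window, are
    zero-filled, and flagged via ``warmup``.
    """
    n = model.G2.shape[0]
    if n % stimulus.D != 0:
        raise DimensionError(
            f"kernel size {n} is not a multiple of D={stimulus.D}"
        )
    L = n // stimulus.D
    tau = L - 1
    if stimulus.T <= tau:
        raise DimensionError(f"stimulus too short (T={stimulus.T}) for tau={tau}")
    X = lag_design_matrix(stimulus.values, tau)
    r = np.zeros(stimulus.T)
    r[tau:] = np.einsum("ti,ij,tj->t", X, model.G2, X, optimize=True)
    return ResponseSet(r, mode=MODE_CONTINUOUS, warmup=tau)


def lnp_spikes(
    stimulus: StimulusEnsemble, model: LNPModel, seed: int = 0
) -> ResponseSet:
    """Poisson spike counts from a rectified multi-filter LNP cell.

    Warm-up bins (incomplete lag window) have zero rate.  Counts are raw
    Poisson draws and may exceed 1 per bin.
    """
    F = model.filter_matrix
    if F.shape[0] % stimulus.D != 0:
        raise DimensionError("filter length is not a multiple of D")
    L = F.shape[0] // stimulus.D
    tau = L - 1
    if stimulus.T <= tau:
        raise DimensionError(f"stimulus too short (T={stimulus.T}) for tau={tau}")
    X = lag_design_matrix(stimulus.values, tau)
    drive = np.maximum(X @ F, 0.0).sum(axis=1)
    rate = np.zeros(stimulus.T)
    rate[tau:] = model.gain * drive
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate)
    return ResponseSet(counts.astype(float), mode=MODE_SPIKES, warmup=tau)


def expected_rectified_rate(model: LNPModel, sigma: float) -> float:
    """Closed-form expected spikes/bin under Gaussian white input.

    For ``x ~ N(0, sigma^2 I)``, ``E[max(0, f . x)] = sigma ||f|| / sqrt(2 pi)``
    (half-normal mean), so the expected rate is
    ``gain * sigma * sum_k ||f_k|| / sqrt(2 pi)``.
    """
    norms = sum(float(np.linalg.norm(f)) for f in model.filters)
    return model.gain * sigma * norms / np.sqrt(2.0 * np.pi)


def calibrate_gain(model: LNPModel, sigma: float, target_rate: float) -> float:
    """Gain that yields ``target_rate`` expected spikes/bin, in closed form."""
    if not target_rate > 0:
        raise ValidationError(f"target_rate must be positive, got {target_rate}")
    norms = sum(float(np.linalg.norm(f)) for f in model.filters)
    if norms == 0:
        raise ValidationError("cannot calibrate gain for all-zero filters")
    return target_rate / (sigma * norms / np.sqrt(2.0 * np.pi))


def biphasic_filter_pair(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal smooth biphasic temporal filters of length ``L``.

    Deterministic fixtures shaped like the fast/slow biphasic impulse
    responses typical of early sensory neurons: a gamma-difference filter
    and a damped oscillation, Gram-Schmidt orthogonalized and unit-normed.
    Index ``i`` of each filter weights the stimulus ``i`` bins in the past.
    """
    if L < 4:
        raise ValidationError(f"need at least 4 taps for a biphasic pair, got L={L}")
    t = np.arange(L, dtype=float)
    t1, t2 = L / 6.0, L / 3.0
    f1 = (t / t1) * np.exp(-t / t1) - 0.55 * (t / t2) * np.exp(-t / t2)
    f2 = np.sin(2.0 * np.pi * t / L) * np.exp(-t / t2)
    f1 = f1 / np.linalg.norm(f1)
    f2 = f2 - (f2 @ f1) * f1
    f2 = f2 / np.linalg.norm(f2)
    return f1, f2


def two_filter_lnp(
    L: int,
    sigma: float = 1.0,
    target_rate: float = DEFAULT_MEAN_RATE,
) -> LNPModel:
    """The two-filter demonstration cell, gain-calibrated to ``target_rate``."""
    f1, f2 = biphasic_filter_pair(L)
    model = LNPModel(filters=[f1, f2], gain=1.0)
    model.gain = calibrate_gain(model, sigma, target_rate)
    return model


def kernel_estimation_error(
    estimate: BlockCovariance | np.ndarray, truth: VolterraModel | np.ndarray
) -> float:
    """Relative Frobenius error ``||estimate - truth||_F / ||truth||_F``."""
    E = estimate.matrix if isinstance(estimate, BlockCovariance) else np.asarray(estimate)
    G = truth.G2 if isinstance(truth, VolterraModel) else np.asarray(truth)
    if E.shape != G.shape:
        raise DimensionError(f"shape mismatch: {E.shape} vs {G.shape}")
    denom = np.linalg.norm(G, "fro")
    if denom == 0:
        raise ValidationError("truth kernel has zero norm")
    return float(np.linalg.norm(E - G, "fro") / denom)
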