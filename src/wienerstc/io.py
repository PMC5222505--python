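"""Readers and writers for the package's on-disk formats.

HDF5 is the canonical interchange format; CSV/TSV is supported for small
inputs.  Conventions:

* stimulus/response pair file (HDF5): datasets ``stimulus`` (T x D) and
  ``response`` (T x R), root attributes ``dt`` and ``sigma``;
* pair file (CSV/TSV): header row with stimulus columns ``s0..s{D-1}``
  and response columns ``r0..r{R-1}``; ``dt``/``sigma`` travel out of
  band (CLI flags);
* covariance file (HDF5): dataset ``matrix`` with attributes ``role``,
  ``tau``, ``D``, ``layout``, ``normalization``, ``demeaned``;
* STC report file (HDF5): datasets ``C0``, ``C1``, ``C2``, ``sta``;
  per-variant eigen-reports under groups ``eigen/<variant>``; root-level
  datasets ``eigenvalues``, ``eigenvectors`` and, when significance was
  assessed, ``null_quantiles`` ((2, n): low/high rows) and
  ``significant`` for the variant the run focused on.

Every output carries enough metadata (tau, layout, sigma, dt, seeds,
variant, package version) to re-derive it from its inputs alone.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .types import (
    LAYOUT,
    MODE_CONTINUOUS,
    MODE_SPIKES,
    BlockCovariance,
    EigenReport,
    ResponseSet,
    StimulusEnsemble,
)


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def _csv_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_pair(
    path, stimulus: StimulusEnsemble, responses: ResponseSet
) -> None:
    """Write an aligned stimulus/response pair (format chosen by extension)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset("stimulus", data=stimulus.values)
            f.create_dataset("response", data=responses.values)
            f.attrs["dt"] = stimulus.dt
            f.attrs["sigma"] = stimulus.sigma
            f.attrs["response_mode"] = responses.mode
            f.attrs["warmup"] = responses.warmup
            f.attrs["wienerstc_version"] = __version__
    else:
        cols = {f"s{d}": stimulus.values[:, d] for d in range(stimulus.D)}
        cols.update({f"r{r}": responses.values[:, r] for r in range(responses.R)})
        pd.DataFrame(cols).to_csv(path, sep=_csv_sep(path), index=False)


def read_pair(
    path, dt: float = 1.0, sigma: float = 1.0, spike_counts: bool | None = None
) -> tuple[StimulusEnsemble, ResponseSet]:
    """Read a stimulus/response pair written by :func:`write_pair`.

    For CSV/TSV, ``dt`` and ``sigma`` must be supplied by the caller;
    for HDF5 they are read from the file attributes.  ``spike_counts``
    forces the response mode; when ``None`` the stored mode (HDF5) or an
    integer/non-negativity sniff (CSV) decides.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "stimulus" not in f or "response" not in f:
                raise ValidationError(
                    f"{path} lacks 'stimulus'/'response' datasets"
                )
            s = np.asarray(f["stimulus"])
            r = np.asarray(f["response"])
            dt = float(f.attrs.get("dt", dt))
            sigma = float(f.attrs.get("sigma", sigma))
            mode = str(f.attrs.get("response_mode", MODE_CONTINUOUS))
            warmup = int(f.attrs.get("warmup", 0))
    else:
        df = pd.read_csv(path, sep=_csv_sep(path), float_precision="round_trip")
        s_cols = sorted(
            (c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        r_cols = sorted(
            (c for c in df.columns if c.startswith("r") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not s_cols or not r_cols:
            raise ValidationError(
                f"{path} must have header columns s0..s(D-1) and r0..r(R-1)"
            )
        s = df[s_cols].to_numpy(dtype=float)
        r = df[r_cols].to_numpy(dtype=float)
        mode = None
        warmup = 0
    if spike_counts is not None:
        mode = MODE_SPIKES if spike_counts else MODE_CONTINUOUS
    elif mode is None:
        is_counts = np.all(r >= 0) and np.array_equal(r, np.round(r))
        mode = MODE_SPIKES if is_counts else MODE_CONTINUOUS
    return (
        StimulusEnsemble(s, dt=dt, sigma=sigma),
        ResponseSet(r, mode=mode, warmup=warmup),
    )


def write_covariance(path, cov: BlockCovariance, extra_attrs: dict | None = None) -> None:
    """Write a covariance/kernel matrix with its full provenance attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=cov.matrix)
        f.attrs["role"] = cov.role
        f.attrs["tau"] = cov.tau
        f.attrs["D"] = cov.D
        f.attrs["layout"] = cov.layout
        f.attrs["normalization"] = cov.normalization
        f.attrs["demeaned"] = cov.demeaned
        f.attrs["wienerstc_version"] = __version__
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def read_covariance(path) -> BlockCovariance:
    path = Path(path)
    with h5py.File(path, "r") as f:
        return BlockCovariance(
            matrix=np.asarray(f["matrix"]),
            role=str(f.attrs["role"]),
            tau=int(f.attrs["tau"]),
            D=int(f.attrs["D"]),
            normalization=float(f.attrs["normalization"]),
            demeaned=bool(f.attrs["demeaned"]),
            layout=str(f.attrs.get("layout", LAYOUT)),
        )


def dump_matrix_csv(path, matrix: np.ndarray) -> None:
    """Plain CSV dump of a full matrix (no header), for quick inspection."""
    np.savetxt(Path(path), np.asarray(matrix), delimiter=",")


def write_stc_report(
    path,
    result,
    reports: dict[str, EigenReport],
    attrs: dict | None = None,
) -> None:
    """Write STC matrices, the STA, and per-variant eigen-reports to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("C0", data=result.C0)
        f.create_dataset("C1", data=result.C1)
        f.create_dataset("C2", data=result.C2)
        f.create_dataset("sta", data=result.sta.a)
        f.attrs["n_r"] = result.sta.n_r
        f.attrs["layout"] = LAYOUT
        f.attrs["wienerstc_version"] = __version__
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for name, rep in reports.items():
            g = f.create_group(f"eigen/{name}")
            g.create_dataset("eigenvalues", data=rep.eigenvalues)
            g.create_dataset("eigenvectors", data=rep.eigenvectors)
            if rep.significant is not None:
                g.create_dataset(
                    "null_quantiles", data=np.vstack([rep.null_low, rep.null_high])
                )
                g.create_dataset("significant", data=rep.significant)
                g.attrs["alpha"] = rep.alpha
        # convenience copies at the root for the variant the run focused on
        focus = (attrs or {}).get("variant")
        if focus in reports:
            rep = reports[focus]
            f.create_dataset("eigenvalues", data=rep.eigenvalues)
            f.create_dataset("eigenvectors", data=rep.eigenvectors)
            if rep.significant is not None:
                f.create_dataset(
                    "null_quantiles", data=np.vstack([rep.null_low, rep.null_high])
                )
                f.create_dataset("significant", data=rep.significant)
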