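"""Containers and elementary transforms for ROI time-series data.

The estimators in this package consume a ``T x p`` matrix of region-of-interest
(ROI) time series (rows = time points, columns = ROIs, known repetition time TR
in seconds).  Before model fitting each column is min-max normalised to [0, 1]
and dichotomised at 0.5 into "High" (+1) / "Low" (-1) activity labels; the
continuous normalised values serve as predictors while the labels serve as the
logistic-regression responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeriesMatrix",
    "NormalizedSeries",
    "ActivityLabels",
    "DfcTensor",
    "DfcEdgeSeries",
    "minmax_normalize",
    "dichotomize",
    "vectorize_upper",
    "unvectorize_upper",
    "upper_triangle_pairs",
    "read_timeseries",
    "write_timeseries",
    "write_edge_series",
]

_SYMMETRY_TOL = 1e-8


def _as_float_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D T x p matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("time-series matrix contains non-finite values")
    return arr


@dataclass(frozen=True)
class RoiTimeSeriesMatrix:
    """Raw ``T x p`` ROI observations with repetition time in seconds."""

    values: np.ndarray
    roi_names: tuple[str, ...] = ()
    tr: float = 1.0

    def __post_init__(self):
        arr = _as_float_matrix(self.values)
        object.__setattr__(self, "values", arr)
        T, p = arr.shape
        if T < 2 or p < 2:
            raise ValueError(f"need T >= 2 and p >= 2, got T={T}, p={p}")
        names = tuple(self.roi_names) or tuple(f"ROI{i + 1}" for i in range(p))
        if len(names) != p:
            raise ValueError("number of ROI names does not match number of columns")
        if len(set(names)) != p:
            raise ValueError("ROI names must be unique")
        object.__setattr__(self, "roi_names", names)
        if not self.tr > 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NormalizedSeries:
    """Column-wise min-max normalised series; every column lies in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_float_matrix(self.values)
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("normalised values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class ActivityLabels:
    """Dichotomised activity levels, entries in {-1, +1}."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError("activity labels must be -1 or +1")
        object.__setattr__(self, "values", arr.astype(np.int8))


@dataclass(frozen=True)
class DfcTensor:
    """Per-timepoint symmetric weighted networks, ``theta[t]`` of shape p x p.

    ``times`` holds the (0-based) sample index each network refers to; the
    KELLER estimator covers every sample while window-based estimators cover
    window centres only.
    """

    theta: np.ndarray
    roi_names: tuple[str, ...] = ()
    tr: float = 1.0
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = np.asarray(self.theta, dtype=float)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("theta must have shape (T, p, p)")
        if not np.allclose(arr, np.swapaxes(arr, 1, 2), atol=_SYMMETRY_TOL):
            raise ValueError("each network must be symmetric")
        if np.abs(arr[:, np.arange(arr.shape[1]), np.arange(arr.shape[1])]).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("diagonals must be zero")
        object.__setattr__(self, "theta", arr)
        p = arr.shape[1]
        names = tuple(self.roi_names) or tuple(f"ROI{i + 1}" for i in range(p))
        if len(names) != p:
            raise ValueError("roi_names length mismatch")
        object.__setattr__(self, "roi_names", names)
        times = self.times
        if times is None:
            times = np.arange(arr.shape[0])
        times = np.asarray(times)
        if times.shape != (arr.shape[0],):
            raise ValueError("times must have one entry per network")
        object.__setattr__(self, "times", times)

    @property
    def n_rois(self) -> int:
        return self.theta.shape[1]

    def edge_series(self) -> "DfcEdgeSeries":
        """Stack upper-triangle vectorisations into an ``N x T`` matrix."""
        pairs = upper_triangle_pairs(self.n_rois)
        iu = np.triu_indices(self.n_rois, k=1)
        D = self.theta[:, iu[0], iu[1]].T  # N x T
        return DfcEdgeSeries(D=D, edge_index=pairs)


@dataclass(frozen=True)
class DfcEdgeSeries:
    """Edge-by-time matrix ``D`` (N x T) with N = p(p-1)/2 node pairs."""

    D: np.ndarray
    edge_index: tuple[tuple[int, int], ...]

    def __post_init__(self):
        arr = np.asarray(self.D, dtype=float)
        if arr.ndim != 2:
            raise ValueError("D must be 2-D (edges x time)")
        pairs = tuple((int(i), int(j)) for i, j in self.edge_index)
        if any(i >= j for i, j in pairs):
            raise ValueError("edge pairs must be in i < j order")
        if len(pairs) != arr.shape[0]:
            raise ValueError("edge_index length must match number of rows")
        object.__setattr__(self, "D", arr)
        object.__setattr__(self, "edge_index", pairs)


def upper_triangle_pairs(p: int) -> tuple[tuple[int, int], ...]:
    """Row-major (i < j) upper-triangle pair order, 0-based indices."""
    iu = np.triu_indices(p, k=1)
    return tuple(zip(iu[0].tolist(), iu[1].tolist()))


def minmax_normalize(raw: RoiTimeSeriesMatrix | np.ndarray) -> NormalizedSeries:
    """Rescale every column linearly to [0, 1].

    A zero-variance column cannot be rescaled; it is mapped to the constant
    0.5 (label "Low" under the strict > 0.5 dichotomisation) and a warning is
    emitted, keeping the pipeline total.
    """
    values = raw.values if isinstance(raw, RoiTimeSeriesMatrix) else _as_float_matrix(raw)
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} constant column(s) mapped to 0.5 during normalisation",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (values - lo) / safe
    out[:, degenerate] = 0.5
    return NormalizedSeries(values=out)


def dichotomize(norm: NormalizedSeries | np.ndarray, threshold: float = 0.5) -> ActivityLabels:
    """Map normalised values to +1 ("High") if strictly above the threshold, else -1."""
    values = norm.values if isinstance(norm, NormalizedSeries) else _as_float_matrix(norm)
    labels = np.where(values > threshold, 1, -1)
    return ActivityLabels(values=labels)


def vectorize_upper(theta_t: np.ndarray) -> np.ndarray:
    """Vectorise the strict upper triangle of a symmetric matrix, row-major.

    For ``p`` ROIs the result has length p(p-1)/2, e.g. 6216 entries for the
    112-region atlas parcellation.
    """
    m = np.asarray(theta_t, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(m - m.T).max(initial=0.0) > _SYMMETRY_TOL:
        raise ValueError("matrix is not symmetric within tolerance 1e-8")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def unvectorize_upper(v: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` onto a symmetric zero-diagonal matrix."""
    v = np.asarray(v, dtype=float)
    if v.shape != (p * (p - 1) // 2,):
        raise ValueError("vector length must be p(p-1)/2")
    out = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    out[iu] = v
    out.T[iu] = v
    return out


def read_timeseries(path, tr: float = 1.0, sep: str | None = None) -> RoiTimeSeriesMatrix:
    """Read a delimited text file (first row = ROI names, one row per time point)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return RoiTimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        roi_names=tuple(str(c) for c in df.columns),
        tr=tr,
    )


def write_timeseries(raw: RoiTimeSeriesMatrix, path) -> None:
    pd.DataFrame(raw.values, columns=list(raw.roi_names)).to_csv(path, sep="\t", index=False)


def write_edge_series(dfc: DfcTensor, path) -> None:
    """Write a long-format TSV edge table: time, roi_i, roi_j, weight.

    Times are reported 1-based to match the usual t = 1..T convention.
    """
    pairs = upper_triangle_pairs(dfc.n_rois)
    rows = []
    for k, t in enumerate(np.asarray(dfc.times)):
        for i, j in pairs:
            rows.append((int(t) + 1, dfc.roi_names[i], dfc.roi_names[j], dfc.theta[k, i, j]))
    pd.DataFrame(rows, columns=["time", "roi_i", "roi_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
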