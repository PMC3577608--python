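"""Whole-brain connectivity features: pairwise Pearson correlations.

The feature unit is an *edge*: one region pair's correlation. Edges are
indexed canonically by the row-major upper triangle of the correlation
matrix, i.e. (0,1), (0,2), ..., (0,R-1), (1,2), ... with 0-based region
indices internally (reports use 1-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .timeseries import RegionalTimeSeries

__all__ = [
    "n_edges",
    "pair_to_edge",
    "edge_to_pair",
    "correlation_matrix",
    "vectorize_upper",
    "matrix_from_vector",
    "feature_matrix",
    "fisher_z",
    "ConnectivityMatrix",
    "ConnectivityVector",
]

_ZERO_VARIANCE_TOL = 1e-12


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs: R(R-1)/2 (6670 for R = 116)."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


@lru_cache(maxsize=32)
def _triu_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_regions, k=1)


def pair_to_edge(i: int, j: int, n_regions: int) -> int:
    """Canonical edge position of region pair (i, j), 0-based, i < j."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"invalid region pair ({i}, {j}) for {n_regions} regions")
    # row-major upper triangle offset
    return i * n_regions - i * (i + 1) // 2 + (j - i - 1)


def edge_to_pair(index: int, n_regions: int) -> tuple[int, int]:
    """Region pair (i, j), i < j, at canonical edge position ``index``."""
    e = n_edges(n_regions)
    if not (0 <= index < e):
        raise ValueError(f"edge index {index} out of range for {n_regions} regions")
    rows, cols = _triu_pairs(n_regions)
    return int(rows[index]), int(cols[index])


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal matrix of pairwise Pearson correlations."""

    values: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        self.region_labels = tuple(self.region_labels)
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityVector:
    """Length-E edge vector, E = R(R-1)/2, in canonical edge order."""

    values: np.ndarray
    n_regions: int
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("edge vector must be 1-D")
        if self.values.size != n_edges(self.n_regions):
            raise ValueError(
                f"edge vector length {self.values.size} != "
                f"{n_edges(self.n_regions)} for {self.n_regions} regions"
            )
        self.region_labels = tuple(self.region_labels)

    def __len__(self) -> int:
        return self.values.size

    def pair(self, index: int) -> tuple[int, int]:
        return edge_to_pair(index, self.n_regions)


def correlation_matrix(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson product-moment correlation between every pair of regions.

    Raises
    ------
    ValueError
        If any region has (numerically) zero variance, naming the region,
        or if fewer than 3 volumes are available.
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes for correlation")
    sd = ts.data.std(axis=1)
    scale = max(float(np.abs(ts.data).max()), 1.0)
    dead = np.nonzero(sd <= _ZERO_VARIANCE_TOL * scale)[0]
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, region_labels=ts.region_labels)


def vectorize_upper(cm: ConnectivityMatrix) -> ConnectivityVector:
    """Upper triangle (excluding the diagonal) in row-major edge order."""
    rows, cols = _triu_pairs(cm.n_regions)
    return ConnectivityVector(
        values=cm.values[rows, cols],
        n_regions=cm.n_regions,
        region_labels=cm.region_labels,
    )


def matrix_from_vector(vec: ConnectivityVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_upper` (unit diagonal restored)."""
    r = vec.n_regions
    m = np.eye(r)
    rows, cols = _triu_pairs(r)
    m[rows, cols] = vec.values
    m[cols, rows] = vec.values
    labels = vec.region_labels or tuple(f"R{i + 1:03d}" for i in range(r))
    return ConnectivityMatrix(values=m, region_labels=labels)


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform (optional feature scale, off by default)."""
    return np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))


def feature_matrix(
    subjects: Sequence[RegionalTimeSeries], use_fisher_z: bool = False
) -> np.ndarray:
    """Stack each subject's edge vector into a subjects x E feature matrix."""
    if not subjects:
        raise ValueError("no subjects")
    vecs = [vectorize_upper(correlation_matrix(ts)).values for ts in subjects]
    feats = np.vstack(vecs)
    if use_fisher_z:
        feats = fisher_z(feats)
    return feats
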