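"""In-memory containers for three-way curve data and block partitions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CellCurve:
    """One cell's curve: observation times and (possibly missing) values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


class CurveMatrix:
    """n x d grid of curves observed on per-row time grids.

    Stored as a dense ``(n, d, T)`` value array with NaN marking missing
    observations, plus an ``(n, T)`` array of row time grids (rows may use
    different grids; within a row all variables share the grid, with
    missingness expressing sparser sampling).
    """

    def __init__(self, values, times, row_ids=None, col_ids=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be a 3-d array (n, d, T)")
        n, d, T = values.shape
        times = np.asarray(times, dtype=float)
        if times.ndim == 1:
            if times.shape != (T,):
                raise ValueError("common time grid length must match values")
            times = np.broadcast_to(times, (n, T)).copy()
        if times.shape != (n, T):
            raise ValueError("times must have shape (T,) or (n, T)")
        if np.any(np.diff(times, axis=1) <= 0):
            raise ValueError("each row's time grid must be strictly increasing")
        self.values = values
        self.times = times
        self.row_ids = list(map(str, row_ids)) if row_ids is not None else [
            f"r{i}" for i in range(n)]
        self.col_ids = list(map(str, col_ids)) if col_ids is not None else [
            f"c{j}" for j in range(d)]
        if len(self.row_ids) != n or len(self.col_ids) != d:
            raise ValueError("row_ids / col_ids lengths must match values")

    # -- shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def T(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    @property
    def common_grid(self) -> bool:
        return bool(np.all(self.times == self.times[0]))

    @property
    def time_range(self) -> tuple:
        return float(self.times.min()), float(self.times.max())

    def cell(self, i: int, j: int) -> CellCurve:
        return CellCurve(self.times[i], self.values[i, j])

    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CurveMatrix(n={self.n}, d={self.d}, T={self.T}, "
                f"missing={int(np.isnan(self.values).sum())})")


def as_curve_matrix(X, times=None) -> CurveMatrix:
    """Coerce a CurveMatrix or an (n, d, T) array into a CurveMatrix.

    A bare array gets an equispaced [0, 1] grid unless ``times`` is given.
    """
    if isinstance(X, CurveMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a CurveMatrix or a 3-d (n, d, T) array")
    if times is None:
        times = np.linspace(0.0, 1.0, X.shape[2])
    return CurveMatrix(X, times)


@dataclass
class BlockPartition:
    """Row labels z (length n) and column labels w (length d), 0-based."""

    z: np.ndarray
    w: np.ndarray
    K: int = 0
    L: int = 0

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=int)
        self.w = np.asarray(self.w, dtype=int)
        if self.z.ndim != 1 or self.w.ndim != 1:
            raise ValueError("z and w must be 1-d label vectors")
        if self.K == 0:
            self.K = int(self.z.max()) + 1 if self.z.size else 0
        if self.L == 0:
            self.L = int(self.w.max()) + 1 if self.w.size else 0
        if self.z.size and (self.z.min() < 0 or self.z.max() >= self.K):
            raise ValueError("row labels out of range")
        if self.w.size and (self.w.min() < 0 or self.w.max() >= self.L):
            raise ValueError("column labels out of range")

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def d(self) -> int:
        return self.w.size

    def copy(self) -> "BlockPartition":
        return BlockPartition(self.z.copy(), self.w.copy(), self.K, self.L)

    def __eq__(self, other) -> bool:
        return (isinstance(other, BlockPartition)
                and self.K == other.K and self.L == other.L
                and np.array_equal(self.z, other.z)
                and np.array_equal(self.w, other.w))
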