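"""Data containers for two-sample IV analyses.

The two-sample layout is the standard TWAS/PWAS setting: a small stage-1
sample carrying the exposure (e.g., a gene's expression) together with the IV
genotypes, and a much larger stage-2 sample carrying the outcome (e.g., a
GWAS trait) with the same IVs in the same order and allele orientation.

All estimators in this package operate on column-standardized data (sample
mean 0, sample SD 1 with denominator n-1, no intercepts anywhere).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateInputError

#: relative tolerance used to call a column constant
_SD_TOL = 1e-13


def standardize_columns(M, ddof: int = 1):
    """Standardize each column to mean 0 and SD 1 (denominator ``n - ddof``).

    Accepts a vector or a matrix and returns the same shape.  The
    transformation is affine per column; applying it twice is a no-op up to
    floating point.

    Raises
    ------
    DegenerateInputError
        If any column has (numerically) zero sample SD; the message names the
        offending column index.
    """
    A = np.array(M, dtype=float, copy=True)
    was_vector = A.ndim == 1
    if was_vector:
        A = A[:, None]
    if A.ndim != 2:
        raise ValueError(f"expected a vector or matrix, got ndim={A.ndim}")
    n = A.shape[0]
    if n < ddof + 1:
        raise DegenerateInputError(f"need at least {ddof + 1} rows to standardize, got {n}")
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=ddof)
    scale_floor = _SD_TOL * np.maximum(1.0, np.abs(mean))
    bad = np.where(~np.isfinite(sd) | (sd <= scale_floor))[0]
    if bad.size:
        raise DegenerateInputError(
            f"column {bad[0]} has zero sample SD (constant column); cannot standardize"
        )
    out = (A - mean) / sd
    return out[:, 0] if was_vector else out


def _as_2d(name, M):
    A = np.asarray(M, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={A.ndim}")
    return A


def _as_1d(name, v):
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got ndim={a.ndim}")
    return a


@dataclass(frozen=True)
class TwoSampleData:
    """Individual-level two-sample data.

    Attributes
    ----------
    x1 : (n1,) exposure vector, stage 1.
    Z1 : (n1, p) IV matrix, stage 1.
    y2 : (n2,) outcome vector, stage 2.
    Z2 : (n2, p) IV matrix, stage 2, columns aligned to ``Z1``.
    """

    x1: np.ndarray
    Z1: np.ndarray
    y2: np.ndarray
    Z2: np.ndarray

    def __post_init__(self):
        x1 = _as_1d("x1", self.x1)
        y2 = _as_1d("y2", self.y2)
        Z1 = _as_2d("Z1", self.Z1)
        Z2 = _as_2d("Z2", self.Z2)
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "y2", y2)
        object.__setattr__(self, "Z1", Z1)
        object.__setattr__(self, "Z2", Z2)
        if Z1.shape[1] != Z2.shape[1]:
            raise ValueError(
                f"Z1 and Z2 must carry the same IVs: {Z1.shape[1]} vs {Z2.shape[1]} columns"
            )
        if x1.shape[0] != Z1.shape[0]:
            raise ValueError("x1 and Z1 must have the same number of rows")
        if y2.shape[0] != Z2.shape[0]:
            raise ValueError("y2 and Z2 must have the same number of rows")
        p = Z1.shape[1]
        if x1.shape[0] < p + 2:
            raise DegenerateInputError(f"stage-1 sample size {x1.shape[0]} < p+2 = {p + 2}")
        if y2.shape[0] < p + 2:
            raise DegenerateInputError(f"stage-2 sample size {y2.shape[0]} < p+2 = {p + 2}")

    @property
    def n1(self) -> int:
        return self.x1.shape[0]

    @property
    def n2(self) -> int:
        return self.y2.shape[0]

    @property
    def p(self) -> int:
        return self.Z1.shape[1]

    def standardized(self) -> "TwoSampleData":
        """Return a copy with every column standardized (mean 0, SD 1)."""
        return TwoSampleData(
            x1=standardize_columns(self.x1),
            Z1=standardize_columns(self.Z1),
            y2=standardize_columns(self.y2),
            Z2=standardize_columns(self.Z2),
        )

    def subset_ivs(self, columns) -> "TwoSampleData":
        """Restrict both IV matrices to the given columns (e.g., cis-SNPs only)."""
        cols = np.asarray(list(columns), dtype=int)
        return replace(self, Z1=self.Z1[:, cols], Z2=self.Z2[:, cols])


@dataclass(frozen=True)
class MultiExposureData:
    """Two-sample data with d exposures observed in stage 1.

    ``X`` is n1 x d; the outcome side is as in :class:`TwoSampleData`.
    Requires d < p for identifiability.
    """

    X: np.ndarray
    Z1: np.ndarray
    y2: np.ndarray
    Z2: np.ndarray

    def __post_init__(self):
        X = _as_2d("X", self.X)
        Z1 = _as_2d("Z1", self.Z1)
        y2 = _as_1d("y2", self.y2)
        Z2 = _as_2d("Z2", self.Z2)
        for name, val in (("X", X), ("Z1", Z1), ("y2", y2), ("Z2", Z2)):
            object.__setattr__(self, name, val)
        if Z1.shape[1] != Z2.shape[1]:
            raise ValueError("Z1 and Z2 must carry the same IVs")
        if X.shape[0] != Z1.shape[0]:
            raise ValueError("X and Z1 must have the same number of rows")
        if y2.shape[0] != Z2.shape[0]:
            raise ValueError("y2 and Z2 must have the same number of rows")
        if X.shape[1] >= Z1.shape[1]:
            raise DegenerateInputError(
                f"need d < p exposures, got d={X.shape[1]}, p={Z1.shape[1]}"
            )

    @property
    def n1(self) -> int:
        return self.X.shape[0]

    @property
    def n2(self) -> int:
        return self.y2.shape[0]

    @property
    def p(self) -> int:
        return self.Z1.shape[1]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def standardized(self) -> "MultiExposureData":
        return MultiExposureData(
            X=standardize_columns(self.X),
            Z1=standardize_columns(self.Z1),
            y2=standardize_columns(self.y2),
            Z2=standardize_columns(self.Z2),
        )
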