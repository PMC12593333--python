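"""Guarded linear solves shared across estimators.

Matrix inverses are always taken through a linear solve with a reciprocal
condition number guard (< 1e-12 raises a singular-design error) rather than
an explicit unguarded inverse.
"""
from __future__ import annotations

import numpy as np

from .exceptions import SingularDesignError

#: reciprocal condition number below this is treated as singular
RCOND_MIN = 1e-12


def solve_guarded(A: np.ndarray, B: np.ndarray, what: str) -> np.ndarray:
    """Solve ``A @ X = B`` for symmetric A with a condition-number guard."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{what}: expected a square matrix, got shape {A.shape}")
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1.0 / RCOND_MIN:
        raise SingularDesignError(
            f"{what}: matrix is singular or near-singular "
            f"(reciprocal condition number < {RCOND_MIN:g})"
        )
    return np.linalg.solve(A, B)


def inv_guarded(A: np.ndarray, what: str) -> np.ndarray:
    """Inverse via a guarded solve against the identity."""
    A = np.asarray(A, dtype=float)
    return solve_guarded(A, np.eye(A.shape[0]), what)
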