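"""Invalid-IV (pleiotropy) handling: selection plus the adjusted r2SLS-S fit.

When some IVs have a direct effect on the outcome (nonzero alpha in
y2 = x2 theta + Z2 alpha + xi), both 2SLS and plain r2SLS are biased.  The
two-step remedy implemented here first identifies the invalid set with a
constrained-ML-style search on the 2SLS side (iterated hard-thresholding of
the pleiotropy coefficients for each candidate model size, scored by BIC,
capped below p/2 by the plurality condition), then projects the identified
columns out of the stage-1 side of the r2SLS regression.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._linalg import solve_guarded
from .core import (
    LOW_R2_THRESHOLD,
    FitResult,
    fit_stage2,
    predict_outcome,
    wald_test,
)
from .data import TwoSampleData
from .exceptions import ConvergenceError, DegenerateInputError

MAX_SELECTION_ITER = 200


@dataclass(frozen=True)
class InvalidIvSelection:
    """Result of the invalid-IV search.

    ``selected`` is the chosen index set B-hat (0-based columns of Z);
    ``path`` records (model size, BIC, member tuple) for every candidate
    size, so selection can be audited or written out as a trace.
    """

    selected: tuple
    path: tuple

    @property
    def m(self) -> int:
        return len(self.selected)


def _refit(xx, xy, gx, gy, G, support):
    """Profile OLS of y2 on [x2_hat, Z2[:, support]] via Gram matrices.

    Returns (theta, alpha_support, rss_reduction) where rss_reduction is
    coef' rhs (to be subtracted from y'y).
    """
    s = list(support)
    k = len(s)
    A = np.empty((k + 1, k + 1))
    A[0, 0] = xx
    rhs = np.empty(k + 1)
    rhs[0] = xy
    if k:
        A[0, 1:] = gx[s]
        A[1:, 0] = gx[s]
        A[1:, 1:] = G[np.ix_(s, s)]
        rhs[1:] = gy[s]
    coef = solve_guarded(A, rhs, "profile design [x2_hat, Z2_B]")
    return coef[0], coef[1:], float(coef @ rhs)


def select_invalid_ivs(
    data: TwoSampleData, max_iter: int = MAX_SELECTION_ITER
) -> InvalidIvSelection:
    """Search for the invalid-IV set by profiled hard-thresholding with BIC.

    For each candidate number of invalid IVs m = 0..ceil(p/2)-1 (the cap
    honours the plurality identification condition), (theta, alpha) with
    ||alpha||_0 = m are estimated in y2 = x2_hat theta + Z2 alpha + xi by
    alternating (i) the joint pleiotropy coefficients given theta, (ii) hard
    thresholding to the m largest |alpha|, (iii) a joint refit on the kept
    support.  Each m is scored by the stage-2 BIC
    n2 log(RSS/n2) + m log(n2); the arg-min set is returned.

    Ties in |alpha| break to the lower column index; BIC ties break to the
    smaller model.  If the support iteration enters a cycle, the visited
    support with smallest RSS is taken (deterministic); exceeding
    ``max_iter`` raises :class:`ConvergenceError` carrying the score path.
    """
    d = data.standardized()
    n2, p = d.n2, d.p
    if p < 3:
        raise DegenerateInputError(f"invalid-IV selection needs p >= 3, got p={p}")

    beta1 = solve_guarded(d.Z1.T @ d.Z1, d.Z1.T @ d.x1, "stage-1 IV Gram matrix Z1'Z1")
    x2_hat = d.Z2 @ beta1
    G = d.Z2.T @ d.Z2
    gy = d.Z2.T @ d.y2
    gx = d.Z2.T @ x2_hat
    yy = float(d.y2 @ d.y2)
    xx = float(x2_hat @ x2_hat)
    if xx <= 0.0:
        raise DegenerateInputError("predicted exposure has zero variance")
    xy = float(x2_hat @ d.y2)

    m_max = math.ceil(p / 2) - 1
    path = []
    best = None  # (bic, m, support)
    for m in range(m_max + 1):
        if m == 0:
            theta, _, red = _refit(xx, xy, gx, gy, G, ())
            support = ()
            rss = yy - red
        else:
            theta = xy / xx
            support = None
            visited: dict[tuple, float] = {}
            rss = math.inf
            for _ in range(max_iter):
                alpha_full = solve_guarded(G, gy - gx * theta, "stage-2 IV Gram matrix")
                order = np.argsort(-np.abs(alpha_full), kind="stable")
                new_support = tuple(sorted(int(j) for j in order[:m]))
                if new_support == support:
                    break
                theta, _, red = _refit(xx, xy, gx, gy, G, new_support)
                rss = yy - red
                if new_support in visited:
                    # cycle: take the best support seen so far
                    support = min(visited, key=visited.get)
                    theta, _, red = _refit(xx, xy, gx, gy, G, support)
                    rss = yy - red
                    break
                visited[new_support] = rss
                support = new_support
            else:
                raise ConvergenceError(
                    f"invalid-IV support search did not converge for m={m} "
                    f"after {max_iter} iterations",
                    path=tuple(path),
                )
        if rss <= 0.0:
            rss = np.finfo(float).tiny
        bic = n2 * math.log(rss / n2) + math.log(n2) * m
        path.append((m, bic, support))
        if best is None or bic < best[0] - 1e-12:
            best = (bic, m, support)
    return InvalidIvSelection(selected=best[2], path=tuple(path))


def _project_out(V: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Residual of each column of V after projecting on the columns of B."""
    if B.shape[1] == 0:
        return V
    coef, *_ = np.linalg.lstsq(B, V, rcond=None)
    return V - B @ coef


@dataclass(frozen=True)
class R2slsSResult(FitResult):
    """r2SLS-S fit result; ``kappa`` holds the projection-adjusted kappa'."""

    selection: Optional[InvalidIvSelection] = None

    @property
    def kappa_prime(self) -> float:
        return self.kappa


def r2sls_s_fit(
    data: TwoSampleData,
    selection: Optional[InvalidIvSelection] = None,
    r2_method: str = "adjusted",
    null_value: float = 0.0,
) -> R2slsSResult:
    """Projection-adjusted r2SLS after removing the selected invalid IVs.

    With M the projection complement of Z1[:, B-hat]:

        theta'     = x1' M yhat1 / x1' M x1
        kappa'_raw = eps'eps / ((1 - m/n1) x1' M x1)
        theta~'    = theta' / (1 - kappa')

    where eps'eps is the stage-1 residual SS of x1 on the *full* Z1 (invalid
    IVs may still predict the exposure).  For ``r2_method="adjusted"`` kappa'
    is inflated by (n1-1)/(n1-p-1), mirroring the adjusted-R^2 kappa of the
    valid-IV fit; both reduce exactly to the core estimator at B-hat = {}.
    The variance uses the projected Phi' and the same standardized-data
    plug-in for the second component as the core corrected variance.
    """
    if selection is None:
        selection = select_invalid_ivs(data)
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    n1, n2, p = d.n1, d.n2, d.p
    m = selection.m
    if m >= n1 - 2:
        raise DegenerateInputError(f"selected {m} invalid IVs but n1 = {n1}")

    fit = fit_stage2(d.y2, d.Z2)
    y1_hat = predict_outcome(d.Z1, fit)

    ZB = d.Z1[:, list(selection.selected)]
    Mx = _project_out(d.x1[:, None], ZB)[:, 0]
    MZ = _project_out(d.Z1, ZB)
    xMx = float(Mx @ d.x1)
    if xMx <= 0.0:
        raise DegenerateInputError("exposure fully explained by the selected invalid IVs")
    theta_prime = float(Mx @ y1_hat) / xMx

    # stage-1 residual SS on the full IV set
    beta1 = solve_guarded(d.Z1.T @ d.Z1, d.Z1.T @ d.x1, "stage-1 IV Gram matrix Z1'Z1")
    r1 = d.x1 - d.Z1 @ beta1
    eps_ss = float(r1 @ r1)
    kappa = eps_ss / ((1.0 - m / n1) * xMx)
    if r2_method == "adjusted":
        kappa *= (n1 - 1.0) / (n1 - p - 1.0)
    elif r2_method != "unadjusted":
        raise ValueError(f"r2_method must be 'adjusted' or 'unadjusted', got {r2_method!r}")

    phi = (Mx @ d.Z1) / xMx
    base = fit.sigma_t2 * float(phi @ fit.psi @ phi)

    corrected = (1.0 - kappa) >= LOW_R2_THRESHOLD
    if corrected:
        theta = theta_prime / (1.0 - kappa)
        v2 = (n2 / n1) * theta**2 * kappa * (1.0 - kappa)
        var = (base + v2) / ((1.0 - kappa) ** 2 * n2)
    else:
        theta = theta_prime
        var = base / n2
    se = math.sqrt(var)
    null_std = null_value * sd_x / sd_y
    z, p_value = wald_test(theta, se, null_std)
    return R2slsSResult(
        method="r2sls_s" if corrected else "r2sls_s_uncorrected",
        theta_raw=theta_prime,
        theta=theta,
        kappa=kappa,
        corrected=corrected,
        r2_method=r2_method if corrected else "none",
        se=se,
        z=z,
        p_value=p_value,
        n1=n1,
        n2=n2,
        p_ivs=p,
        sd_x=sd_x,
        sd_y=sd_y,
        selection=selection,
    )


def tscml_fit(
    data: TwoSampleData,
    selection: Optional[InvalidIvSelection] = None,
    null_value: float = 0.0,
) -> FitResult:
    """2SLS-side estimator with the selected invalid IVs as covariates.

    Refits y2 on [x2_hat, Z2[:, B-hat]] by OLS and reports the theta
    coefficient with its OLS standard error.  Comparator method for the
    invalid-IV simulations; stage-1 estimation uncertainty is ignored in
    the SE, as in the selection model itself.
    """
    if selection is None:
        selection = select_invalid_ivs(data)
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    n2 = d.n2
    beta1 = solve_guarded(d.Z1.T @ d.Z1, d.Z1.T @ d.x1, "stage-1 IV Gram matrix Z1'Z1")
    x2_hat = d.Z2 @ beta1
    s = list(selection.selected)
    D = np.column_stack([x2_hat, d.Z2[:, s]]) if s else x2_hat[:, None]
    A = D.T @ D
    coef = solve_guarded(A, D.T @ d.y2, "profile design [x2_hat, Z2_B]")
    resid = d.y2 - D @ coef
    sigma2 = float(resid @ resid) / (n2 - D.shape[1])
    cov00 = solve_guarded(A, np.eye(D.shape[1]), "profile design [x2_hat, Z2_B]")[0, 0]
    theta = float(coef[0])
    se = math.sqrt(sigma2 * cov00)
    null_std = null_value * sd_x / sd_y
    z, p_value = wald_test(theta, se, null_std)
    return FitResult(
        method="tscml",
        theta_raw=theta,
        theta=theta,
        kappa=float("nan"),
        corrected=False,
        r2_method="none",
        se=se,
        z=z,
        p_value=p_value,
        n1=d.n1,
        n2=n2,
        p_ivs=d.p,
        sd_x=sd_x,
        sd_y=sd_y,
    )
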