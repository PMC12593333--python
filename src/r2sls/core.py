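"""Reverse two-stage least squares (r2SLS) for a single exposure.

The two-sample structural model is

    stage 1:  x1 = Z1 beta + eps          (exposure on IVs, small sample)
    stage 2:  y2 = x2 theta + xi          (outcome on unobserved exposure)

with (eps, xi) mean-zero normal errors that may be correlated within a
sample (confounding).  Substituting stage 1 into stage 2 gives
y2 = Z2 (beta theta) + eps theta + xi, so the product coefficient
``beta*theta`` is estimable by OLS of y2 on Z2 in the *large* stage-2
sample.  r2SLS predicts the outcome in stage 1, yhat1 = Z1 @ coef, and
regresses it on the observed exposure:

    theta_hat = x1' yhat1 / x1' x1 .

theta_hat is unbiased under theta = 0 but attenuated by the bias factor
kappa = eps'eps / x1'x1 = 1 - R^2 of the stage-1 regression otherwise; the
de-attenuated estimator is theta_tilde = theta_hat / (1 - kappa), with
kappa estimated through the adjusted or Olkin-Pratt R^2.

All estimator arithmetic assumes column-standardized inputs; the top-level
:func:`r2sls_fit` standardizes internally and records the input-scale SDs so
results can be mapped back (z and p are scale-invariant).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from ._linalg import inv_guarded, solve_guarded
from .data import TwoSampleData, standardize_columns
from .exceptions import CorrectionNotApplicable, DegenerateInputError

#: stage-1 R^2 below this disables the attenuation correction
LOW_R2_THRESHOLD = 0.01

R2_METHODS = ("adjusted", "olkin_pratt", "unadjusted")


@dataclass(frozen=True)
class Stage2Fit:
    """OLS fit of the outcome on the IVs in the stage-2 sample.

    ``coef`` estimates the product beta*theta; ``sigma_t2`` the total
    residual variance of eps*theta + xi; ``psi`` is (Z2'Z2/n2)^{-1}.
    """

    coef: np.ndarray
    sigma_t2: float
    psi: np.ndarray
    n2: int

    @property
    def p(self) -> int:
        return self.coef.shape[0]


@dataclass(frozen=True)
class FitResult:
    """Point estimate and Wald inference for the exposure effect theta.

    Estimates are on the standardized scale of the data handed to the
    estimator; ``sd_x``/``sd_y`` record the input-sample SDs so
    :meth:`on_input_scale` can restore the original units.
    """

    method: str
    theta_raw: float
    theta: float
    kappa: float
    corrected: bool
    r2_method: str
    se: float
    z: float
    p_value: float
    n1: int
    n2: int
    p_ivs: int
    sd_x: float = 1.0
    sd_y: float = 1.0

    @property
    def scale(self) -> float:
        """Slope back-transformation factor sd(y)/sd(x) to the input scale."""
        return self.sd_y / self.sd_x

    def on_input_scale(self) -> "FitResult":
        """Return a copy with estimate and SE on the original input scale."""
        s = self.scale
        return replace(
            self,
            theta_raw=self.theta_raw * s,
            theta=self.theta * s,
            se=self.se * s,
            sd_x=1.0,
            sd_y=1.0,
        )

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "theta_raw": self.theta_raw,
            "kappa": self.kappa,
            "r2_method": self.r2_method,
            "theta": self.theta,
            "se": self.se,
            "z": self.z,
            "p": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "p_ivs": self.p_ivs,
            "corrected": self.corrected,
        }


def fit_stage2(y2: np.ndarray, Z2: np.ndarray) -> Stage2Fit:
    """Regress the outcome on the IVs by OLS in the stage-2 sample.

    Returns the coefficient vector (estimating beta*theta), the residual
    mean square with denominator n2 - p, and Psi = (Z2'Z2/n2)^{-1}.
    """
    y2 = np.asarray(y2, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    n2, p = Z2.shape
    G = Z2.T @ Z2
    coef = solve_guarded(G, Z2.T @ y2, "stage-2 IV Gram matrix Z2'Z2")
    resid = y2 - Z2 @ coef
    sigma_t2 = float(resid @ resid) / (n2 - p)
    psi = inv_guarded(G / n2, "stage-2 IV correlation matrix Z2'Z2/n2")
    return Stage2Fit(coef=coef, sigma_t2=sigma_t2, psi=psi, n2=n2)


def predict_outcome(Z1: np.ndarray, fit: Stage2Fit) -> np.ndarray:
    """Predict the (unobserved) stage-1 outcome as yhat1 = Z1 @ coef."""
    Z1 = np.asarray(Z1, dtype=float)
    if Z1.shape[1] != fit.p:
        raise ValueError(
            f"Z1 has {Z1.shape[1]} columns but the stage-2 fit used {fit.p} IVs"
        )
    return Z1 @ fit.coef


def raw_theta(x1: np.ndarray, y1_hat: np.ndarray) -> float:
    """No-intercept OLS slope of the predicted outcome on the exposure."""
    x1 = np.asarray(x1, dtype=float)
    y1_hat = np.asarray(y1_hat, dtype=float)
    denom = float(x1 @ x1)
    if denom <= 0.0:
        raise DegenerateInputError("exposure vector has zero sum of squares")
    return float(x1 @ y1_hat) / denom


def _stage1_r2(x1: np.ndarray, Z1: np.ndarray) -> tuple[float, float]:
    """Sample R^2 and residual SS of the no-intercept OLS of x1 on Z1."""
    beta = solve_guarded(Z1.T @ Z1, Z1.T @ x1, "stage-1 IV Gram matrix Z1'Z1")
    resid = x1 - Z1 @ beta
    rss = float(resid @ resid)
    tss = float(x1 @ x1)
    if tss <= 0.0:
        raise DegenerateInputError("exposure vector has zero sum of squares")
    return 1.0 - rss / tss, rss


def olkin_pratt_r2(r2: float, n: int, p: int, tol: float = 1e-12, max_terms: int = 10000) -> float:
    """Olkin-Pratt (approximately unbiased) estimator of the population R^2.

    Evaluated through its hypergeometric form

        R2_OP = 1 - (n-3)/(n-p-1) * (1-R2) * 2F1(1, 1; (n-p+1)/2; 1-R2),

    with the 2F1 series truncated once a term drops below ``tol`` relative
    to the partial sum.  Can be negative for small sample R^2.
    """
    if n <= p + 2:
        raise DegenerateInputError(f"Olkin-Pratt estimator needs n > p+2, got n={n}, p={p}")
    z = 1.0 - r2
    c = (n - p + 1) / 2.0
    # 2F1(1,1;c;z) = sum_k k! z^k / (c)_k ; term ratio (k+1) z / (c+k)
    term = 1.0
    total = 1.0
    for k in range(max_terms):
        term *= (k + 1.0) * z / (c + k)
        total += term
        if term < tol * total:
            break
    return 1.0 - (n - 3.0) / (n - p - 1.0) * z * total


def estimate_kappa(x1: np.ndarray, Z1: np.ndarray, method: str = "adjusted") -> float:
    """Bias factor kappa = 1 - R2_hat of the stage-1 exposure-on-IV regression.

    ``method`` selects the R^2 estimator: ``"unadjusted"`` (sample R^2),
    ``"adjusted"`` (1 - (1-R2)(n-1)/(n-p-1)), or ``"olkin_pratt"``.  The
    returned kappa may exceed 1 when the chosen estimator is negative;
    callers must handle that (low-R^2 fallback).
    """
    if method not in R2_METHODS:
        raise ValueError(f"unknown r2 method {method!r}; choose from {R2_METHODS}")
    x1 = np.asarray(x1, dtype=float)
    Z1 = np.asarray(Z1, dtype=float)
    n1, p = Z1.shape
    if n1 <= p + 2:
        raise DegenerateInputError(f"kappa estimation needs n1 > p+2, got n1={n1}, p={p}")
    r2, _ = _stage1_r2(x1, Z1)
    if method == "unadjusted":
        r2_hat = r2
    elif method == "adjusted":
        r2_hat = 1.0 - (1.0 - r2) * (n1 - 1.0) / (n1 - p - 1.0)
    else:
        r2_hat = olkin_pratt_r2(r2, n1, p)
    return 1.0 - r2_hat


def corrected_theta(theta_raw: float, kappa: float, tol: float = LOW_R2_THRESHOLD) -> float:
    """De-attenuated estimator theta_tilde = theta_hat / (1 - kappa).

    Raises :class:`CorrectionNotApplicable` when the estimated stage-1 R^2
    (= 1 - kappa) falls below ``tol``; the caller should then report the
    uncorrected null test instead.
    """
    if kappa >= 1.0 - tol:
        raise CorrectionNotApplicable(
            f"stage-1 R2 estimate {1.0 - kappa:.4g} < {tol:g}; "
            "attenuation correction not applicable"
        )
    return theta_raw / (1.0 - kappa)


def _phi_psi_phi(x1: np.ndarray, Z1: np.ndarray, fit: Stage2Fit) -> float:
    denom = float(x1 @ x1)
    if denom <= 0.0:
        raise DegenerateInputError("exposure vector has zero sum of squares")
    phi = (x1 @ Z1) / denom
    return float(phi @ fit.psi @ phi)


def null_variance(x1: np.ndarray, Z1: np.ndarray, fit: Stage2Fit) -> float:
    """Variance of theta_hat under theta = 0.

    sqrt(n2) theta_hat is asymptotically N(0, sigma_t^2 Phi Psi Phi') with
    Phi = x1'Z1 / x1'x1; this returns the finite-sample plug-in divided
    by n2.
    """
    x1 = np.asarray(x1, dtype=float)
    Z1 = np.asarray(Z1, dtype=float)
    return fit.sigma_t2 * _phi_psi_phi(x1, Z1, fit) / fit.n2


def corrected_variance(
    theta_tilde: float,
    kappa: float,
    x1: np.ndarray,
    Z1: np.ndarray,
    fit: Stage2Fit,
    n1: int,
    n2: int,
) -> float:
    """Variance of the de-attenuated estimator theta_tilde.

    The numerator combines the null component sigma_t^2 Phi Psi Phi' with a
    second component due to estimating a nonzero theta; for standardized
    data the latter is plugged in as (n2/n1) * theta_tilde^2 * kappa *
    (1-kappa).  The whole is divided by (1-kappa)^2 * n2.
    """
    if kappa >= 1.0 - LOW_R2_THRESHOLD:
        raise CorrectionNotApplicable(
            f"stage-1 R2 estimate {1.0 - kappa:.4g} too small for corrected variance"
        )
    x1 = np.asarray(x1, dtype=float)
    Z1 = np.asarray(Z1, dtype=float)
    base = fit.sigma_t2 * _phi_psi_phi(x1, Z1, fit)
    v2 = (n2 / n1) * theta_tilde**2 * kappa * (1.0 - kappa)
    return (base + v2) / ((1.0 - kappa) ** 2 * n2)


def wald_test(estimate: float, se: float, null_value: float = 0.0) -> tuple[float, float]:
    """Two-sided Wald z and p-value against N(0, 1)."""
    if se <= 0.0 or not math.isfinite(se):
        raise DegenerateInputError(f"non-positive or non-finite standard error {se!r}")
    z = (estimate - null_value) / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def r2sls_fit(
    data: TwoSampleData,
    r2_method: str = "adjusted",
    null_value: float = 0.0,
    force_uncorrected: bool = False,
) -> FitResult:
    """End-to-end r2SLS fit: standardize, predict the outcome, de-attenuate, test.

    Pipeline: column standardization -> stage-2 OLS -> outcome prediction ->
    raw slope -> kappa -> correction.  When the estimated stage-1 R^2 is
    below 0.01 (or ``force_uncorrected``), the raw estimate is reported with
    the null variance and ``corrected=False``; this mirrors the recommended
    fallback for weakly heritable exposures.

    ``null_value`` is interpreted on the scale of the input data.
    """
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    fit = fit_stage2(d.y2, d.Z2)
    y1_hat = predict_outcome(d.Z1, fit)
    theta_hat = raw_theta(d.x1, y1_hat)
    kappa = estimate_kappa(d.x1, d.Z1, method=r2_method)

    r2_hat = 1.0 - kappa
    corrected = (not force_uncorrected) and r2_hat >= LOW_R2_THRESHOLD
    if corrected:
        theta = corrected_theta(theta_hat, kappa)
        var = corrected_variance(theta, kappa, d.x1, d.Z1, fit, d.n1, d.n2)
        label = r2_method
    else:
        theta = theta_hat
        var = null_variance(d.x1, d.Z1, fit)
        label = "none"
    se = math.sqrt(var)
    null_std = null_value * sd_x / sd_y  # input-scale null mapped to standardized scale
    z, p_value = wald_test(theta, se, null_std)
    return FitResult(
        method="r2sls" if corrected else "r2sls_uncorrected",
        theta_raw=theta_hat,
        theta=theta,
        kappa=kappa,
        corrected=corrected,
        r2_method=label,
        se=se,
        z=z,
        p_value=p_value,
        n1=d.n1,
        n2=d.n2,
        p_ivs=d.p,
        sd_x=sd_x,
        sd_y=sd_y,
    )
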