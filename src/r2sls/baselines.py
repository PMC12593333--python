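"""Comparator estimators: two-sample 2SLS, the naive/WLS variants, observed OLS.

These reproduce the comparison methods used alongside r2SLS in simulation
studies.  The naive and WLS variants share the r2SLS point estimate but use
(incorrect) textbook standard errors; they are retained as documented
failure modes, not as recommended procedures.  The observed-data regressions
require the exposure and outcome jointly observed in one sample, which only
the simulator can provide.
"""
from __future__ import annotations

import math

import numpy as np

from ._linalg import solve_guarded
from .core import FitResult, fit_stage2, predict_outcome, raw_theta, wald_test
from .data import TwoSampleData
from .exceptions import DegenerateInputError

#: ridge added to squared residuals when estimating WLS weights
WLS_WEIGHT_RIDGE = 1e-6


def tsls_fit(
    data: TwoSampleData,
    cis_columns=None,
    null_value: float = 0.0,
) -> FitResult:
    """Two-sample two-stage least squares.

    Stage 1 estimates beta by OLS of x1 on Z1 (optionally restricted to
    ``cis_columns``, the typical TWAS practice of using only cis-SNPs);
    stage 2 regresses y2 on the imputed exposure Z2 @ beta_hat.  The SE is
    the asymptotic plug-in

        var(theta*) = (sigma_t^2 + (n2/n1) theta*^2 sigma_eps^2) / (xhat2'xhat2),

    with stage-wise residual mean squares for the two error variances.
    """
    if cis_columns is not None:
        data = data.subset_ivs(cis_columns)
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    n1, n2, p = d.n1, d.n2, d.p

    beta = solve_guarded(d.Z1.T @ d.Z1, d.Z1.T @ d.x1, "stage-1 IV Gram matrix Z1'Z1")
    resid1 = d.x1 - d.Z1 @ beta
    sigma_eps2 = float(resid1 @ resid1) / (n1 - p)

    x2_hat = d.Z2 @ beta
    denom = float(x2_hat @ x2_hat)
    if denom <= n2 * 1e-16:
        raise DegenerateInputError("predicted exposure has zero variance (beta_hat = 0)")
    theta_star = float(x2_hat @ d.y2) / denom
    resid2 = d.y2 - x2_hat * theta_star
    sigma_t2 = float(resid2 @ resid2) / (n2 - 1)

    var = (sigma_t2 + (n2 / n1) * theta_star**2 * sigma_eps2) / denom
    se = math.sqrt(var)
    null_std = null_value * sd_x / sd_y
    z, p_value = wald_test(theta_star, se, null_std)
    return FitResult(
        method="tsls",
        theta_raw=theta_star,
        theta=theta_star,
        kappa=float("nan"),
        corrected=False,
        r2_method="none",
        se=se,
        z=z,
        p_value=p_value,
        n1=n1,
        n2=n2,
        p_ivs=p,
        sd_x=sd_x,
        sd_y=sd_y,
    )


def r2sls_naive_fit(data: TwoSampleData, null_value: float = 0.0) -> FitResult:
    """r2SLS point estimate with the (invalid) textbook OLS slope SE.

    The residuals of the predicted outcome on the exposure are
    heteroskedastic by construction, so this SE understates the sampling
    variability and the test has grossly inflated type-I error.
    """
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    fit = fit_stage2(d.y2, d.Z2)
    y1_hat = predict_outcome(d.Z1, fit)
    theta_hat = raw_theta(d.x1, y1_hat)
    resid = y1_hat - d.x1 * theta_hat
    var_resid = float(np.var(resid, ddof=1))
    var_x = float(np.var(d.x1, ddof=1))
    se = math.sqrt(var_resid / (d.n1 * var_x)) if var_resid > 0 else 0.0
    if se <= 0.0:
        raise DegenerateInputError("zero residual variance: naive SE undefined")
    null_std = null_value * sd_x / sd_y
    z, p_value = wald_test(theta_hat, se, null_std)
    return FitResult(
        method="r2sls_naive",
        theta_raw=theta_hat,
        theta=theta_hat,
        kappa=float("nan"),
        corrected=False,
        r2_method="none",
        se=se,
        z=z,
        p_value=p_value,
        n1=d.n1,
        n2=d.n2,
        p_ivs=d.p,
        sd_x=sd_x,
        sd_y=sd_y,
    )


def wls_fit(data: TwoSampleData, null_value: float = 0.0) -> FitResult:
    """Two-pass weighted least squares of the predicted outcome on the exposure.

    Weights are 1 / (e_i^2 + 1e-6) from first-pass OLS residuals.  With a
    small stage-1 sample the weights are poorly estimated and the WLS SE is
    strongly anti-conservative; kept as a documented failure mode.
    """
    sd_x = float(np.std(data.x1, ddof=1))
    sd_y = float(np.std(data.y2, ddof=1))
    d = data.standardized()
    fit = fit_stage2(d.y2, d.Z2)
    y1_hat = predict_outcome(d.Z1, fit)
    theta_ols = raw_theta(d.x1, y1_hat)
    resid = y1_hat - d.x1 * theta_ols
    w = 1.0 / (resid**2 + WLS_WEIGHT_RIDGE)
    sw = float(np.sum(w * d.x1**2))
    if sw <= 0.0:
        raise DegenerateInputError("degenerate WLS weights")
    theta_w = float(np.sum(w * d.x1 * y1_hat)) / sw
    se = math.sqrt(1.0 / sw)
    null_std = null_value * sd_x / sd_y
    z, p_value = wald_test(theta_w, se, null_std)
    return FitResult(
        method="wls",
        theta_raw=theta_ols,
        theta=theta_w,
        kappa=float("nan"),
        corrected=False,
        r2_method="none",
        se=se,
        z=z,
        p_value=p_value,
        n1=d.n1,
        n2=d.n2,
        p_ivs=d.p,
        sd_x=sd_x,
        sd_y=sd_y,
    )


def observed_fit(x: np.ndarray, y: np.ndarray, null_value: float = 0.0, method: str = "observed") -> FitResult:
    """Confounded simple linear regression of y on x within one sample.

    Used only by the simulation engine (real two-sample data never observes
    the exposure and outcome jointly); the slope converges to
    theta + cov(eps, xi)/var(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.shape[0]
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateInputError("zero-variance regressor in observed-data regression")
    slope = float(xc @ yc) / sxx
    resid = yc - xc * slope
    se = math.sqrt(float(resid @ resid) / (n - 2) / sxx)
    z, p_value = wald_test(slope, se, null_value)
    return FitResult(
        method=method,
        theta_raw=slope,
        theta=slope,
        kappa=float("nan"),
        corrected=False,
        r2_method="none",
        se=se,
        z=z,
        p_value=p_value,
        n1=n,
        n2=n,
        p_ivs=0,
        sd_x=1.0,
        sd_y=1.0,
    )
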