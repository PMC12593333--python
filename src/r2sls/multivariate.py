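"""r2SLS with several exposures fitted jointly.

Model: each exposure x_j = Z1 beta_j + eps_j in stage 1 and
y2 = sum_j x2j theta_j + xi in stage 2, all errors jointly normal.  The
outcome is predicted from the IVs in stage 2 as in the univariate case;
regressing it on the exposure matrix X gives theta_hat = (X'X)^{-1} X' yhat1,
which is de-attenuated by the correction matrix

    Lambda = [I_d - (X'X)^{-1} V'V]^{-1},

the matrix analogue of 1/(1 - kappa), where V is the stage-1 residual
matrix.  The d = 1 case reduces exactly to the univariate estimator with
the unadjusted-R^2 kappa.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._linalg import inv_guarded, solve_guarded
from .data import MultiExposureData
from .core import fit_stage2, predict_outcome
from .exceptions import SingularDesignError


@dataclass(frozen=True)
class MultiFitResult:
    """Joint estimate for d exposures with per-coordinate Wald tests.

    Estimates are on the standardized scale; ``sd_x`` (length d) and
    ``sd_y`` allow mapping back to input units.
    """

    theta: np.ndarray
    theta_raw: np.ndarray
    lam: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    n1: int
    n2: int
    p_ivs: int
    d: int
    sd_x: np.ndarray
    sd_y: float

    def on_input_scale(self) -> "MultiFitResult":
        s = self.sd_y / self.sd_x
        from dataclasses import replace

        return replace(
            self,
            theta=self.theta * s,
            theta_raw=self.theta_raw * s,
            cov=self.cov * np.outer(s, s),
            se=self.se * s,
            sd_x=np.ones_like(self.sd_x),
            sd_y=1.0,
        )


def multi_r2sls_fit(
    data: MultiExposureData, null_value=0.0, r2_method: str = "adjusted"
) -> MultiFitResult:
    """Joint r2SLS fit for d exposures with the plug-in asymptotic covariance.

    With ``r2_method="adjusted"`` (default) the residual matrix V'V inside
    the correction is inflated by (n1-1)/(n1-p-1), the matrix analogue of
    the adjusted-R^2 kappa (the raw V'V underestimates the stage-1 noise
    for the same reason the unadjusted R^2 is biased upward);
    ``"unadjusted"`` uses V'V as is.  The d = 1 case reduces exactly to the
    univariate fit with the matching kappa estimator.

    The covariance combines a stage-2 prediction term
    sigma_t^2 Lambda W Psi W' Lambda' / n2 (W = (X'X)^{-1} X'Z1) and a
    stage-1 term sigma_tX^2 Lambda SX^{-1} B'SZ B SX^{-1} Lambda' / n1 with
    sample covariances throughout; both reduce to the univariate variance
    components asymptotically.
    """
    if r2_method not in ("adjusted", "unadjusted"):
        raise ValueError("r2_method must be 'adjusted' or 'unadjusted'")
    sd_x = np.std(data.X, axis=0, ddof=1).astype(float)
    sd_y = float(np.std(data.y2, ddof=1))
    d0 = data.standardized()
    X, Z1, y2, Z2 = d0.X, d0.Z1, d0.y2, d0.Z2
    n1, n2, p, d = d0.n1, d0.n2, d0.p, d0.d

    stage2 = fit_stage2(y2, Z2)
    y1_hat = predict_outcome(Z1, stage2)

    XtX = X.T @ X
    theta_raw = solve_guarded(XtX, X.T @ y1_hat, "exposure Gram matrix X'X")

    B_hat = solve_guarded(Z1.T @ Z1, Z1.T @ X, "stage-1 IV Gram matrix Z1'Z1")
    V = X - Z1 @ B_hat
    VtV = V.T @ V
    if r2_method == "adjusted":
        VtV = VtV * (n1 - 1.0) / (n1 - p - 1.0)
    core_mat = np.eye(d) - solve_guarded(XtX, VtV, "exposure Gram matrix X'X")
    try:
        lam = inv_guarded(core_mat, "correction matrix I - (X'X)^{-1} V'V")
    except SingularDesignError as exc:
        raise SingularDesignError(
            "attenuation correction matrix is singular; exposures may be "
            "indistinguishable from their stage-1 residuals"
        ) from exc
    theta = lam @ theta_raw

    # plug-in covariance
    W = solve_guarded(XtX, X.T @ Z1, "exposure Gram matrix X'X")  # d x p
    term1 = stage2.sigma_t2 * lam @ W @ stage2.psi @ W.T @ lam.T / n2

    SX = XtX / (n1 - 1)
    SZ = Z1.T @ Z1 / n1
    Sig_eps = V.T @ V / (n1 - p)
    sigma_tX2 = float(theta @ Sig_eps @ theta)
    SX_inv = inv_guarded(SX, "exposure covariance")
    mid = B_hat.T @ SZ @ B_hat
    term2 = sigma_tX2 * lam @ SX_inv @ mid @ SX_inv @ lam.T / n1

    cov = term1 + term2
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    null_vec = np.broadcast_to(np.asarray(null_value, dtype=float), (d,))
    null_std = null_vec * sd_x / sd_y
    z = (theta - null_std) / se
    p_value = 2.0 * stats.norm.sf(np.abs(z))
    return MultiFitResult(
        theta=theta,
        theta_raw=theta_raw,
        lam=lam,
        cov=cov,
        se=se,
        z=z,
        p_value=p_value,
        n1=n1,
        n2=n2,
        p_ivs=p,
        d=d,
        sd_x=sd_x,
        sd_y=sd_y,
    )
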