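"""r2SLS from GWAS summary statistics plus a reference LD panel.

Individual-level data are replaced by per-SNP marginal effect estimates.
A marginal effect and its variance convert to the SNP-trait correlation

    r = gamma / sqrt(gamma^2 + (N - 2) var(gamma)),

the classic t-statistic-to-correlation identity.  Joint stage-2
coefficients on the standardized scale are recovered from the outcome
marginal correlations through the inverse LD (SNP correlation) matrix,
after which the estimator, the adjusted-R^2 kappa, and the variance mirror
the individual-level pipeline with summary plug-ins (Phi <- r_x,
sigma_t^2 <- 1 - joint outcome R^2).  The Olkin-Pratt kappa is not
available here: it needs the individual-level R^2 sampling model, so the
adjusted R^2 is used.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._linalg import solve_guarded
from .core import LOW_R2_THRESHOLD, FitResult, wald_test
from .data import standardize_columns
from .exceptions import DegenerateInputError, HarmonizationError, SingularDesignError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


@dataclass(frozen=True)
class SummaryDataset:
    """Per-SNP marginal GWAS summary statistics for one trait.

    ``beta`` are marginal effects on the standardized scale, ``var`` their
    sampling variances (SE^2), ``n`` per-SNP sample sizes.  Allele columns
    are optional but required for harmonization.
    """

    ids: np.ndarray
    beta: np.ndarray
    var: np.ndarray
    n: np.ndarray
    effect_allele: Optional[np.ndarray] = None
    other_allele: Optional[np.ndarray] = None

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=object)
        beta = np.asarray(self.beta, dtype=float)
        var = np.asarray(self.var, dtype=float)
        n = np.asarray(self.n, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "var", var)
        object.__setattr__(self, "n", n)
        if not (ids.shape == beta.shape == var.shape == n.shape):
            raise ValueError("ids, beta, var, n must have equal length")
        if len(set(ids.tolist())) != ids.size:
            dupes = sorted({i for i in ids.tolist() if list(ids).count(i) > 1})
            raise DegenerateInputError(f"duplicate SNP ids: {dupes[:5]}")
        if np.any(var <= 0):
            raise DegenerateInputError("all summary variances must be positive")
        if np.any(n <= 2):
            raise DegenerateInputError("all per-SNP sample sizes must exceed 2")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=object)
                if a.shape != ids.shape:
                    raise ValueError(f"{name} must match ids in length")
                object.__setattr__(self, name, a)

    @property
    def size(self) -> int:
        return self.ids.size

    def subset(self, idx) -> "SummaryDataset":
        idx = np.asarray(idx)
        return SummaryDataset(
            ids=self.ids[idx],
            beta=self.beta[idx],
            var=self.var[idx],
            n=self.n[idx],
            effect_allele=None if self.effect_allele is None else self.effect_allele[idx],
            other_allele=None if self.other_allele is None else self.other_allele[idx],
        )


def beta_to_correlation(effect, variance, N):
    """Marginal SNP-trait correlation from a GWAS effect, variance, and N.

    r = gamma / sqrt(gamma^2 + (N-2) var(gamma)); lies in (-1, 1), keeps the
    sign of the effect, and is invariant to jointly rescaling (gamma, SE).
    """
    effect = np.asarray(effect, dtype=float)
    variance = np.asarray(variance, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(variance <= 0):
        raise DegenerateInputError("variance must be positive")
    if np.any(N <= 2):
        raise DegenerateInputError("sample size must exceed 2")
    r = effect / np.sqrt(effect**2 + (N - 2.0) * variance)
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class LDPanel:
    """Reference panel: standardized genotypes and/or a SNP correlation matrix."""

    ids: np.ndarray
    genotypes: Optional[np.ndarray] = None
    corr: Optional[np.ndarray] = None
    effect_allele: Optional[np.ndarray] = None

    def __post_init__(self):
        ids = np.asarray(self.ids, dtype=object)
        object.__setattr__(self, "ids", ids)
        if self.genotypes is None and self.corr is None:
            raise ValueError("LDPanel needs genotypes or a precomputed correlation matrix")
        if self.genotypes is not None:
            g = np.asarray(self.genotypes, dtype=float)
            if g.shape[1] != ids.size:
                raise ValueError("genotype columns must match ids")
            object.__setattr__(self, "genotypes", g)
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (ids.size, ids.size):
                raise ValueError("correlation matrix must be p x p")
            object.__setattr__(self, "corr", c)
        if self.effect_allele is not None:
            a = np.asarray(self.effect_allele, dtype=object)
            if a.shape != ids.shape:
                raise ValueError("effect_allele must match ids in length")
            object.__setattr__(self, "effect_allele", a)

    @property
    def p(self) -> int:
        return self.ids.size

    def aligned(self, ids, flip_signs=None) -> "LDPanel":
        """Reorder to ``ids`` and optionally flip the coded allele of some SNPs."""
        pos = {s: i for i, s in enumerate(self.ids.tolist())}
        try:
            idx = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise HarmonizationError(f"panel is missing SNP {exc.args[0]!r}") from exc
        g = None if self.genotypes is None else self.genotypes[:, idx].copy()
        c = None if self.corr is None else self.corr[np.ix_(idx, idx)].copy()
        ea = None if self.effect_allele is None else self.effect_allele[idx].copy()
        if flip_signs is not None:
            s = np.where(np.asarray(flip_signs, dtype=bool), -1.0, 1.0)
            if g is not None:
                g = g * s
            if c is not None:
                c = c * np.outer(s, s)
            if ea is not None:
                ea = np.array(
                    [_COMPLEMENT.get(a, a) if f else a for a, f in zip(ea, flip_signs)],
                    dtype=object,
                )
        return LDPanel(ids=np.asarray(ids, dtype=object), genotypes=g, corr=c, effect_allele=ea)


def ld_matrix(panel: LDPanel, shrinkage: float = 0.0):
    """SNP correlation matrix R (optionally shrunk toward I) and its inverse Psi.

    ``shrinkage`` lambda in [0, 1] replaces R by (1-lambda) R + lambda I;
    use a small positive value (0.001-0.1) for near-singular panels.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    if panel.corr is not None:
        R = np.array(panel.corr, dtype=float, copy=True)
    else:
        G = standardize_columns(panel.genotypes)
        nref = G.shape[0]
        if nref <= panel.p and shrinkage == 0.0:
            raise SingularDesignError(
                f"reference panel has {nref} samples for {panel.p} SNPs; "
                "pass --ld-shrinkage > 0"
            )
        R = G.T @ G / (nref - 1)
    R = (1.0 - shrinkage) * R + shrinkage * np.eye(panel.p)
    np.fill_diagonal(R, 1.0)
    try:
        psi = solve_guarded(R, np.eye(panel.p), "LD correlation matrix")
    except SingularDesignError as exc:
        raise SingularDesignError(
            "LD correlation matrix is singular; consider --ld-shrinkage 0.001-0.1"
        ) from exc
    return R, psi


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    keep_palindromic: bool = False,
):
    """Align two summary datasets on shared SNPs with consistent alleles.

    Returns (exposure_subset, outcome_subset_with_flipped_signs,
    flip_relative_to_exposure, n_dropped).  Outcome effects are sign-flipped
    where its coded allele is the exposure's other allele (directly or via
    strand complement); strand-ambiguous (A/T, C/G) SNPs are dropped unless
    ``keep_palindromic``; unresolvable allele pairs are dropped with a
    logged count.  Raises if no SNP survives.
    """
    out_pos = {s: i for i, s in enumerate(outcome.ids.tolist())}
    keep_e, keep_o, signs = [], [], []
    dropped = 0
    have_alleles = (
        exposure.effect_allele is not None
        and exposure.other_allele is not None
        and outcome.effect_allele is not None
        and outcome.other_allele is not None
    )
    for i, snp in enumerate(exposure.ids.tolist()):
        j = out_pos.get(snp)
        if j is None:
            continue
        if not have_alleles:
            keep_e.append(i)
            keep_o.append(j)
            signs.append(1.0)
            continue
        ea_x = str(exposure.effect_allele[i]).upper()
        oa_x = str(exposure.other_allele[i]).upper()
        ea_y = str(outcome.effect_allele[j]).upper()
        oa_y = str(outcome.other_allele[j]).upper()
        if _is_palindromic(ea_x, oa_x) and not keep_palindromic:
            dropped += 1
            continue
        flip = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            flip = 1.0
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = -1.0
        else:
            cea = _COMPLEMENT.get(ea_y)
            coa = _COMPLEMENT.get(oa_y)
            if cea is not None and coa is not None:
                if (cea, coa) == (ea_x, oa_x):
                    flip = 1.0
                elif (cea, coa) == (oa_x, ea_x):
                    flip = -1.0
        if flip is None:
            dropped += 1
            continue
        keep_e.append(i)
        keep_o.append(j)
        signs.append(flip)
    if not keep_e:
        raise HarmonizationError(
            f"no SNP shared with consistent alleles ({dropped} dropped)"
        )
    if dropped:
        logger.info("harmonization dropped %d SNPs", dropped)
    exp_sub = exposure.subset(np.array(keep_e, dtype=int))
    out_sub = outcome.subset(np.array(keep_o, dtype=int))
    signs = np.asarray(signs)
    out_sub = SummaryDataset(
        ids=out_sub.ids,
        beta=out_sub.beta * signs,
        var=out_sub.var,
        n=out_sub.n,
        effect_allele=exp_sub.effect_allele,
        other_allele=exp_sub.other_allele,
    )
    return exp_sub, out_sub, dropped


def r2sls_from_summary(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    panel: LDPanel,
    n1: int,
    n2: int,
    shrinkage: float = 0.0,
    keep_palindromic: bool = False,
    null_value: float = 0.0,
    force_uncorrected: bool = False,
) -> FitResult:
    """r2SLS from exposure and outcome GWAS summaries plus a reference panel.

    Pipeline: harmonize -> marginal correlations r_x, r_y -> joint stage-2
    coefficients Psi r_y -> theta_hat = r_x' Psi r_y -> adjusted-R^2 kappa
    from r_x' Psi r_x with ``n1`` -> correction, variance and Wald test as
    in the individual-level fit with Phi <- r_x and
    sigma_t^2 <- 1 - r_y' Psi r_y.
    """
    exp_h, out_h, _ = harmonize(exposure, outcome, keep_palindromic=keep_palindromic)
    p = exp_h.size
    if n1 <= p + 2:
        raise DegenerateInputError(f"summary mode needs n1 > p+2 (n1={n1}, p={p})")

    # align panel to the harmonized exposure ids and coded alleles
    flips = None
    if panel.effect_allele is not None and exp_h.effect_allele is not None:
        pos = {s: i for i, s in enumerate(panel.ids.tolist())}
        flips = []
        for snp, ea in zip(exp_h.ids.tolist(), exp_h.effect_allele.tolist()):
            i = pos.get(snp)
            if i is None:
                raise HarmonizationError(f"panel is missing SNP {snp!r}")
            pa = str(panel.effect_allele[i]).upper()
            ea = str(ea).upper()
            flips.append(pa != ea and _COMPLEMENT.get(pa) != ea)
    panel_a = panel.aligned(exp_h.ids.tolist(), flip_signs=flips)
    _, psi = ld_matrix(panel_a, shrinkage=shrinkage)

    r_x = beta_to_correlation(exp_h.beta, exp_h.var, exp_h.n)
    r_y = beta_to_correlation(out_h.beta, out_h.var, out_h.n)

    b_joint = psi @ r_y
    theta_hat = float(r_x @ b_joint)
    quad_x = float(r_x @ psi @ r_x)
    quad_y = float(r_y @ b_joint)
    sigma_t2 = 1.0 - quad_y
    if sigma_t2 <= 0.0:
        raise DegenerateInputError(
            "outcome summaries imply a joint R^2 >= 1; check LD panel alignment"
        )
    r2_adj = 1.0 - (1.0 - quad_x) * (n1 - 1.0) / (n1 - p - 1.0)
    kappa = 1.0 - r2_adj

    base = sigma_t2 * quad_x
    corrected = (not force_uncorrected) and r2_adj >= LOW_R2_THRESHOLD
    if corrected:
        theta = theta_hat / (1.0 - kappa)
        v2 = (n2 / n1) * theta**2 * kappa * (1.0 - kappa)
        var = (base + v2) / ((1.0 - kappa) ** 2 * n2)
    else:
        theta = theta_hat
        var = base / n2
    if var <= 0.0:
        raise DegenerateInputError("non-positive variance from summary plug-ins")
    se = math.sqrt(var)
    z, p_value = wald_test(theta, se, null_value)
    return FitResult(
        method="r2sls_summary" if corrected else "r2sls_summary_uncorrected",
        theta_raw=theta_hat,
        theta=theta,
        kappa=kappa,
        corrected=corrected,
        r2_method="adjusted" if corrected else "none",
        se=se,
        z=z,
        p_value=p_value,
        n1=int(n1),
        n2=int(n2),
        p_ivs=p,
        sd_x=1.0,
        sd_y=1.0,
    )


def summaries_from_individual(x: np.ndarray, Z: np.ndarray, ids=None) -> SummaryDataset:
    """Marginal GWAS-style summaries from individual-level data.

    Runs a simple linear regression (with intercept) of the trait on each
    SNP separately and records slope, SE^2 with n-2 denominator, and n.
    On standardized data the summaries reproduce the Pearson correlation
    exactly through :func:`beta_to_correlation`.
    """
    x = np.asarray(x, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if ids is None:
        ids = np.array([f"snp{j}" for j in range(p)], dtype=object)
    xc = x - x.mean()
    Zc = Z - Z.mean(axis=0)
    sxx = np.sum(Zc**2, axis=0)
    if np.any(sxx <= 0):
        raise DegenerateInputError("constant SNP column in individual-level data")
    beta = Zc.T @ xc / sxx
    rss = np.sum(xc**2) - beta**2 * sxx
    var = rss / (n - 2) / sxx
    return SummaryDataset(ids=np.asarray(ids, dtype=object), beta=beta, var=var, n=np.full(p, n))
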