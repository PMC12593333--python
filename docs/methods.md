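# Methods

This note documents the statistical model, the estimator variants, the
synthetic-data generators, and the numerical choices made where the design
was genuinely open. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and core estimator

Two independent samples share the same p IVs (SNPs): the exposure sample
`(x1, Z1)` of size n1 and the outcome sample `(y2, Z2)` of size n2, with
n2 ≫ n1 and p fixed. The structural model is

    x1 = Z1 β + ε,        y2 = x2 θ + ξ,

with (ε, ξ) mean-zero, independent of Z, jointly normal, and correlated
within a sample (shared environment/confounding). All variables are
standardized columnwise to mean 0, SD 1 (denominator n−1, stated once and
applied uniformly); no model carries an intercept.

Because `y2 = Z2(βθ) + εθ + ξ`, the product coefficient is estimable by
OLS in the large sample. The pipeline is

1. stage-2 OLS of y2 on Z2 → `coef`, residual mean square
   `σ̂t² = RSS/(n2−p)` (no estimator for σt² is canonical; the residual
   mean square is unbiased under the rewritten stage-2 model), and
   `Ψ = (Z2'Z2/n2)⁻¹`;
2. outcome prediction `ŷ1 = Z1·coef`;
3. raw slope `θ̂ = x1'ŷ1/x1'x1`;
4. bias factor `κ̂ = 1 − R̂²` from the stage-1 regression of x1 on Z1;
5. corrected estimate `θ̃ = θ̂/(1−κ̂)` and Wald test.

Under the null, `√n2·θ̂ ~ N(0, σt² Φ Ψ Φ')` with `Φ = x1'Z1/x1'x1`; we use
this finite-sample Φ (not its population limit) in all reported variances.
For θ ≠ 0 the corrected variance is

    var(θ̃) = [σt² Φ Ψ Φ' + V2] / ((1−κ)² n2),
    V2 = (n2/n1) · θ̃² · κ (1−κ).

V2 plugs in the theoretical component `n2 θ² σε² ‖Z1β‖² / (x1'x1)²`: for
standardized data σε² ≈ κ, ‖Z1β‖²/x1'x1 ≈ 1−κ and x1'x1 ≈ n1. The
θ̃² (squared) form is required for dimensional consistency of the variance;
a first-power variant would not scale correctly under θ → cθ. With the
squared form the predicted SE in the strong-IV design at θ=0.2 (≈0.028)
matches the Monte-Carlo SD computed by the simulation engine.

### Estimating R²

Three estimators of the stage-1 R² are offered: `unadjusted` (sample R²,
biased upward, not recommended), `adjusted`
(`1 − (1−R²)(n1−1)/(n1−p−1)`, the default), and `olkin_pratt`, the
approximately unbiased estimator evaluated through its hypergeometric form

    R²_OP = 1 − (n−3)/(n−p−1) · (1−R²) · ₂F₁(1, 1; (n−p+1)/2; 1−R²),

with the ₂F₁ series truncated when a term falls below 1e−12 of the partial
sum (max 10 000 terms); the series is cross-checked in the tests against
`scipy.special.hyp2f1`. Both adjusted and Olkin–Pratt estimates can be
zero or negative for weakly heritable exposures; whenever `R̂² < 0.01`
(threshold fixed at 0.01) the de-attenuation is switched off and the raw
estimate is reported with the null variance (`corrected = false`). This
fallback keeps the *test* valid even when unbiased *estimation* is
impossible.

### Scales

Estimator theory lives on the standardized scale, and fit functions
standardize internally; `FitResult` records the input-sample SDs so
`on_input_scale()` can restore original units via the usual slope
back-transformation `× sd(y)/sd(x)`. z-statistics and p-values are
identical on both scales. Tested null values are interpreted on the input
scale. Two-sided normal p-values are used throughout (the asymptotics are
normal; no small-sample t correction).

### Numerical choices

- Every matrix inverse is a guarded linear solve: condition number above
  1e12 raises a singular-design error (e.g., collinear IV panels).
- Degenerate inputs (constant columns, zero-variance exposure, zero
  predicted-exposure variance in 2SLS) raise typed errors naming the
  offending stage/column.
- `fit_stage2`'s Ψ is formed by solving against the identity once; all
  quadratic forms reuse it.

## Baselines

- **2SLS**: stage-1 OLS β̂ (optionally restricted to a cis-SNP subset, the
  standard TWAS practice), imputed exposure `x̂2 = Z2β̂`, slope
  `θ̂* = x̂2'y2/x̂2'x̂2`. The SE is the asymptotic plug-in
  `(σ̂t² + (n2/n1) θ̂*² σ̂ε²)/x̂2'x̂2` with stage-wise residual mean
  squares (the two error variances have no canonical plug-in; stage-wise
  residual MS is consistent under the model). A conventional 2SLS-software
  SE would omit the second term; the difference vanishes under the null.
- **naive**: same point estimate as the raw r2SLS slope but the textbook
  OLS slope SE. The prediction residuals are heteroskedastic by
  construction (each observation's variance depends on its own Z1 row), so
  this SE is invalid; kept as a documented failure mode.
- **WLS**: two-pass weighted fit with weights `1/(e_i² + 1e−6)`. With n1 in
  the hundreds the weights are far too noisy and the test is strongly
  anti-conservative; also a documented failure mode.
- **observed-1/2**: confounded within-sample OLS of y on x. These need the
  exposure and outcome jointly observed, which only the simulator provides;
  the CLI does not expose them.

## Invalid IVs (r2SLS-S)

Pleiotropy turns stage 2 into `y2 = x2θ + Z2α + ξ`; the support of α is
the invalid set. Selection runs on the 2SLS side (conditional on Z1 the
predicted outcome is independent of the exposure, so selection under the
reverse framework itself is an open problem): for each candidate size
m = 0..⌈p/2⌉−1 — the cap honours the plurality identification condition —
(θ, α) with ‖α‖₀ = m are estimated in `y2 = x̂2θ + Z2α + ξ` by iterated
hard thresholding (joint α given θ; keep the m largest |α|; refit jointly
on the kept support), and each m is scored by the stage-2 BIC
`n2·log(RSS/n2) + m·log(n2)`. Ties in |α| break to the lower column index;
BIC ties to the smaller model. A support cycle is resolved
deterministically by taking the visited support with the smallest RSS;
exceeding 200 iterations raises an error carrying the score path. For
p ≤ 6 the selector agrees with an exhaustive subset search under the same
BIC (tested).

Given the selected set B̂ (|B̂| = m), with `M = I − P(Z1,B̂)`:

    θ̂' = x1'M ŷ1 / x1'M x1,
    κ̂' = ε'ε / ((1 − m/n1) · x1'M x1),
    θ̃' = θ̂' / (1 − κ̂'),

where ε'ε is the stage-1 residual SS of x1 on the **full** Z1 — invalid IVs
may still predict the exposure, so they stay in the stage-1 model. Under
the default `r2_method="adjusted"`, κ̂' is additionally inflated by
(n1−1)/(n1−p−1), the same correction the adjusted-R² κ applies in the
valid-IV fit; both choices reduce exactly to the core estimator when
B̂ = ∅. The variance uses the projected `Φ' = x1'M Z1 / x1'M x1` and the
same standardized-data plug-in for the second component as the core fit;
the population normalizer τ of the asymptotic theory is absorbed into that
plug-in and is therefore approximate (exact analogue of the valid-IV
shortcut).

`tscml_fit` reports the comparator 2SLS-side estimate: the θ coefficient of
the joint OLS of y2 on [x̂2, Z2_B̂] with its OLS SE (stage-1 uncertainty
ignored, as in the selection model itself).

## Multivariate exposures

For d exposures X (d < p): `θ̂ = (X'X)⁻¹X'ŷ1` and `θ̃ = Λ̂ θ̂` with

    Λ̂ = [I_d − (X'X)⁻¹ V̂'V̂ · c]⁻¹,

V̂ the stage-1 residual matrix and c = (n1−1)/(n1−p−1) by default
(`r2_method="adjusted"`); c = 1 gives the raw matrix analogue of the
unadjusted 1/(1−κ). The raw form underestimates the stage-1 noise exactly
as the unadjusted R² does, which at n1 = 500, p = 30 leaves a visible
residual attenuation; the adjusted default removes it (the d = 2 coverage
test holds 95% intervals at nominal level). The d = 1 fit reduces exactly
to the univariate estimator with the matching κ.

The plug-in covariance combines a stage-2 term
`σ̂t² Λ W Ψ W' Λ'/n2` (W = (X'X)⁻¹X'Z1) and a stage-1 term
`σ̂tX² Λ Σ̂X⁻¹ B̂'Σ̂Z B̂ Σ̂X⁻¹ Λ'/n1` with sample covariances throughout
(`σ̂tX² = θ̃'Σ̂ε θ̃`, Σ̂ε = V̂'V̂/(n1−p)). The two terms match the
univariate variance components asymptotically (the leading sample-size
factor attaches 1/n2 to the prediction term and 1/n1 to the stage-1 term,
consistent with the univariate formula).

## GWAS summary-statistics mode

Marginal effect γ̂, variance var(γ̂) and sample size N convert to the
SNP-trait correlation `r = γ̂/√(γ̂² + (N−2)·var(γ̂))` (the exact
t-to-correlation identity; on standardized individual-level data the
round-trip is exact to machine precision, tested). With Ψ the inverse of
the LD (SNP correlation) matrix from a reference panel:

- joint stage-2 coefficients from outcome marginals: `b = Ψ r_y` (the
  standard marginal-to-joint conversion on the standardized scale; the
  estimator is then `θ̂ = r_x' b`);
- stage-1 R² from `r_x'Ψ r_x`, adjusted with n1 — the Olkin–Pratt
  estimator needs the individual-level sampling model and is not
  applicable to summaries;
- `σ̂t² = 1 − r_y'Ψ r_y` (re-estimated from the outcome summaries rather
  than fixed at 1; the alternative matters only when the IVs explain a
  non-negligible share of the outcome);
- variance and test as in the core fit with Φ ← r_x.

Harmonization aligns datasets on shared SNP ids, flips outcome signs when
its coded allele is the exposure's other allele (directly or via strand
complement), drops strand-ambiguous A/T and C/G SNPs by default
(`keep_palindromic` overrides), and drops unresolvable pairs with a logged
count; the reference panel is re-signed to the exposure's coded alleles
when it carries allele labels, else assumed aligned. LD shrinkage
`(1−λ)R + λI` (default λ = 0; 0.001–0.1 recommended for near-singular
panels) guards against rank-deficient panels.

## Synthetic-data generators

`gen_two_sample` draws, per repetition: per-SNP effects
`β_j ~ scale·N(mean, sd²)` (redrawn each repetition — the convention fixed
here; fixing β once would shrink the between-repetition spread of the
biased estimators), Gaussian IVs (iid, or AR(1) rows with
corr ρ^|j−k|), error pairs (ε, ξ) with unit variances and within-sample
covariance 0.25, then

    x = Zβ + ε,    y = xθ + Zα + ξ,

with α nonzero on the leading `invalid_count` IVs (Unif(0.1, 0.2)), whose
β entries are zeroed or left random by `invalid_beta_mode`. Hidden truths
(β, α, x2, y1) are returned for oracle checks. Non-normal outcome errors
(centered unit-variance exponential or scaled t₅) replace ξ's margin
through a Gaussian copula whose latent correlation is calibrated by
Gauss–Hermite quadrature so the realized Pearson covariance equals the
configured value exactly in population (verified empirically in the tests).

`target_r2` rescales β so the population stage-1 R² (=
β'Σ_Zβ/(β'Σ_Zβ+1)) is exact per draw. The stock scenarios fix it at
0.235 for the independent-IV (`table1_*`) and invalid-IV
(`table3_*`/`table4_*`) designs; the correlated-IV `table2_*` scenarios
leave the raw effect scale (implied R² ≈ 0.5). The two conventions are
deliberate: the published operating characteristics these scenarios
reproduce are mutually consistent only under this assignment — the
independent-IV 2SLS attenuation means pin R² = 0.235, while the
correlated-IV means pin the unrescaled effect scale. Estimates in the
metrics tables are reported on the generator's natural (input) scale, so
Monte-Carlo means are directly comparable with the nominal θ.

What the generators deliberately do **not** emulate: discrete genotypes
(allele counts under Hardy–Weinberg), minor-allele-frequency spectra,
LD blocks beyond AR(1), population structure, selection of IVs from GWAS
p-values, or winner's-curse effects. Passing simulations therefore
demonstrate the estimator's statistical properties under the stated
Gaussian designs, not robustness to real-genotype artifacts.

The Monte-Carlo driver spawns one RNG substream per repetition from a
single `SeedSequence`, so all methods see identical data within a
repetition and every table is bit-reproducible from its seed.
Per-repetition fit failures are counted per method and excluded from the
aggregates, never silently. Reported per method: Mean, SD of the
estimates, mean reported SE, MSE (satisfying the exact identity
MSE = bias² + (k−1)/k·SD²), and the rejection rate at the configured
α-level (type-I error when θ equals the tested null, power otherwise).

## Problem sizes

The published designs run at n1 = 500, n2 = 10 000, p ∈ {30, 120}, 500
repetitions; the acceptance script and the acceptance tests use exactly
these sizes. Unit and property tests use smaller designs
(n ≈ 200–4000, p ≈ 5–10, tens to hundreds of repetitions) chosen so each
check retains clear statistical resolution; asymptotic-equivalence checks
use n1 = n2 = 50 000 with few repetitions.

## Known limitations

- The variance plug-ins V2 and its projected analogue are standardized-data
  approximations of the exact theoretical components; they are accurate in
  the regimes tested (stage-1 R² roughly 0.2–0.6) and degrade as R̂² → 0,
  where the uncorrected fallback takes over anyway.
- The correction factor 1/(1−κ̂) is a nonlinear function of R̂², so θ̃
  carries a small upward finite-sample bias (visible as Monte-Carlo means
  of ≈ 0.102/0.204 for true 0.1/0.2); an unbiased correction is an open
  problem.
- Invalid-IV selection assumes the plurality condition and a
  well-conditioned stage-2 IV covariance; it is univariate-exposure only.
- Summary mode trusts the marginal effects to be on the standardized scale;
  mixed per-SNP sample sizes are accepted but the joint conversion assumes
  a common underlying cohort per trait.
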