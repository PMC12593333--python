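# r2sls — reverse two-stage least squares for two-sample IV inference

`r2sls` implements the **reverse two-stage least squares** estimator for
two-sample instrumental-variable analyses of the kind used in
transcriptome-/proteome-wide association studies (TWAS/PWAS) and two-sample
Mendelian randomization. It is aimed at statistical geneticists and
biostatisticians who have a *small* exposure sample (e.g., a few hundred
individuals with gene-expression measurements) and a *large* outcome sample
(a GWAS cohort), and who want an exposure-outcome effect estimate that does
not suffer the weak-instrument attenuation bias of conventional 2SLS.

## The model and the estimator

With standardized data, IVs (SNPs) `Z`, exposure `x`, outcome `y`:

```
stage 1:  x1 = Z1 β + ε          (n1 individuals, exposure sample)
stage 2:  y2 = x2 θ + ξ          (n2 individuals, outcome sample; x2 unobserved)
```

The errors (ε, ξ) are mean-zero normal and may be correlated within a sample
(confounding). Conventional 2SLS predicts the exposure from the small
stage-1 sample, so when n1 is small or the IVs weak, the estimate of θ is
attenuated toward zero. r2SLS goes the other way: substituting stage 1 into
stage 2 gives `y2 = Z2 (βθ) + εθ + ξ`, so the product coefficient `βθ` is
estimated by OLS in the **large** stage-2 sample, the outcome is predicted
in stage 1 as `ŷ1 = Z1 · coef`, and

```
θ̂ = x1'ŷ1 / x1'x1 ,        θ̃ = θ̂ / (1 − κ) ,       κ = 1 − R²(stage 1)
```

θ̂ is unbiased under the null and attenuated by the bias factor κ otherwise;
dividing by `1 − κ` (estimated via the adjusted or Olkin–Pratt R²)
de-attenuates it. Wald inference uses the asymptotic variance
`[σt² Φ Ψ Φ' + (n2/n1) θ̃² κ (1−κ)] / ((1−κ)² n2)` with
`Φ = x1'Z1/x1'x1`, `Ψ = (Z2'Z2/n2)⁻¹`, and σt² the stage-2 residual
variance. When the stage-1 R² estimate falls below 0.01 the correction is
switched off and the uncorrected null test is reported instead.

Also included:

- **Baselines**: two-sample 2SLS (with the weak-IV attenuation it is prone
  to), the naive-SE and WLS variants (documented failure modes), and
  observed-data regressions for simulations.
- **Invalid-IV handling (r2SLS-S)**: a constrained-ML-style search (iterated
  hard thresholding + BIC, capped below p/2 by the plurality condition)
  identifies pleiotropic IVs with direct outcome effects; the fit then
  projects them out of the stage-1 regression.
- **Multivariate exposures**: joint estimation for d exposures with the
  matrix correction `Λ = [I − (X'X)⁻¹V'V]⁻¹`.
- **GWAS summary-statistics mode**: marginal effects + a reference LD panel
  instead of individual-level data, with allele harmonization.
- **Simulation engine**: the generators and Monte-Carlo driver behind all
  operating-characteristic tables (type-I error, power, bias, MSE).

## Worked example

Simulate one TWAS-like dataset (n1=500, n2=10000, 30 IVs, stage-1 R²=0.235,
true θ=0.1) and fit both estimators:

```python
import numpy as np
from r2sls import r2sls_fit, tsls_fit, gen_two_sample, scenario_config

cfg = scenario_config("table1_p30", theta=0.1, reps=1)
data, truth = gen_two_sample(cfg, np.random.default_rng(7))
for fit in (r2sls_fit(data), tsls_fit(data)):
    f = fit.on_input_scale()
    print(f"{f.method}: theta={f.theta:.4f} raw={f.theta_raw:.4f} "
          f"kappa={f.kappa:.4f} se={f.se:.4f} z={f.z:.2f} p={f.p_value:.3g}")
```

which prints

```
r2sls: theta=0.1222 raw=0.0272 kappa=0.7777 se=0.0233 z=5.25 p=1.53e-07
tsls:  theta=0.0894 raw=0.0894 kappa=nan se=0.0182 z=4.92 p=8.47e-07
```

Read: the raw slope of the predicted outcome on the exposure is 0.027 —
heavily attenuated because the stage-1 R² is only `1 − κ ≈ 0.22`; dividing
by `1 − κ` recovers θ̃ = 0.122, close to the true 0.1 given SE 0.023. 2SLS
on the same data returns 0.089, attenuated toward zero (on average ≈ 0.083
in this design), though still significant here.

The same design as a 50-repetition Monte-Carlo table, from the shell:

```bash
r2sls simulate --scenario table1_p30 --theta 0.1 --reps 50 --seed 7 \
    --methods r2sls,tsls --out demo.tsv
```

```
method  mean    sd      se      mse       rejection  n_used  n_failed
r2sls   0.1049  0.0230  0.0231  5.42e-04  1.0        50      0
tsls    0.0855  0.0179  0.0183  5.24e-04  1.0        50      0
```

The r2SLS mean sits on the true θ=0.1 while 2SLS centres near 0.085: the
attenuation is systematic, not sampling noise. `r2sls fit` and
`r2sls fit-summary` run the same estimators on your own TSV files
(individual-level matrices, or GWAS summary statistics plus an LD panel);
see `r2sls --help`.

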