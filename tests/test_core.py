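import math

import numpy as np
import pytest
from scipy import special, stats

from r2sls.core import (
    corrected_theta,
    corrected_variance,
    estimate_kappa,
    fit_stage2,
    null_variance,
    olkin_pratt_r2,
    predict_outcome,
    r2sls_fit,
    raw_theta,
)
from r2sls.data import TwoSampleData, standardize_columns
from r2sls.exceptions import (
    CorrectionNotApplicable,
    DegenerateInputError,
    SingularDesignError,
)
from r2sls.simulate import ScenarioConfig, gen_two_sample

from conftest import make_dataset


class TestFitStage2:
    def test_perfect_fit_zero_residual_variance(self, rng):
        Z = rng.normal(size=(40, 3))
        y = Z @ np.array([0.5, -1.0, 2.0])
        fit = fit_stage2(y, Z)
        assert fit.sigma_t2 <= 1e-20

    def test_orthogonal_design_coefficients(self, rng):
        # Z'Z = n I  ->  coef_j = Z_j'y / n
        n = 64
        Q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        Z = Q * math.sqrt(n)
        y = rng.normal(size=n)
        fit = fit_stage2(y, Z)
        np.testing.assert_allclose(fit.coef, Z.T @ y / n, atol=1e-10)

    def test_simulated_coefficients_within_ols_bands(self, rng):
        n2, p = 10000, 6
        Z = rng.normal(size=(n2, p))
        bt = rng.normal(0.1, 0.05, size=p)
        y = Z @ bt + rng.normal(size=n2)
        fit = fit_stage2(y, Z)
        # oracle: OLS covariance sigma^2 (Z'Z)^-1
        cov = fit.sigma_t2 * np.linalg.inv(Z.T @ Z)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(fit.coef - bt) < 3.0 * se)

    def test_singular_design_raises(self, rng):
        Z = rng.normal(size=(50, 3))
        Z[:, 2] = Z[:, 0]  # exact collinearity
        with pytest.raises(SingularDesignError):
            fit_stage2(rng.normal(size=50), Z)


class TestPredictAndRawTheta:
    def test_zero_coef_and_one_hot_rows(self, rng):
        Z2 = rng.normal(size=(30, 3))
        fit = fit_stage2(rng.normal(size=30), Z2)
        zero_fit = fit_stage2(np.zeros(30), Z2)
        assert np.allclose(predict_outcome(np.eye(3), zero_fit), 0.0)
        np.testing.assert_allclose(predict_outcome(np.eye(3), fit), fit.coef, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        Z1 = rng.normal(size=(15, 4))
        fit = fit_stage2(rng.normal(size=40), rng.normal(size=(40, 4)))
        got = predict_outcome(Z1, fit)
        want = np.array(
            [sum(Z1[i, j] * fit.coef[j] for j in range(4)) for i in range(15)]
        )
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_column_mismatch(self, rng):
        fit = fit_stage2(rng.normal(size=40), rng.normal(size=(40, 4)))
        with pytest.raises(ValueError, match="columns"):
            predict_outcome(rng.normal(size=(10, 3)), fit)

    def test_raw_theta_proportionality_and_orthogonality(self, rng):
        x = rng.normal(size=50)
        assert raw_theta(x, 2.0 * x) == pytest.approx(2.0, abs=1e-12)
        y = rng.normal(size=50)
        y -= x * (x @ y) / (x @ x)
        assert raw_theta(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_raw_theta_matches_lstsq_oracle(self, rng):
        x = standardize_columns(rng.normal(size=80))
        y = standardize_columns(rng.normal(size=80))
        slope = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
        assert raw_theta(x, y) == pytest.approx(slope, abs=1e-12)

    def test_estimator_identity_decomposition(self):
        # theta_hat == x1'Z1 (Z2'Z2)^-1 Z2'y2 / x1'x1 on any dataset
        data, _ = make_dataset(seed=5)
        d = data.standardized()
        fit = fit_stage2(d.y2, d.Z2)
        theta = raw_theta(d.x1, predict_outcome(d.Z1, fit))
        direct = (
            d.x1 @ d.Z1 @ np.linalg.solve(d.Z2.T @ d.Z2, d.Z2.T @ d.y2) / (d.x1 @ d.x1)
        )
        assert theta == pytest.approx(direct, abs=1e-10)


class TestKappa:
    def test_perfect_stage1_fit_gives_zero_kappa(self, rng):
        Z = standardize_columns(rng.normal(size=(60, 3)))
        x = Z @ np.array([1.0, -0.5, 0.25])
        for method in ("unadjusted", "adjusted", "olkin_pratt"):
            assert estimate_kappa(x, Z, method) == pytest.approx(0.0, abs=1e-8)

    def test_unadjusted_definition_on_constructed_r2(self, rng):
        # build x with sample R^2 exactly 0.5 -> kappa = 0.5
        Z = standardize_columns(rng.normal(size=(200, 5)))
        x0 = rng.normal(size=200)
        beta = np.linalg.lstsq(Z, x0, rcond=None)[0]
        fitted, resid = Z @ beta, x0 - Z @ beta
        x = fitted / np.linalg.norm(fitted) + resid / np.linalg.norm(resid)
        assert estimate_kappa(x, Z, "unadjusted") == pytest.approx(0.5, abs=1e-10)

    def test_adjusted_matches_direct_arithmetic_and_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n1, p = 500, 30
        Z = standardize_columns(rng.normal(size=(n1, p)))
        x0 = rng.normal(size=n1)
        x0 -= x0.mean()
        beta = np.linalg.lstsq(Z, x0, rcond=None)[0]
        fitted, resid = Z @ beta, x0 - Z @ beta
        # sample R^2 exactly 0.25 by construction
        x = fitted / np.linalg.norm(fitted) * 0.5 + resid / np.linalg.norm(resid) * math.sqrt(0.75)
        kappa = estimate_kappa(x, Z, "adjusted")
        assert kappa == pytest.approx(0.75 * 499 / 469, abs=1e-10)
        # cross-check against the reference adjusted-R^2 implementation
        sm_fit = sm.OLS(x, sm.add_constant(Z)).fit()
        assert kappa == pytest.approx(1 - sm_fit.rsquared_adj, abs=1e-8)

    def test_olkin_pratt_series_matches_hyp2f1(self):
        for n, p, r2 in [(500, 30, 0.25), (100, 5, 0.05), (50, 10, 0.6)]:
            want = 1 - (n - 3) / (n - p - 1) * (1 - r2) * special.hyp2f1(
                1, 1, (n - p + 1) / 2, 1 - r2
            )
            assert olkin_pratt_r2(r2, n, p) == pytest.approx(want, rel=1e-10)

    def test_olkin_pratt_nearly_unbiased(self):
        # mean of the estimator over repeated samples approximates the
        # population R^2, unlike the raw sample R^2
        rng = np.random.default_rng(42)
        n, p = 200, 8
        beta = np.full(p, 0.2)
        pop_r2 = (beta @ beta) / (beta @ beta + 1.0)
        ops, raws = [], []
        for _ in range(300):
            Z = rng.normal(size=(n, p))
            x = Z @ beta + rng.normal(size=n)
            Zs, xs = standardize_columns(Z), standardize_columns(x)
            raw = 1.0 - estimate_kappa(xs, Zs, "unadjusted")
            raws.append(raw)
            ops.append(olkin_pratt_r2(raw, n, p))
        assert abs(np.mean(ops) - pop_r2) < 0.01
        assert np.mean(raws) - pop_r2 > 0.02  # raw R^2 visibly biased up


class TestCorrection:
    def test_corrected_theta_definition(self):
        assert corrected_theta(0.1, 0.0) == pytest.approx(0.1)
        assert corrected_theta(0.1, 0.5) == pytest.approx(0.2)

    def test_low_r2_signal(self):
        with pytest.raises(CorrectionNotApplicable):
            corrected_theta(0.1, 0.995)

    def test_mean_recovery_and_attenuation(self):
        # over repetitions the corrected estimate centres on theta while the
        # raw estimate is attenuated by roughly (1 - mean kappa)
        cfg = ScenarioConfig(n1=500, n2=4000, p_cis=10, theta=0.2, target_r2=0.3, reps=1)
        ss = np.random.SeedSequence(123).spawn(200)
        tildes, raws, kappas = [], [], []
        for child in ss:
            data, _ = gen_two_sample(cfg, np.random.default_rng(child))
            fr = r2sls_fit(data).on_input_scale()
            tildes.append(fr.theta)
            raws.append(fr.theta_raw)
            kappas.append(fr.kappa)
        mc_se = np.std(tildes, ddof=1) / math.sqrt(len(tildes))
        assert abs(np.mean(tildes) - 0.2) < 3 * mc_se
        assert np.mean(raws) == pytest.approx(0.2 * (1 - np.mean(kappas)), abs=0.01)


class TestVariances:
    def test_identity_psi_unit_phi(self, rng):
        n2 = 49
        Q, _ = np.linalg.qr(rng.normal(size=(n2, 3)))
        Z2 = Q * math.sqrt(n2)  # Z2'Z2/n2 = I
        y2 = rng.normal(size=n2)
        fit = fit_stage2(y2, Z2)
        Z1 = rng.normal(size=(20, 3))
        x1 = Z1[:, 0]
        v = null_variance(x1, Z1, fit)
        phi = x1 @ Z1 / (x1 @ x1)
        assert v == pytest.approx(fit.sigma_t2 * (phi @ phi) / n2, rel=1e-10)
        # linearity in sigma_t2
        fit2 = fit_stage2(y2 * math.sqrt(2), Z2)
        assert null_variance(x1, Z1, fit2) == pytest.approx(
            v * fit2.sigma_t2 / fit.sigma_t2, rel=1e-10
        )

    def test_null_variance_matches_monte_carlo(self):
        # empirical variance of theta_hat under theta=0 vs the formula
        cfg = ScenarioConfig(n1=400, n2=4000, p_cis=10, theta=0.0, target_r2=0.3, reps=1)
        ss = np.random.SeedSequence(3).spawn(1200)
        thetas, formulas = [], []
        for child in ss:
            data, _ = gen_two_sample(cfg, np.random.default_rng(child))
            d = data.standardized()
            fit = fit_stage2(d.y2, d.Z2)
            thetas.append(raw_theta(d.x1, predict_outcome(d.Z1, fit)))
            formulas.append(null_variance(d.x1, d.Z1, fit))
        assert np.var(thetas, ddof=1) == pytest.approx(np.mean(formulas), rel=0.10)

    def test_corrected_variance_limits_and_monotonicity(self, small_data):
        d = small_data.standardized()
        fit = fit_stage2(d.y2, d.Z2)
        nv = null_variance(d.x1, d.Z1, fit)
        # theta_tilde = 0: reduces to null variance / (1-kappa)^2
        assert corrected_variance(0.0, 0.4, d.x1, d.Z1, fit, d.n1, d.n2) == pytest.approx(
            nv / 0.6**2, rel=1e-10
        )
        # kappa -> 0 with fixed theta: tends to the null variance
        assert corrected_variance(0.2, 1e-12, d.x1, d.Z1, fit, d.n1, d.n2) == pytest.approx(
            nv, rel=1e-6
        )
        # nonincreasing in (1 - kappa)
        kappas = np.linspace(0.0, 0.9, 10)
        vs = [corrected_variance(0.2, k, d.x1, d.Z1, fit, d.n1, d.n2) for k in kappas]
        assert np.all(np.diff(vs) >= 0)


class TestR2slsFit:
    def test_standardization_scale_invariance(self):
        # multiplying the raw exposure by 10 leaves (theta_tilde, p) unchanged
        data, _ = make_dataset(seed=21, theta=0.2)
        a = r2sls_fit(data)
        b = r2sls_fit(TwoSampleData(x1=10.0 * data.x1, Z1=data.Z1, y2=data.y2, Z2=data.Z2))
        assert a.theta == pytest.approx(b.theta, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_input_scale_backtransform(self):
        data, _ = make_dataset(seed=22, theta=0.2)
        fr = r2sls_fit(data)
        fi = fr.on_input_scale()
        assert fi.theta == pytest.approx(fr.theta * fr.scale)
        assert fi.z == pytest.approx(fr.z)

    def test_uncorrected_branch_p_values_uniform_under_independence(self):
        # beta = 0: R^2 ~ 0 forces the uncorrected test; p-values uniform
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(1200):
            Z1 = rng.normal(size=(200, 5))
            Z2 = rng.normal(size=(1000, 5))
            x1 = rng.normal(size=200)
            y2 = rng.normal(size=1000)
            fr = r2sls_fit(TwoSampleData(x1=x1, Z1=Z1, y2=y2, Z2=Z2))
            pvals.append(fr.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_force_uncorrected_flag(self, small_data):
        fr = r2sls_fit(small_data, force_uncorrected=True)
        assert not fr.corrected
        assert fr.theta == pytest.approx(fr.theta_raw)
        assert fr.r2_method == "none"

    def test_errors_carry_stage_name(self, rng):
        Z1 = rng.normal(size=(30, 3))
        Z2 = rng.normal(size=(40, 3))
        Z2[:, 1] = Z2[:, 0]
        data = TwoSampleData(x1=rng.normal(size=30), Z1=Z1, y2=rng.normal(size=40), Z2=Z2)
        with pytest.raises(SingularDesignError, match="stage-2"):
            r2sls_fit(data)

    def test_asymptotic_agreement_with_tsls(self):
        # same IVs, n1 = n2 large: the two estimators converge (median
        # absolute difference < 0.005)
        from r2sls.baselines import tsls_fit

        cfg = ScenarioConfig(
            n1=50000, n2=50000, p_cis=30, theta=0.2, target_r2=0.235, reps=1
        )
        ss = np.random.SeedSequence(17).spawn(30)
        diffs = []
        for child in ss:
            data, _ = gen_two_sample(cfg, np.random.default_rng(child))
            a = r2sls_fit(data).on_input_scale().theta
            b = tsls_fit(data).on_input_scale().theta
            diffs.append(abs(a - b))
        assert np.median(diffs) < 0.005
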