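import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from longgwas import lmm
from longgwas.datamodel import AnalysisDataset
from longgwas.lmm import (
    DegenerateDataError,
    FixedEffects,
    LmmFit,
    VarianceComponents,
    chibar2_sf,
    fit_lmm,
    lrt_random_slope,
    marginal_covariance,
    profile_loglik,
    wald_test,
)
from longgwas.synthetic import CohortSpec, default_params, simulate_cohort
from longgwas.datamodel import assemble_dataset

from conftest import dense_gaussian_loglik, make_longitudinal_dataset


class TestMarginalCovariance:
    def test_compound_symmetry_limit(self):
        vc = VarianceComponents(2.0, 0.0, 0.0, 0.5)
        V = marginal_covariance(vc, np.array([0.0, 6.0, 12.0]))
        np.testing.assert_allclose(np.diag(V), 2.5)
        off = V[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)

    def test_baseline_variance_ignores_slope_terms(self):
        vc = VarianceComponents(2.0, 5.0, 1.0, 0.5)
        V = marginal_covariance(vc, np.array([0.0]))
        np.testing.assert_allclose(V, [[2.5]])

    def test_printed_formula_values(self):
        # vc = (1, 0.04, 0.1, 0.5), times (0, 6):
        # Var(6) = 1 + 2*6*0.1 + 36*0.04 + 0.5 = 4.14; Cov = 1 + 6*0.1 = 1.6
        vc = VarianceComponents(1.0, 0.04, 0.1, 0.5)
        V = marginal_covariance(vc, np.array([0.0, 6.0]))
        assert V[1, 1] == pytest.approx(4.14)
        assert V[0, 1] == pytest.approx(1.6)
        assert V[0, 0] == pytest.approx(1.5)

    def test_invalid_vc_rejected(self):
        with pytest.raises(ValueError):
            marginal_covariance(VarianceComponents(1.0, 1.0, 2.0, 0.5), np.array([0.0]))
        with pytest.raises(ValueError):
            marginal_covariance(VarianceComponents(1.0, 0.0, 0.0, 0.0), np.array([0.0]))

    @given(
        s0=st.floats(0.0, 10.0),
        s2=st.floats(0.0, 10.0),
        rho=st.floats(-1.0, 1.0),
        se=st.floats(0.01, 10.0),
        times=st.lists(st.floats(0.0, 60.0), min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_psd(self, s0, s2, rho, se, times):
        vc = VarianceComponents(s0, s2, rho * np.sqrt(s0 * s2), se)
        V = marginal_covariance(vc, np.array(times))
        assert np.min(np.linalg.eigvalsh(V)) >= -1e-10


class TestProfileLoglik:
    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_matches_dense_brute_force(self, method):
        rng = np.random.default_rng(42)
        for _ in range(8):
            data = make_longitudinal_dataset(rng, n=int(rng.integers(4, 11)), max_visits=4)
            vc = VarianceComponents(0.8, 0.3, 0.1, 0.6)
            crit, _, _ = profile_loglik(vc, data, method)
            assert crit == pytest.approx(dense_gaussian_loglik(data, vc, method), abs=1e-10)

    def test_single_visit_collapses_to_ols_loglik(self):
        rng = np.random.default_rng(1)
        n = 30
        data = AnalysisDataset(
            subject_ids=np.arange(n),
            times=rng.uniform(0, 10, n),
            y=rng.standard_normal(n),
            subject_index=np.arange(n),
            snp=rng.binomial(2, 0.3, n).astype(float),
            covariates=rng.standard_normal((n, 1)),
            covariate_names=("c1",),
        )
        vc = VarianceComponents(0.4, 0.0, 0.0, 0.6)  # total variance 1.0
        crit, fe, _ = profile_loglik(vc, data, "ML")
        X, _ = data.design_matrix()
        b = np.linalg.lstsq(X, data.y, rcond=None)[0]
        r = data.y - X @ b
        ols_ll = float(np.sum(stats.norm.logpdf(r, scale=1.0)))
        assert crit == pytest.approx(ols_ll, abs=1e-8)
        np.testing.assert_allclose(fe.as_array(), b, atol=1e-8)

    def test_inflating_residual_variance_penalizes_small_residuals(self):
        # when whitened residual SS is below its expectation, growing the
        # residual variance only adds determinant penalty
        data = make_longitudinal_dataset(np.random.default_rng(3), n=20)
        data.y = data.y * 1e-3  # residuals tiny relative to vc below
        vc = VarianceComponents(1.0, 0.1, 0.0, 1.0)
        vc2 = VarianceComponents(1.0, 0.1, 0.0, 2.0)
        c1, _, _ = profile_loglik(vc, data, "ML")
        c2, _, _ = profile_loglik(vc2, data, "ML")
        assert c2 < c1


class TestFitLmm:
    def test_parameter_recovery_default_cohort(self):
        spec = CohortSpec(seed=9)
        params = default_params("rsi", hypothesis="alternative")
        pheno, cov, geno = simulate_cohort(spec, params)
        data = assemble_dataset(pheno, cov, geno, "snp1", "LHippVol")
        fit = fit_lmm(data, random_slope=True)
        assert fit.converged
        truth = params.fixed.as_array()
        est = fit.fixed.as_array()
        se = np.sqrt(np.diag(fit.cov_fixed))
        assert np.all(np.abs(est - truth) < 4 * se)
        vc = fit.vc
        assert vc.sigma0_sq == pytest.approx(160_000, rel=0.3)
        assert vc.sigma2_sq == pytest.approx(64, rel=0.3)
        assert vc.sigma_eps_sq == pytest.approx(22_500, rel=0.3)

    def test_ri_single_visit_matches_ols(self):
        rng = np.random.default_rng(4)
        n = 50
        data = AnalysisDataset(
            subject_ids=np.arange(n),
            times=rng.uniform(0, 10, n),
            y=rng.standard_normal(n) + 2.0,
            subject_index=np.arange(n),
            snp=rng.binomial(2, 0.3, n).astype(float),
            covariates=rng.standard_normal((n, 1)),
            covariate_names=("c1",),
        )
        fit = fit_lmm(data, random_slope=False)
        X, _ = data.design_matrix()
        ols = np.linalg.lstsq(X, data.y, rcond=None)[0]
        np.testing.assert_allclose(fit.fixed.as_array(), ols, atol=1e-6)

    def test_random_slope_needs_repeat_visits(self):
        rng = np.random.default_rng(5)
        n = 20
        data = AnalysisDataset(
            subject_ids=np.arange(n), times=rng.uniform(0, 10, n),
            y=rng.standard_normal(n), subject_index=np.arange(n),
            snp=rng.binomial(2, 0.3, n).astype(float),
            covariates=rng.standard_normal((n, 1)), covariate_names=("c1",),
        )
        with pytest.raises(DegenerateDataError):
            fit_lmm(data, random_slope=True)

    def test_constant_snp_raises(self, toy_dataset):
        toy_dataset.snp[:] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            fit_lmm(toy_dataset)


def synthetic_fit(beta1, beta3, cov):
    fe = FixedEffects(0.0, beta1, 0.0, beta3, np.zeros(0))
    vc = VarianceComponents(1.0, 0.0, 0.0, 1.0)
    return LmmFit(fe, vc, cov, 0.0, "REML", True, 10, 20)


class TestWald:
    def test_zero_estimates_give_p_one(self):
        res = wald_test(synthetic_fit(0.0, 0.0, np.eye(4)), "joint")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_unit_estimates_identity_cov(self):
        res = wald_test(synthetic_fit(1.0, 1.0, np.eye(4)), "joint")
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(np.exp(-1.0), abs=1e-4)  # 0.3679

    def test_joint_is_sum_of_marginals_under_diagonal_cov(self):
        cov = np.diag([1.0, 2.0, 1.0, 0.5])
        fit = synthetic_fit(0.7, -1.1, cov)
        j = wald_test(fit, "joint").statistic
        m = wald_test(fit, "main").statistic
        i = wald_test(fit, "interaction").statistic
        assert j == pytest.approx(m + i)

    def test_singular_submatrix_raises(self):
        cov = np.zeros((4, 4))
        with pytest.raises(np.linalg.LinAlgError):
            wald_test(synthetic_fit(1.0, 1.0, cov), "joint")

    def test_p_decreasing_in_statistic(self):
        ps = [wald_test(synthetic_fit(b, 0.0, np.eye(4)), "main").p_value
              for b in (0.5, 1.0, 2.0)]
        assert ps[0] > ps[1] > ps[2]


class TestBoundaryLrt:
    def test_mixture_survival_values(self):
        assert chibar2_sf(0.0) == 1.0
        # 0.5 * P(chi2_1 > 5) + 0.5 * P(chi2_2 > 5) = 0.05372
        assert chibar2_sf(5.0) == pytest.approx(0.05372, abs=5e-5)

    def test_detects_strong_slope_heterogeneity(self):
        spec = CohortSpec(seed=21)
        pheno, cov, geno = simulate_cohort(spec, default_params("rsi"))
        data = assemble_dataset(pheno, cov, geno, "snp1", "LHippVol")
        res = lrt_random_slope(data)
        assert res.statistic > 50
        assert res.p_value < 1e-10

    def test_null_calibration_under_random_intercept_truth(self):
        # data from the compound-symmetry model: the boundary-mixture test
        # should reject at about the nominal rate
        import warnings

        spec = CohortSpec(n_subjects=150, seed=0,
                          visit_months=(0., 6., 12., 24.),
                          retention=(1.0, 0.9, 0.9, 0.8))
        params = default_params("cs", hypothesis="null")
        n_reps, hits = 400, 0
        seeds = np.random.SeedSequence(2718).spawn(n_reps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for s in seeds:
                rng = np.random.default_rng(s)
                pheno, cov, geno = simulate_cohort(spec, params, seed=rng)
                data = assemble_dataset(pheno, cov, geno, "snp1", "LHippVol")
                hits += lrt_random_slope(data).p_value < 0.05
        rate = hits / n_reps
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)  # 99% binomial band
        assert abs(rate - 0.05) < band + 0.01  # boundary approx is asymptotic
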