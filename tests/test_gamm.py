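import numpy as np
import pytest

from sfcoupling import SmoothSpec, bh_fdr, fit_gamm, lrt, select_model, spline_basis
from sfcoupling.gamm import ModelFit, SmoothTerm, marginal_loglik_dense


@pytest.fixture(scope="module")
def ages(rng=np.random.default_rng(3)):
    return np.sort(rng.uniform(9.0, 14.0, 200))


class TestSplineBasis:
    def test_partition_of_unity(self, ages):
        basis = spline_basis(ages)
        np.testing.assert_allclose(basis.raw(ages).sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_null_space_contains_linear_pattern(self, ages):
        basis = spline_basis(ages, SmoothSpec(k=6))
        k = 6
        lin = np.arange(k, dtype=float)
        np.testing.assert_allclose(basis.penalty @ lin, 0.0, atol=1e-10)
        np.testing.assert_allclose(basis.penalty @ np.ones(k), 0.0, atol=1e-10)

    def test_constrained_columns_sum_to_zero(self, ages):
        basis = spline_basis(ages)
        xn, zp = basis.terms(ages)
        np.testing.assert_allclose(xn.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(zp.sum(axis=0), 0.0, atol=1e-8)

    def test_column_counts(self, ages):
        basis = spline_basis(ages, SmoothSpec(k=4, penalty_order=2))
        # k=4, one centering constraint, penalty null space {const, linear}
        assert basis.n_null == 1 and basis.n_pen == 2

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            spline_basis(np.array([9.0, 9.0, 10.0, 10.0]))


def _balanced_data(seed=1, n=100, j=2, sigma_b=1.0, sigma=0.5):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n), j)
    y = 2.0 + rng.normal(0, sigma_b, n)[subj] + rng.normal(0, sigma, n * j)
    return y, subj, n, j


class TestFitGamm:
    def test_balanced_random_intercept_matches_closed_form(self):
        y, subj, n, j = _balanced_data()
        fit = fit_gamm(y, np.ones((n * j, 1)), [], subj)
        ym = y.reshape(n, j)
        sig_e = ((ym - ym.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (j - 1))
        sig_b = ((ym.mean(axis=1) - y.mean()) ** 2).sum() / n - sig_e / j
        assert fit.sigma2 == pytest.approx(sig_e, abs=1e-6)
        assert fit.sigma_b2 == pytest.approx(sig_b, abs=1e-6)

    def test_loglik_matches_dense_oracle(self, ages):
        rng = np.random.default_rng(7)
        subj = rng.integers(0, 60, ages.size).astype(str)
        y = 0.2 + 0.05 * (ages - 9) + rng.normal(0, 0.08, ages.size)
        basis = spline_basis(ages)
        xn, zp = basis.terms(ages)
        sm = [SmoothTerm("s_age", xn, zp)]
        fit = fit_gamm(y, np.ones((ages.size, 1)), sm, subj)
        dense = marginal_loglik_dense(y, np.ones((ages.size, 1)), sm, subj, fit)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_zero_column_rejected_as_collinear(self):
        y, subj, n, j = _balanced_data()
        x = np.column_stack([np.ones(n * j), np.zeros(n * j)])
        with pytest.raises(ValueError, match="collinear|singular"):
            fit_gamm(y, x, [], subj, coef_names=["intercept", "dead"])

    def test_aic_identity(self):
        y, subj, n, j = _balanced_data()
        fit = fit_gamm(y, np.ones((n * j, 1)), [], subj)
        assert fit.aic == pytest.approx(
            -2 * fit.loglik + 2 * (fit.n_fixed + fit.n_varpar))

    def test_huge_lambda_recovers_ols_line(self, ages):
        rng = np.random.default_rng(5)
        y = 0.1 + 0.05 * ages + rng.normal(0, 0.05, ages.size)
        basis = spline_basis(ages)
        xn, zp = basis.terms(ages)
        sm = [SmoothTerm("s_age", xn, zp, fixed_ratio=1e-8)]
        fit = fit_gamm(y, np.ones((ages.size, 1)), sm, None)
        a = np.column_stack([np.ones(ages.size), ages])
        beta = np.linalg.lstsq(a, y, rcond=None)[0]
        assert np.abs(fit.fitted - a @ beta).max() < 1e-3


def _fake_fit(model_id, loglik, n_fixed, aic, n_obs=100):
    return ModelFit(model_id=model_id, beta=np.zeros(1), coef_names=["i"],
                    sigma2=1.0, sigma_b2=0.0, lambdas={}, loglik=loglik,
                    n_fixed=n_fixed, n_varpar=2, aic=aic, edf=1.0,
                    fitted=np.zeros(1), n_obs=n_obs, converged=True)


class TestLrt:
    def test_equal_logliks_give_p_one(self):
        _, _, p = lrt(_fake_fit("M0", -10.0, 5, 0), _fake_fit("M1", -10.0, 8, 0))
        assert p == 1.0

    def test_chisq_reference_value(self):
        # deviance 3.841 on 1 df sits at the 5% point of chi-square(1)
        _, df, p = lrt(_fake_fit("M0", 0.0, 5, 0),
                       _fake_fit("M1", 3.841 / 2, 6, 0))
        assert df == 1
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_deviance_clipped(self):
        _, _, p = lrt(_fake_fit("M0", -9.999, 5, 0), _fake_fit("M1", -10.0, 8, 0))
        assert p == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            lrt(_fake_fit("M1", 0, 8, 0), _fake_fit("M0", 0, 5, 0))
        with pytest.raises(ValueError, match="identical rows"):
            lrt(_fake_fit("M0", 0, 5, 0, n_obs=90), _fake_fit("M1", 0, 8, 0))


class TestSelectModel:
    def _ladder(self, logliks, aics):
        nf = [5, 8, 9, 12]
        return [_fake_fit(f"M{i}", ll, nf[i], a)
                for i, (ll, a) in enumerate(zip(logliks, aics))]

    def test_all_stages_pass_reaches_m3(self):
        fits = self._ladder([0, 20, 40, 60], [0, -10, -20, -30])
        assert select_model(fits) == "M3"

    def test_aic_rule_blocks_despite_significant_lrt(self):
        # stage 1: huge LRT but AIC improves by only 1 -> stay at M0
        fits = self._ladder([0, 20, 40, 60], [0, -1, -20, -30])
        assert select_model(fits) == "M0"

    def test_stops_at_first_failing_stage(self):
        # M0 -> M1 passes; M1 -> M2 LRT ns (equal loglik)
        fits = self._ladder([0, 20, 20, 60], [0, -10, -8, -30])
        assert select_model(fits) == "M1"


class TestBhFdr:
    def test_step_up_example(self):
        q, rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        assert list(rej) == [True, True, True, False]

    def test_all_ones(self):
        q, rej = bh_fdr(np.ones(6))
        assert not rej.any() and np.all(q == 1.0)

    def test_single_pvalue(self):
        q, rej = bh_fdr(np.array([0.04]))
        assert rej[0] and q[0] == pytest.approx(0.04)

    def test_nan_passthrough(self):
        q, rej = bh_fdr(np.array([0.01, np.nan, 0.9]))
        assert np.isnan(q[1]) and not rej[1]
        assert rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_q_at_least_p(self, rng):
        p = rng.random(500)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-15)

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        def brute(p, alpha=0.05):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            for pos, idx in enumerate(order):
                q[idx] = min(
                    min(m * p[j] / (np.flatnonzero(order == j)[0] + 1)
                        for j in order[pos:]), 1.0)
            return q

        for _ in range(25):
            p = rng.random(rng.integers(1, 40))
            q, rej = bh_fdr(p)
            np.testing.assert_allclose(q, brute(p), atol=1e-12)
            sm_rej, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)
            np.testing.assert_array_equal(rej, sm_rej)
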