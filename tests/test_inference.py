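import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import LassoCV

from gclasso import (InputError, PredictorGraph, RegressionData,
                     assemble_theta, confidence_intervals, desparsify,
                     effective_number_of_tests, gene_wide_alpha, global_test,
                     gumbel_critical_value, rcv_sigma2, run_pipeline,
                     wald_pvalues)
from gclasso.graphs import Neighborhoods
from gclasso.inference import _variance_weights

Z975 = 1.959963984540054  # Phi^{-1}(0.975), frozen from scipy


class TestDesparsify:
    def test_zero_residual_returns_initial(self, small_data):
        data, _ = small_data
        beta = np.linalg.lstsq(data.X, data.Y, rcond=None)[0]
        # make the residual exactly zero by using Y = X beta
        d2 = RegressionData(X=data.X, Y=data.X @ beta)
        out = desparsify(beta, np.eye(data.p), d2)
        np.testing.assert_allclose(out, beta, atol=1e-12)

    def test_exact_inverse_gives_ols_for_any_start(self, rng):
        """With Theta = Sigma_hat^{-1} the one-step correction lands exactly
        on OLS no matter how biased the initial estimate is."""
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal(40)
        data = RegressionData(X=X, Y=Y)
        Theta = np.linalg.inv(X.T @ X / 40)
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        for start in (np.zeros(5), rng.standard_normal(5)):
            np.testing.assert_allclose(desparsify(start, Theta, data), ols,
                                       atol=1e-8)


class TestRcvSigma2:
    def test_noiseless_data(self, rng):
        X = rng.standard_normal((60, 8))
        beta = np.zeros(8)
        beta[:2] = [4.0, -3.0]
        data = RegressionData(X=X, Y=X @ beta)
        est = rcv_sigma2(data, seed=0)
        assert est.sigma_sq <= 1e-10
        assert est.method == "rcv"

    def test_unit_variance_recovered_roughly(self):
        vals = []
        for r in range(25):
            rng = np.random.default_rng(100 + r)
            X = rng.standard_normal((100, 20))
            beta = np.zeros(20)
            beta[0] = 2.0
            Y = X @ beta + rng.standard_normal(100)
            vals.append(rcv_sigma2(RegressionData(X=X, Y=Y), seed=r).sigma_sq)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_scale_equivariance_of_variance(self, rng):
        X = rng.standard_normal((80, 10))
        Y = X[:, 0] * 2 + rng.standard_normal(80)
        s1 = rcv_sigma2(RegressionData(X=X, Y=Y), seed=3).sigma_sq
        s2 = rcv_sigma2(RegressionData(X=X, Y=3 * Y), seed=3).sigma_sq
        assert s2 == pytest.approx(9 * s1, rel=1e-8)

    def test_small_sample_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(InputError):
            rcv_sigma2(RegressionData(X=X, Y=np.zeros(10)), seed=0)


class TestConfidenceIntervals:
    def test_forced_arithmetic(self):
        """se_j = 1/sqrt(n) with sigma2 * Theta' Sigma Theta = 1 gives the
        textbook +/- z/sqrt(n) interval around zero."""
        n, p = 100, 3
        X = np.vstack([np.eye(p)] * (n // p) + [np.zeros((n % p, p))]) \
            * np.sqrt(n / (n // p))
        data = RegressionData(X=X, Y=np.zeros(n))
        # Theta = I and Sigma_hat = I by construction
        np.testing.assert_allclose(X.T @ X / n, np.eye(p), atol=1e-12)
        res = confidence_intervals(np.zeros(p), np.eye(p), data, 1.0, 0.05)
        np.testing.assert_allclose(res.ci_upper, Z975 / np.sqrt(n), atol=1e-12)
        np.testing.assert_allclose(res.ci_lower, -Z975 / np.sqrt(n), atol=1e-12)
        assert round(float(res.ci_upper[0]), 3) == 0.196

    def test_length_identity(self, rng):
        X = rng.standard_normal((50, 6))
        data = RegressionData(X=X, Y=rng.standard_normal(50))
        Theta = np.linalg.inv(X.T @ X / 50)
        b = rng.standard_normal(6)
        res = confidence_intervals(b, Theta, data, 2.0, 0.1)
        z = stats.norm.ppf(0.95)
        np.testing.assert_allclose(res.ci_upper - res.ci_lower, 2 * z * res.se,
                                   atol=1e-12)
        assert np.all(res.ci_lower <= res.b_hat)
        assert np.all(res.b_hat <= res.ci_upper)

    def test_bad_alpha_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        data = RegressionData(X=X, Y=np.zeros(20))
        with pytest.raises(InputError):
            confidence_intervals(np.zeros(3), np.eye(3), data, 1.0, 1.5)


class TestWaldPvalues:
    def test_zero_estimate_gives_one(self):
        assert wald_pvalues(np.zeros(3), np.ones(3)).tolist() == [1.0] * 3

    def test_quantile_identity(self):
        p = wald_pvalues(np.array([Z975]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-12)

    def test_null_pvalues_uniform(self):
        """Standard-normal z-scores give U(0,1) p-values (KS at 1%)."""
        rng = np.random.default_rng(11)
        z = rng.standard_normal(2000)
        p = wald_pvalues(z, np.ones(2000))
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestGlobalTest:
    def test_critical_value_arithmetic(self):
        # frozen independent arithmetic: q_.05 = -ln(pi) - 2 ln ln(1/.95)
        assert gumbel_critical_value(100, 0.05) == pytest.approx(
            12.478821358403213, abs=1e-9)
        q = gumbel_critical_value(100, 0.05) - 2 * np.log(100) \
            + np.log(np.log(100))
        assert q == pytest.approx(4.795660612234931, abs=1e-9)

    def test_zero_estimates_never_reject(self):
        T, C, rej = global_test(np.zeros(10), np.ones(10), alpha=0.05)
        assert T == 0.0 and not rej

    def test_statistic_is_max_squared_ratio(self, rng):
        b = rng.standard_normal(20)
        se = np.abs(rng.standard_normal(20)) + 0.1
        T, _, _ = global_test(b, se)
        assert T == pytest.approx(np.max((b / se) ** 2))

    def test_small_p_rejected(self):
        with pytest.raises(InputError):
            global_test(np.zeros(1), np.ones(1))


class TestEffectiveTests:
    def test_printed_pathway_value(self):
        # E0 = 59.79 at family level 0.05 -> 8.57e-4 (3 significant figures)
        a = gene_wide_alpha(59.79, 0.05)
        assert a == pytest.approx(8.57e-4, rel=5e-3)

    def test_uncorrelated_columns_give_p(self):
        n, p = 30, 5
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((n, p)))
        X = q - q.mean(axis=0)
        # re-orthogonalize the centered columns pairwise-uncorrelated enough
        e0 = effective_number_of_tests(q)
        assert e0 == pytest.approx(p, abs=0.2)

    def test_identical_columns_give_one(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, x, -x])
        assert effective_number_of_tests(X) == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.ones(20)])
        with pytest.raises(InputError):
            effective_number_of_tests(X)


class TestPipeline:
    def test_matches_hand_assembled_debiasing(self, rng):
        """Empty graph, lambda2 = 0: the pipeline must agree with a manual
        composition of pilot lasso, diagonal precision, one-step correction
        and the Wald interval formulas."""
        X = rng.standard_normal((100, 10))
        beta = np.zeros(10)
        beta[1] = 1.5
        Y = X @ beta + rng.standard_normal(100)
        data = RegressionData(X=X, Y=Y)
        res = run_pipeline(data, None, seed=4, lambda2=0.0)

        # manual: pilot lasso with the pipeline's grid convention
        n = 100
        lam_max = np.max(np.abs(X.T @ Y / n))
        alphas = np.logspace(np.log10(0.01 * lam_max), np.log10(lam_max),
                             30)[::-1]
        cv = LassoCV(alphas=alphas, cv=5, fit_intercept=False, max_iter=5000,
                     tol=1e-4, random_state=4).fit(X, Y)
        tau = (X ** 2).sum(0) / n
        Theta = np.diag(1 / tau)
        b = cv.coef_ + Theta.T @ (X.T @ (Y - X @ cv.coef_)) / n
        np.testing.assert_allclose(res.b_hat, b, atol=1e-8)
        s2 = rcv_sigma2(data, seed=4).sigma_sq
        omega = np.einsum("ij,ij->j", X @ Theta, X @ Theta) / n
        np.testing.assert_allclose(res.se, np.sqrt(s2 * omega / n), atol=1e-10)

    def test_scale_equivariance(self, rng):
        """Y -> 3Y multiplies estimates, ses and CI endpoints by 3 and
        leaves p-values and the max statistic unchanged."""
        X = rng.standard_normal((60, 8))
        Y = X[:, 0] + rng.standard_normal(60)
        g = PredictorGraph.from_edges([str(i) for i in range(8)],
                                      [("0", "1"), ("2", "3")])
        r1 = run_pipeline(RegressionData(X=X, Y=Y), g, seed=9)
        r3 = run_pipeline(RegressionData(X=X, Y=3 * Y), g, seed=9)
        np.testing.assert_allclose(r3.b_hat, 3 * r1.b_hat, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(r3.se, 3 * r1.se, rtol=1e-8)
        np.testing.assert_allclose(r3.ci_upper, 3 * r1.ci_upper, rtol=1e-8,
                                   atol=1e-12)
        np.testing.assert_allclose(r3.p_values, r1.p_values, atol=1e-10)
        assert r3.T_n == pytest.approx(r1.T_n, rel=1e-8)

    def test_p_equal_one_contract(self, rng):
        """Pointwise CI is produced for a single predictor; the global max
        test is undefined there and stays unset."""
        X = rng.standard_normal((40, 1))
        Y = X[:, 0] * 2 + rng.standard_normal(40)
        res = run_pipeline(RegressionData(X=X, Y=Y), None, seed=0)
        assert res.T_n is None
        assert np.isfinite(res.ci_lower[0]) and np.isfinite(res.ci_upper[0])
        with pytest.raises(InputError):
            global_test(res.b_hat, res.se, 1)

    def test_provenance_recorded(self, small_data):
        data, _ = small_data
        res = run_pipeline(data, None, seed=2)
        for key in ("n", "p", "lambda1", "lambda2", "sigma_sq", "seed"):
            assert key in res.provenance


def test_variance_weights_match_quadratic_form(rng):
    X = rng.standard_normal((30, 4))
    data = RegressionData(X=X, Y=np.zeros(30))
    T = rng.standard_normal((4, 4))
    S = X.T @ X / 30
    direct = np.array([T[:, j] @ S @ T[:, j] for j in range(4)])
    np.testing.assert_allclose(_variance_weights(T, data), direct, atol=1e-10)


class TestAlternativesAndAdjustment:
    def test_one_sided_pvalues_split_the_two_sided(self):
        from gclasso import adjust_pvalues
        b = np.array([1.5, -0.7])
        se = np.ones(2)
        two = wald_pvalues(b, se)
        gt = wald_pvalues(b, se, alternative="greater")
        lt = wald_pvalues(b, se, alternative="less")
        np.testing.assert_allclose(gt + lt, 1.0, atol=1e-12)
        np.testing.assert_allclose(np.minimum(gt, lt) * 2, two, atol=1e-12)

    def test_bonferroni_and_bh_adjustments(self):
        from gclasso import adjust_pvalues
        p = np.array([0.01, 0.04, 0.5])
        np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"),
                                   np.minimum(p * 3, 1.0), atol=1e-12)
        bh = adjust_pvalues(p, "bh")
        # step-up: p_(i) * m / i, monotonized
        np.testing.assert_allclose(bh, [0.03, 0.06, 0.5], atol=1e-12)
        with pytest.raises(InputError):
            adjust_pvalues(p, "holm-sidak-nonsense")
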