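"""Unit and property tests for the M-estimation engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resindex as rx
from conftest import random_ls_instance


def _ls_problem(y, X, m0, m1):
    return rx.least_squares_problem(rx.ObservationTable(y, X, m0=m0, m1=m1))


class TestSolveTheta:
    def test_intercept_only_returns_sample_mean(self):
        p = _ls_problem(np.array([0.0, 1.0, 2.0]), np.ones((3, 1)), 0, 1)
        assert rx.solve_theta(p) == pytest.approx([1.0], abs=1e-12)

    def test_exact_linear_outcome_interpolates(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = X @ np.array([1.5, -2.0])
        p = _ls_problem(y, X, 1, 1)
        theta = rx.solve_theta(p)
        assert theta == pytest.approx([1.5, -2.0], abs=1e-10)
        # exact fit: zero meat, zero sandwich
        est = rx.sandwich_covariance(p, theta)
        assert np.allclose(est.K_hat, 0.0, atol=1e-18)
        assert np.allclose(est.Sigma_hat, 0.0, atol=1e-15)

    def test_least_squares_matches_normal_equations(self, rng):
        p, X, y = random_ls_instance(rng)
        theta = rx.solve_theta(p)
        expected = np.linalg.lstsq(X, y, rcond=None)[0]
        assert theta == pytest.approx(expected, abs=1e-8)

    def test_logistic_matches_irls_oracle(self, rng):
        import statsmodels.api as sm

        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        theta_true = np.array([-0.3, 0.8, -0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ theta_true))).astype(float)
        p = rx.logistic_problem(rx.ObservationTable(y, X, m0=1, m1=2))
        theta = rx.solve_theta(p)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        assert theta == pytest.approx(np.asarray(oracle), abs=1e-6)

    def test_gradient_norm_at_solution(self, rng):
        p, _, _ = random_ls_instance(rng)
        theta = rx.solve_theta(p)
        assert np.max(np.abs(p.mean_score(theta))) <= 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.standard_normal((50, 3))
        X = np.column_stack([X, X[:, 1]])  # duplicate column
        y = rng.standard_normal(50)
        table = rx.ObservationTable(y, X, m0=2, m1=2, columns=["a", "b", "c", "dup_b"])
        p = rx.least_squares_problem(table)
        with pytest.raises(rx.RankDeficientDesignError) as exc:
            rx.solve_theta(p)
        assert set(exc.value.columns) & {"b", "dup_b"}

    def test_iteration_cap_reports_gradient_norm(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.3).astype(float)
        p = rx.logistic_problem(rx.ObservationTable(y, X, m0=1, m1=1))
        with pytest.raises(rx.ConvergenceError, match="grad"):
            rx.solve_theta(p, theta0=np.array([8.0, -8.0]), max_iter=1)


class TestBreadAndMeat:
    def test_intercept_only_J_is_one(self):
        p = _ls_problem(np.array([0.0, 1.0, 5.0]), np.ones((3, 1)), 0, 1)
        assert rx.estimate_J(p, np.array([2.0])) == pytest.approx(np.ones((1, 1)))

    def test_J_is_design_gram_matrix_and_matches_finite_differences(self, rng):
        p, X, y = random_ls_instance(rng)
        n = X.shape[0]
        theta = rx.solve_theta(p)
        J = rx.estimate_J(p, theta)
        assert J == pytest.approx(X.T @ X / n, rel=1e-10)
        # strip the analytic Hessian to force the finite-difference path
        import dataclasses

        p_num = dataclasses.replace(p, hessian=None)
        assert rx.estimate_J(p_num, theta) == pytest.approx(J, rel=1e-6, abs=1e-8)

    def test_two_means_J_is_one(self, rng):
        y = rng.standard_normal(40)
        g = (rng.random(40) < 0.5).astype(float)
        p = rx.two_means_problem(y, g, pi1=0.5)
        assert rx.estimate_J(p, np.array([0.0])) == pytest.approx(np.ones((1, 1)))

    def test_K_matches_bruteforce_outer_product(self, rng):
        p, X, y = random_ls_instance(rng)
        theta = rx.solve_theta(p)
        e = y - X @ theta
        n = X.shape[0]
        brute = sum(e[i] ** 2 * np.outer(X[i], X[i]) for i in range(n)) / n
        assert rx.estimate_K(p, theta) == pytest.approx(brute, rel=1e-10)

    def test_information_equality_homoskedastic_gaussian(self):
        # correctly specified limit: K -> sigma^2 J
        rng = np.random.default_rng(11)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        sigma = 1.3
        y = X @ np.array([0.5, -1.0, 0.2]) + sigma * rng.standard_normal(n)
        p = _ls_problem(y, X, 2, 1)
        theta = rx.solve_theta(p)
        diff = rx.estimate_K(p, theta) - sigma**2 * rx.estimate_J(p, theta)
        assert np.max(np.abs(diff)) < 0.12  # ~ Monte-Carlo scale 1/sqrt(n)

    def test_singular_J_reports_condition_number(self, rng):
        y = rng.standard_normal(30)
        X = np.zeros((30, 1))
        p = _ls_problem(y, X, 0, 1)
        with pytest.raises(rx.SingularMatrixError, match="cond"):
            rx.estimate_J(p, np.array([0.0]))


class TestSandwich:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_hc0_equivalence_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        p, X, y = random_ls_instance(rng)
        theta = rx.solve_theta(p)
        est = rx.sandwich_covariance(p, theta)
        e = y - X @ theta
        XtXinv = np.linalg.inv(X.T @ X)
        hc0 = XtXinv @ (X.T * e**2) @ X @ XtXinv
        scale = np.max(np.abs(hc0))
        assert np.max(np.abs(est.Sigma_hat / est.n - hc0)) <= 1e-8 * scale

    def test_two_group_heteroskedastic_limit(self):
        # Sigma -> pi1^{-1} sigma1^2 + pi0^{-1} sigma0^2
        rng = np.random.default_rng(4)
        n, pi1, s1, s0 = 200_000, 0.3, 2.0, 0.5
        g = (rng.random(n) < pi1).astype(float)
        y = np.where(g == 1, 1.0 + np.sqrt(s1) * rng.standard_normal(n),
                     np.sqrt(s0) * rng.standard_normal(n))
        p = rx.two_means_problem(y, g, pi1=pi1)
        est = rx.sandwich_covariance(p, rx.solve_theta(p))
        expected = s1 / pi1 + s0 / (1 - pi1)
        assert est.Sigma_beta[0, 0] == pytest.approx(expected, rel=0.05)

    def test_affine_equivariance(self, rng):
        p, X, y = random_ls_instance(rng)
        theta = rx.solve_theta(p)
        t2 = rx.wald_statistic(rx.sandwich_covariance(p, theta), p.beta0)
        c = 3.7
        Xs = X.copy()
        Xs[:, -1] *= c
        ps = rx.least_squares_problem(
            rx.ObservationTable(y, Xs, m0=p.m0, m1=p.m1)
        )
        theta_s = rx.solve_theta(ps)
        assert theta_s[-1] == pytest.approx(theta[-1] / c, rel=1e-8)
        t2_s = rx.wald_statistic(rx.sandwich_covariance(ps, theta_s), ps.beta0)
        assert t2_s == pytest.approx(t2, rel=1e-8)

    def test_sigma_beta_is_trailing_block(self, rng):
        p, _, _ = random_ls_instance(rng)
        est = rx.sandwich_covariance(p, rx.solve_theta(p))
        assert np.array_equal(est.Sigma_beta, est.Sigma_hat[p.m0 :, p.m0 :])
        assert np.linalg.eigvalsh(est.Sigma_beta).min() >= -1e-10


class TestWaldStatistic:
    @pytest.mark.parametrize(
        "sigma, diff, n, expected",
        [
            (np.eye(2), np.zeros(2), 50, 0.0),
            (np.eye(2), np.array([1.0, 0.0]), 100, 100.0),
            (np.array([[4.0]]), np.array([2.0]), 25, 25.0),
        ],
    )
    def test_closed_form_values(self, sigma, diff, n, expected):
        m1 = sigma.shape[0]
        est = rx.SandwichEstimate(
            theta_hat=diff, J_hat=np.eye(m1), K_hat=sigma,
            Sigma_hat=sigma, Sigma_beta=sigma, n=n, m0=0, m1=m1,
        )
        assert rx.wald_statistic(est, np.zeros(m1)) == pytest.approx(expected)

    def test_permutation_invariance(self, rng):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        beta = np.array([0.5, -0.2])
        perm = [1, 0]
        est = lambda s, b: rx.SandwichEstimate(b, np.eye(2), s, s, s, 80, 0, 2)
        t2 = rx.wald_statistic(est(sigma, beta), np.zeros(2))
        t2p = rx.wald_statistic(est(sigma[np.ix_(perm, perm)], beta[perm]), np.zeros(2))
        assert t2p == pytest.approx(t2, rel=1e-12)

    def test_singular_sigma_beta_fails(self):
        sigma = np.zeros((2, 2))
        est = rx.SandwichEstimate(
            np.ones(2), np.eye(2), sigma, sigma, sigma, 10, 0, 2
        )
        with pytest.raises(rx.SingularMatrixError):
            rx.wald_statistic(est, np.zeros(2))


class TestContracts:
    def test_score_objective_mismatch_rejected(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        table = rx.ObservationTable(y, X, m0=1, m1=1)
        with pytest.raises(ValueError, match="gradient"):
            rx.EstimatingProblem(
                data=table,
                score=lambda th: X * (y - X @ th)[:, None],
                objective=lambda th: -((y - X @ th) ** 2),  # off by factor 2
                m0=1,
                m1=1,
            )

    def test_builtin_families_pass_score_objective_check(self, rng):
        # construction itself runs the probe-point consistency check
        p, _, _ = random_ls_instance(rng)
        assert p.objective is not None
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.4).astype(float)
        assert rx.logistic_problem(
            rx.ObservationTable(y, X, m0=1, m1=1)
        ).objective is not None

    def test_table_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing|finite"):
            rx.ObservationTable(
                np.array([1.0, np.nan]), np.ones((2, 1)), m0=0, m1=1
            )

    def test_dataframe_round_trip_and_record(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "y": rng.standard_normal(40),
                "age": rng.standard_normal(40),
                "dose": rng.standard_normal(40),
            }
        )
        table = rx.ObservationTable.from_dataframe(df, "y", ["age"], ["dose"])
        p = rx.least_squares_problem(table, add_intercept=True)
        res = rx.estimate_from_data(p)
        record = rx.estimate_record(p, res.sandwich, res.t2)
        assert list(record) == ["theta_hat", "Sigma_hat", "Sigma_beta", "T2", "n", "m", "m1"]
        assert record["n"] == 40 and record["m"] == 3 and record["m1"] == 1
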