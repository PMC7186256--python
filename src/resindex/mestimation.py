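"""M-estimation with sandwich (robust) covariance matrices.

An M-estimator maximises a sample-average objective

.. math::

    \\Psi(\\theta; W) = n^{-1} \\sum_{i=1}^n \\psi(\\theta; W_i)

or, equivalently, solves the estimating equation obtained by setting the
averaged per-observation score to zero.  Writing ``J`` for the expected
negative Hessian of ``Psi`` (the "bread") and ``K`` for the second moment of
the per-observation score (the "meat"), ``sqrt(n)(theta_hat - theta)`` is
asymptotically normal with covariance ``J^{-1} K J^{-1}``.  The sandwich is
consistent under second-moment misspecification (heteroskedasticity,
overdispersion), which is what makes Wald statistics built from it robust.

The parameter vector is partitioned ``theta = (alpha, beta)`` with the ``m0``
nuisance coordinates first and the ``m1`` target coordinates last;
``Sigma_beta`` is the trailing ``m1 x m1`` block of the sandwich.

Built-in families
-----------------
``least_squares_problem``
    Linear regression, ``psi_i = -(y_i - x_i theta)^2 / 2``.
``logistic_problem``
    Bernoulli log-likelihood score for logistic regression.
``two_means_problem``
    A difference-in-means score with known or estimated group proportions;
    a single parameter equal to ``mu_1 - mu_0``.

Arbitrary user problems are accepted through the same
:class:`EstimatingProblem` contract (a per-observation score callable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import expit, log_expit

__all__ = [
    "ObservationTable",
    "EstimatingProblem",
    "SandwichEstimate",
    "ConvergenceError",
    "RankDeficientDesignError",
    "SingularMatrixError",
    "least_squares_problem",
    "logistic_problem",
    "two_means_problem",
    "solve_theta",
    "estimate_J",
    "estimate_K",
    "sandwich_covariance",
    "wald_statistic",
    "estimate_record",
]

_EPS = float(np.finfo(float).eps)


class ConvergenceError(RuntimeError):
    """The score iteration did not reach the gradient tolerance."""


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The design matrix does not have full column rank."""

    def __init__(self, columns: Sequence[object], message: Optional[str] = None):
        self.columns = list(columns)
        super().__init__(
            message
            or f"design matrix is rank deficient; offending column(s): {self.columns}"
        )


class SingularMatrixError(np.linalg.LinAlgError):
    """A matrix required to be invertible is singular or near-singular."""


@dataclass(frozen=True)
class ObservationTable:
    """Outcome and covariates for one estimation problem.

    Covariate columns are ordered nuisance first, target last; ``m0`` and
    ``m1`` record the split.  No missing values are allowed.
    """

    outcome: np.ndarray
    covariates: np.ndarray
    m0: int
    m1: int
    columns: Optional[tuple] = None

    def __post_init__(self):
        y = np.asarray(self.outcome, dtype=float)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.ndim != 1:
            raise ValueError("outcome must be one-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("outcome and covariates disagree on n")
        if y.shape[0] < 1:
            raise ValueError("need at least one observation")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("missing or non-finite values in the data")
        if self.m1 < 0 or self.m0 < 0 or self.m0 + self.m1 != X.shape[1]:
            raise ValueError("m0 + m1 must equal the number of covariate columns")
        cols = self.columns
        if cols is not None:
            cols = tuple(cols)
            if len(cols) != X.shape[1]:
                raise ValueError("column labels disagree with covariate count")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def m(self) -> int:
        return self.covariates.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        nuisance: Sequence[str],
        target: Sequence[str],
    ) -> "ObservationTable":
        """Build a table from a data frame using column-role labels."""
        nuisance = list(nuisance)
        target = list(target)
        missing = [c for c in [outcome, *nuisance, *target] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        X = df[nuisance + target].to_numpy(dtype=float)
        y = df[outcome].to_numpy(dtype=float)
        return cls(y, X, m0=len(nuisance), m1=len(target), columns=nuisance + target)


@dataclass(frozen=True)
class EstimatingProblem:
    """Data plus a per-observation score defining an M-estimator.

    Parameters
    ----------
    data : ObservationTable
    score : callable
        ``score(theta) -> (n, m)`` array of per-observation gradients of
        ``psi`` with respect to ``theta`` (maximisation convention).
    m0, m1 : int
        Nuisance / target split of ``theta``; target coordinates last.
    beta0 : ndarray, optional
        Reference value of the target block (defaults to zero).
    objective : callable, optional
        ``objective(theta) -> (n,)`` per-observation ``psi``.  When given, the
        score is validated against its numerical gradient at random probes.
    hessian : callable, optional
        ``hessian(theta) -> (m, m)`` average Hessian of ``Psi``.  Used for
        Newton steps and the analytic bread; otherwise finite differences of
        the score are used.
    meat : callable, optional
        Family-specific estimator of ``K`` overriding the default score
        outer product (used by the two-means family, whose score does not
        have conditional mean zero given the design).
    """

    data: ObservationTable
    score: Callable[[np.ndarray], np.ndarray]
    m0: int
    m1: int
    beta0: np.ndarray = None
    objective: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    meat: Optional[Callable[[np.ndarray], np.ndarray]] = None
    family: str = "custom"
    info: Mapping = field(default_factory=dict)

    def __post_init__(self):
        m = self.m0 + self.m1
        if m < 1 or self.m1 < 1:
            raise ValueError("need m = m0 + m1 >= 1 with at least one target")
        if self.data.n <= m:
            raise ValueError(f"need n > m (n={self.data.n}, m={m})")
        beta0 = self.beta0
        beta0 = np.zeros(self.m1) if beta0 is None else np.atleast_1d(
            np.asarray(beta0, dtype=float)
        )
        if beta0.shape != (self.m1,) or not np.isfinite(beta0).all():
            raise ValueError("beta0 must be a finite vector of length m1")
        object.__setattr__(self, "beta0", beta0)
        if self.objective is not None:
            self._check_score_against_objective()

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def m(self) -> int:
        return self.m0 + self.m1

    def mean_score(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(self.score(np.asarray(theta, dtype=float))).mean(axis=0)

    def _check_score_against_objective(self, n_probes: int = 3) -> None:
        # The score contract must be the gradient of the objective; probe a few
        # random points and compare with central differences.
        rng = np.random.default_rng(20200330)
        for _ in range(n_probes):
            theta = 0.3 * rng.standard_normal(self.m)
            g = self.mean_score(theta)
            num = np.empty(self.m)
            for j in range(self.m):
                h = 1e-6 * (1.0 + abs(theta[j]))
                up, dn = theta.copy(), theta.copy()
                up[j] += h
                dn[j] -= h
                num[j] = (
                    np.mean(self.objective(up)) - np.mean(self.objective(dn))
                ) / (2 * h)
            if not np.allclose(g, num, rtol=1e-4, atol=1e-6):
                raise ValueError(
                    "score is not the gradient of the supplied objective "
                    f"(analytic {g}, numerical {num})"
                )


@dataclass(frozen=True)
class SandwichEstimate:
    """An M-estimate with its bread, meat and sandwich covariance.

    ``Sigma_hat = J_hat^{-1} K_hat J_hat^{-1}`` is the asymptotic covariance
    of ``sqrt(n)(theta_hat - theta)``; ``Sigma_beta`` is its trailing
    ``m1 x m1`` (target) block.
    """

    theta_hat: np.ndarray
    J_hat: np.ndarray
    K_hat: np.ndarray
    Sigma_hat: np.ndarray
    Sigma_beta: np.ndarray
    n: int
    m0: int
    m1: int

    @property
    def m(self) -> int:
        return self.m0 + self.m1

    @property
    def beta_hat(self) -> np.ndarray:
        return self.theta_hat[self.m0 :]


# ---------------------------------------------------------------------------
# Built-in families
# ---------------------------------------------------------------------------


def _with_intercept(table: ObservationTable) -> ObservationTable:
    ones = np.ones((table.n, 1))
    cols = None
    if table.columns is not None:
        cols = ("(intercept)",) + table.columns
    return ObservationTable(
        table.outcome,
        np.hstack([ones, table.covariates]),
        m0=table.m0 + 1,
        m1=table.m1,
        columns=cols,
    )


def least_squares_problem(
    table: ObservationTable,
    beta0: Optional[np.ndarray] = None,
    add_intercept: bool = False,
) -> EstimatingProblem:
    """Least-squares family: ``psi_i = -(y_i - x_i theta)^2 / 2``.

    ``add_intercept`` prepends a column of ones as an extra nuisance
    coordinate.
    """
    if add_intercept:
        table = _with_intercept(table)
    X, y, n = table.covariates, table.outcome, table.n

    def score(theta):
        e = y - X @ theta
        return X * e[:, None]

    def objective(theta):
        e = y - X @ theta
        return -0.5 * e**2

    H = -(X.T @ X) / n  # Hessian of Psi; constant in theta

    return EstimatingProblem(
        data=table,
        score=score,
        objective=objective,
        hessian=lambda theta: H,
        m0=table.m0,
        m1=table.m1,
        beta0=beta0,
        family="least-squares",
        info={"design": X},
    )


def logistic_problem(
    table: ObservationTable,
    beta0: Optional[np.ndarray] = None,
    add_intercept: bool = False,
) -> EstimatingProblem:
    """Bernoulli log-likelihood family for logistic regression."""
    if add_intercept:
        table = _with_intercept(table)
    X, y, n = table.covariates, table.outcome, table.n
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError("logistic outcome must be coded 0/1")

    def score(theta):
        p = expit(X @ theta)
        return X * (y - p)[:, None]

    def objective(theta):
        z = X @ theta
        return y * log_expit(z) + (1.0 - y) * log_expit(-z)

    def hessian(theta):
        p = expit(X @ theta)
        w = p * (1.0 - p)
        return -(X.T @ (X * w[:, None])) / n

    return EstimatingProblem(
        data=table,
        score=score,
        objective=objective,
        hessian=hessian,
        m0=table.m0,
        m1=table.m1,
        beta0=beta0,
        family="logistic",
        info={"design": X},
    )


def two_means_problem(
    y: np.ndarray,
    group: np.ndarray,
    pi1: Optional[float] = None,
    beta0: float = 0.0,
) -> EstimatingProblem:
    """Difference-in-means score with group proportions known or estimated.

    The single parameter is ``theta = mu_1 - mu_0``; the per-observation
    score is ``(2 x_i - 1) pi_{x_i}^{-1} y_i - theta`` for group labels
    ``x_i in {0, 1}``.  When ``pi1`` is None the group-1 proportion is
    estimated by ``n_1 / n`` (labelled in ``info['pi_mode']``).

    The meat uses group-centred residuals ``pi_{x_i}^{-2} (y_i - mu_x)^2``,
    the empirical analogue of the conditional-variance definition of ``K``;
    the raw score outer product would additionally pick up the spread of the
    scaled group means, which is not part of the asymptotic variance of the
    difference in means conditional on the design.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    if not np.isin(np.unique(g), [0.0, 1.0]).all():
        raise ValueError("group labels must be coded 0/1")
    n1 = int(g.sum())
    n = y.shape[0]
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    pi_mode = "known" if pi1 is not None else "estimated"
    p1 = float(pi1) if pi1 is not None else n1 / n
    if not 0.0 < p1 < 1.0:
        raise ValueError("pi1 must lie in (0, 1)")
    p0 = 1.0 - p1
    w = np.where(g == 1.0, 1.0 / p1, -1.0 / p0)  # (2x-1)/pi_x

    table = ObservationTable(y, g[:, None], m0=0, m1=1, columns=("group",))

    def score(theta):
        return (w * y - theta[0])[:, None]

    def meat(theta):
        mu1 = y[g == 1.0].mean()
        mu0 = y[g == 0.0].mean()
        resid = y - np.where(g == 1.0, mu1, mu0)
        return np.array([[np.mean((resid * np.abs(w)) ** 2)]])

    return EstimatingProblem(
        data=table,
        score=score,
        hessian=lambda theta: np.array([[-1.0]]),
        meat=meat,
        m0=0,
        m1=1,
        beta0=np.atleast_1d(beta0),
        family="two-means",
        info={"pi1": p1, "pi_mode": pi_mode},
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _check_design_rank(problem: EstimatingProblem) -> None:
    X = problem.info.get("design") if problem.info else None
    if X is None:
        return
    m = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < m:
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * _EPS * (diag.max() if diag.size else 1.0)
        bad = piv[np.flatnonzero(diag <= tol)] if diag.size else piv
        bad = sorted(set(int(j) for j in np.atleast_1d(bad)) | set(int(j) for j in piv[rank:]))
        cols = problem.data.columns
        names = [cols[j] if cols is not None else j for j in bad]
        raise RankDeficientDesignError(names)


def _numeric_hessian(problem: EstimatingProblem, theta: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the mean score (Hessian of Psi)."""
    theta = np.asarray(theta, dtype=float)
    m = theta.shape[0]
    H = np.empty((m, m))
    for j in range(m):
        h = _EPS ** (1.0 / 3.0) * (1.0 + abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (problem.mean_score(up) - problem.mean_score(dn)) / (2 * h)
    return 0.5 * (H + H.T)


def solve_theta(
    problem: EstimatingProblem,
    theta0: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Solve the estimating equation by damped Newton iteration.

    Returns ``theta_hat`` with ``||mean score||_inf <= tol``.  Uses the
    family's analytic Hessian when available and central finite differences
    of the score otherwise; steps are halved until the score norm decreases.

    Raises
    ------
    ConvergenceError
        If the gradient tolerance is not reached within ``max_iter``
        iterations (the message names the final gradient norm).
    RankDeficientDesignError
        For built-in regression families with a rank-deficient design.
    SingularMatrixError
        If a Newton system is singular.
    """
    _check_design_rank(problem)
    theta = (
        np.zeros(problem.m)
        if theta0 is None
        else np.asarray(theta0, dtype=float).copy()
    )
    g = problem.mean_score(theta)
    for _ in range(max_iter):
        gnorm = np.max(np.abs(g))
        if gnorm <= tol:
            return theta
        H = (
            np.asarray(problem.hessian(theta), dtype=float)
            if problem.hessian is not None
            else _numeric_hessian(problem, theta)
        )
        try:
            step = -sla.solve(H, g)
        except (sla.LinAlgError, ValueError) as exc:
            raise SingularMatrixError(
                f"singular Newton system (cond={np.linalg.cond(H):.3e})"
            ) from exc
        lam = 1.0
        while lam > 1e-12:
            cand = theta + lam * step
            gc = problem.mean_score(cand)
            if np.isfinite(gc).all() and np.max(np.abs(gc)) < gnorm:
                theta, g = cand, gc
                break
            lam *= 0.5
        else:
            raise ConvergenceError(
                f"no descent direction found; final |grad|_inf = {gnorm:.3e}"
            )
    gnorm = np.max(np.abs(g))
    if gnorm <= tol:
        return theta
    raise ConvergenceError(
        f"did not converge in {max_iter} iterations; final |grad|_inf = {gnorm:.3e}"
    )


def estimate_J(problem: EstimatingProblem, theta: np.ndarray) -> np.ndarray:
    """Empirical bread ``J = -n^{-1} sum_i d^2 psi / d theta d theta^T``.

    Analytic when the family provides a Hessian, otherwise central finite
    differences of the score; the result is symmetrised.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    H = (
        np.asarray(problem.hessian(theta), dtype=float)
        if problem.hessian is not None
        else _numeric_hessian(problem, theta)
    )
    J = -0.5 * (H + H.T)
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularMatrixError(f"J is singular or near-singular (cond={cond:.3e})")
    return J


def estimate_K(problem: EstimatingProblem, theta: np.ndarray) -> np.ndarray:
    """Empirical meat ``K = n^{-1} sum_i score_i score_i^T``.

    Families may override this with a specialised estimator through
    ``problem.meat`` (see :func:`two_means_problem`).
    """
    theta = np.asarray(theta, dtype=float)
    if problem.meat is not None:
        K = np.atleast_2d(np.asarray(problem.meat(theta), dtype=float))
    else:
        S = np.asarray(problem.score(theta), dtype=float)
        K = S.T @ S / problem.n
    return 0.5 * (K + K.T)


def sandwich_covariance(
    problem: EstimatingProblem, theta: np.ndarray
) -> SandwichEstimate:
    """Assemble ``Sigma_hat = J^{-1} K J^{-1}`` and its target block."""
    theta = np.asarray(theta, dtype=float)
    J = estimate_J(problem, theta)
    K = estimate_K(problem, theta)
    try:
        Jinv = sla.solve(J, np.eye(problem.m), assume_a="sym")
    except sla.LinAlgError as exc:
        raise SingularMatrixError("J is singular") from exc
    Sigma = Jinv @ K @ Jinv
    Sigma = 0.5 * (Sigma + Sigma.T)
    Sigma_beta = Sigma[problem.m0 :, problem.m0 :]
    evals = np.linalg.eigvalsh(Sigma_beta)
    if evals.min() < -1e-8 * max(1.0, abs(evals).max()):
        raise SingularMatrixError(
            f"Sigma_beta is not positive semidefinite (min eigenvalue {evals.min():.3e})"
        )
    return SandwichEstimate(
        theta_hat=theta,
        J_hat=J,
        K_hat=K,
        Sigma_hat=Sigma,
        Sigma_beta=Sigma_beta,
        n=problem.n,
        m0=problem.m0,
        m1=problem.m1,
    )


def wald_statistic(estimate: SandwichEstimate, beta0: np.ndarray) -> float:
    """Robust Wald chi-squared ``T^2 = n (b - b0)' Sigma_beta^{-1} (b - b0)``."""
    beta0 = np.atleast_1d(np.asarray(beta0, dtype=float))
    if beta0.shape != (estimate.m1,):
        raise ValueError("beta0 must have length m1")
    diff = estimate.beta_hat - beta0
    try:
        c, low = sla.cho_factor(estimate.Sigma_beta)
    except (sla.LinAlgError, ValueError) as exc:
        raise SingularMatrixError("Sigma_beta is not positive definite") from exc
    t2 = float(estimate.n * diff @ sla.cho_solve((c, low), diff))
    return max(t2, 0.0)


def estimate_record(
    problem: EstimatingProblem, estimate: SandwichEstimate, t2: float
) -> dict:
    """JSON-ready summary with deterministic key order."""
    return {
        "theta_hat": estimate.theta_hat.tolist(),
        "Sigma_hat": estimate.Sigma_hat.tolist(),
        "Sigma_beta": estimate.Sigma_beta.tolist(),
        "T2": float(t2),
        "n": int(estimate.n),
        "m": int(estimate.m),
        "m1": int(estimate.m1),
    }
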