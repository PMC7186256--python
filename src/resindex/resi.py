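"""The robust effect size index (RESI).

The index standardises the distance of a target parameter ``beta`` from a
reference value ``beta0`` by the sandwich covariance of its M-estimator,

.. math::

    S = \\sqrt{(\\beta - \\beta_0)^T \\Sigma_\\beta^{-1} (\\beta - \\beta_0)},

so ``n S^2`` is the noncentrality parameter of the robust Wald chi-squared
statistic.  Because the standardisation is model-agnostic, ``S`` lives on a
single scale across models (it is proportional to Cohen's *d* for a two-group
comparison with equal variances and equal group sizes) and feeds directly
into power calculations.

The estimator truncates the natural noncentrality estimate at zero,

.. math::

    \\hat S = \\sqrt{\\max\\{0, (T^2 - m) / (n - m)\\}},

where ``m`` is the *total* number of estimated parameters (nuisance plus
target), which accounts for their estimation in finite samples.

Closed-form special cases implemented here:

* difference of two means with unequal variances and sampling proportions
  (:func:`two_sample_s`),
* simple linear regression under arbitrary heteroskedasticity
  (:func:`linreg_s`),
* logistic regression with nuisance covariates, model-based and robust
  (:func:`logistic_s`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg as sla
from scipy.special import expit

from .mestimation import (
    EstimatingProblem,
    SandwichEstimate,
    SingularMatrixError,
    sandwich_covariance,
    solve_theta,
    wald_statistic,
)

__all__ = [
    "EffectSizeEstimate",
    "TwoSampleSpec",
    "LinRegMoments",
    "LogisticDesignSummary",
    "resi_parameter",
    "resi_estimate",
    "estimate_from_data",
    "two_sample_s",
    "linreg_s",
    "logistic_s",
]


@dataclass(frozen=True)
class EffectSizeEstimate:
    """A truncated index estimate with its Wald-statistic provenance."""

    s_hat: float
    t2: float
    n: int
    m: int
    m1: Optional[int] = None
    truncated: bool = False
    sandwich: Optional[SandwichEstimate] = None


def resi_parameter(
    beta: np.ndarray, beta0: np.ndarray, sigma_beta: np.ndarray
) -> float:
    """Population index ``sqrt((b-b0)' Sigma_beta^{-1} (b-b0))``.

    ``sigma_beta`` must be positive definite.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    beta0 = np.atleast_1d(np.asarray(beta0, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma_beta, dtype=float))
    diff = beta - beta0
    try:
        c, low = sla.cho_factor(sigma)
    except (sla.LinAlgError, ValueError) as exc:
        raise ValueError("sigma_beta must be positive definite") from exc
    return float(np.sqrt(max(diff @ sla.cho_solve((c, low), diff), 0.0)))


def resi_estimate(
    t2: float, n: int, m: int, m1: Optional[int] = None
) -> EffectSizeEstimate:
    """Truncated estimator ``sqrt(max(0, (T^2 - m)/(n - m)))``.

    ``m`` counts *all* estimated parameters.  The ``truncated`` flag records
    that the raw noncentrality estimate fell below zero (``T^2 < m``).
    """
    if not np.isfinite(t2) or t2 < 0:
        raise ValueError("T2 must be a nonnegative finite number")
    n, m = int(n), int(m)
    if m < 1 or n <= m:
        raise ValueError(f"need n > m >= 1 (n={n}, m={m})")
    s_hat = float(np.sqrt(max(0.0, (t2 - m) / (n - m))))
    return EffectSizeEstimate(
        s_hat=s_hat, t2=float(t2), n=n, m=m, m1=m1, truncated=bool(t2 < m)
    )


def estimate_from_data(problem: EstimatingProblem) -> EffectSizeEstimate:
    """Full pipeline: solve, sandwich, Wald statistic, truncated index."""
    theta = solve_theta(problem)
    est = sandwich_covariance(problem, theta)
    t2 = wald_statistic(est, problem.beta0)
    result = resi_estimate(t2, problem.n, problem.m, problem.m1)
    return EffectSizeEstimate(
        s_hat=result.s_hat,
        t2=result.t2,
        n=result.n,
        m=result.m,
        m1=result.m1,
        truncated=result.truncated,
        sandwich=est,
    )


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoSampleSpec:
    """Population description of a two-group comparison."""

    mu1: float
    mu0: float
    sigma1_sq: float
    sigma0_sq: float
    pi1: float

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError("pi1 must lie in (0, 1)")
        if self.sigma1_sq <= 0 or self.sigma0_sq <= 0:
            raise ValueError("variances must be positive")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def sigma_beta(self) -> float:
        """Asymptotic variance of the difference-in-means estimator."""
        return self.sigma1_sq / self.pi1 + self.sigma0_sq / self.pi0


def two_sample_s(spec: TwoSampleSpec) -> float:
    """Index for a difference of means.

    ``S = sqrt((mu1-mu0)^2 / (pi1^{-1} sigma1^2 + pi0^{-1} sigma0^2))``;
    reduces to a multiple of Cohen's *d* with equal variances.
    """
    delta = spec.mu1 - spec.mu0
    return float(np.sqrt(delta**2 / spec.sigma_beta))


@dataclass(frozen=True)
class LinRegMoments:
    """Moments defining the simple-linear-regression index.

    ``sigma_sq`` is the mean squared residual, ``mu_xy = E[X e^2]`` and
    ``sigma_xy_sq = E[(X - mu_x)^2 e^2]`` capture the dependence between the
    covariate and the conditional outcome variance; under homoskedasticity
    ``sigma_xy_sq = sigma_x_sq * sigma_sq``.
    """

    mu_x: float
    sigma_x_sq: float
    sigma_sq: float
    mu_xy: float
    sigma_xy_sq: float
    beta: float
    alpha: float = 0.0

    def __post_init__(self):
        if self.sigma_x_sq <= 0 or self.sigma_xy_sq <= 0:
            raise ValueError("sigma_x_sq and sigma_xy_sq must be positive")

    @classmethod
    def homoskedastic(
        cls, sigma_x_sq: float, sigma_sq: float, beta: float,
        mu_x: float = 0.0, alpha: float = 0.0,
    ) -> "LinRegMoments":
        return cls(
            mu_x=mu_x,
            sigma_x_sq=sigma_x_sq,
            sigma_sq=sigma_sq,
            mu_xy=0.0 if mu_x == 0.0 else mu_x * sigma_sq,
            sigma_xy_sq=sigma_x_sq * sigma_sq,
            beta=beta,
            alpha=alpha,
        )

    @classmethod
    def from_sample(cls, x: np.ndarray, y: np.ndarray) -> "LinRegMoments":
        """Empirical plug-in moments (divide-by-n convention)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        mu_x = x.mean()
        xc = x - mu_x
        sigma_x_sq = np.mean(xc**2)
        beta = np.mean(xc * (y - y.mean())) / sigma_x_sq
        alpha = y.mean() - beta * mu_x
        e = y - alpha - beta * x
        return cls(
            mu_x=float(mu_x),
            sigma_x_sq=float(sigma_x_sq),
            sigma_sq=float(np.mean(e**2)),
            mu_xy=float(np.mean(x * e**2)),
            sigma_xy_sq=float(np.mean(xc**2 * e**2)),
            beta=float(beta),
            alpha=float(alpha),
        )


def linreg_s(moments: LinRegMoments) -> float:
    """Index for simple linear regression: ``|beta| sqrt(sigma_x^4 / sigma_xy^2)``.

    Under homoskedasticity this equals ``|beta| sqrt(sigma_x^2 / sigma^2)``.
    """
    return float(
        abs(moments.beta) * np.sqrt(moments.sigma_x_sq**2 / moments.sigma_xy_sq)
    )


@dataclass(frozen=True)
class LogisticDesignSummary:
    """Weight cross-product blocks for the logistic-regression index.

    ``A_kl(W) = n^{-1} X_k' diag(w) X_l`` for the model weights
    ``P_ii = p_i (1 - p_i)`` and the empirical weights
    ``Q_ii = (y_i - p_i)^2``; ``P = Q`` in expectation iff the binomial
    variance model is correct (otherwise there is under/over dispersion).
    ``I_beta`` is the information of the target block after projecting out
    the nuisance block; ``Sigma_beta`` the robust (sandwich) counterpart,
    equal to ``I_beta^{-1}`` when ``P = Q``.
    """

    A00_p: np.ndarray
    A01_p: np.ndarray
    A11_p: np.ndarray
    A00_q: np.ndarray
    A01_q: np.ndarray
    A11_q: np.ndarray
    I_beta: np.ndarray
    Sigma_beta: np.ndarray
    m0: int
    m1: int

    @classmethod
    def from_weights(
        cls,
        X0: np.ndarray,
        X1: np.ndarray,
        model_weights: np.ndarray,
        empirical_weights: Optional[np.ndarray] = None,
    ) -> "LogisticDesignSummary":
        X0 = np.atleast_2d(np.asarray(X0, dtype=float))
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        if X0.size == 0:
            X0 = X0.reshape(X1.shape[0], 0)
        if X0.ndim == 2 and X0.shape[0] == 1 and X1.shape[0] != 1:
            X0 = X0.T
        if X1.shape[0] == 1 and X0.shape[0] != 1:
            X1 = X1.T
        n = X1.shape[0]
        p = np.asarray(model_weights, dtype=float)
        q = p if empirical_weights is None else np.asarray(empirical_weights, float)

        def a(Xa, Xb, w):
            return Xa.T @ (Xb * w[:, None]) / n

        A00_p, A01_p, A11_p = a(X0, X0, p), a(X0, X1, p), a(X1, X1, p)
        A00_q, A01_q, A11_q = a(X0, X0, q), a(X0, X1, q), a(X1, X1, q)
        m0, m1 = X0.shape[1], X1.shape[1]
        if m0 > 0:
            cond = np.linalg.cond(A00_p)
            if not np.isfinite(cond) or cond > 1e12:
                raise SingularMatrixError(
                    f"A00(P) is singular or near-singular (cond={cond:.3e})"
                )
            A00_p_inv = np.linalg.inv(A00_p)
        else:
            A00_p_inv = np.zeros((0, 0))
        I_beta = A11_p - A01_p.T @ A00_p_inv @ A01_p
        C = np.linalg.inv(I_beta)
        # Printed two-bracket form of the beta block of J^{-1} K J^{-1}.
        B = A01_p.T @ A00_p_inv  # A10(P) A00(P)^{-1}
        bracket1 = B @ A00_q @ B.T - B @ A01_q
        bracket2 = A11_q - A01_q.T @ B.T
        Sigma_beta = C @ (bracket1 + bracket2) @ C
        Sigma_beta = 0.5 * (Sigma_beta + Sigma_beta.T)
        return cls(
            A00_p=A00_p, A01_p=A01_p, A11_p=A11_p,
            A00_q=A00_q, A01_q=A01_q, A11_q=A11_q,
            I_beta=0.5 * (I_beta + I_beta.T),
            Sigma_beta=Sigma_beta,
            m0=m0, m1=m1,
        )

    @classmethod
    def from_model(
        cls,
        X0: np.ndarray,
        X1: np.ndarray,
        theta: np.ndarray,
        y: Optional[np.ndarray] = None,
    ) -> "LogisticDesignSummary":
        """Summary at parameter ``theta``; with ``y`` the empirical weights
        are the squared residuals, otherwise the model is taken as correct."""
        X0 = np.atleast_2d(np.asarray(X0, dtype=float))
        X1 = np.asarray(X1, dtype=float)
        if X1.ndim == 1:
            X1 = X1[:, None]
        if X0.size == 0:
            X0 = np.zeros((X1.shape[0], 0))
        elif X0.shape[0] == 1 and X1.shape[0] != 1:
            X0 = X0.T
        X = np.hstack([X0, X1])
        p = expit(X @ np.asarray(theta, dtype=float))
        model_w = p * (1.0 - p)
        emp_w = None if y is None else (np.asarray(y, float) - p) ** 2
        return cls.from_weights(X0, X1, model_w, emp_w)


def logistic_s(
    summary: LogisticDesignSummary,
    beta: np.ndarray,
    assume_correct_model: bool = False,
) -> float:
    """Index for logistic regression with nuisance covariates.

    Uses ``sqrt(beta' Sigma_beta^{-1} beta)`` with the robust block in
    general; with ``assume_correct_model`` (``P = Q``) this reduces to
    ``sqrt(beta' I_beta beta)``, the information-standardised coefficient
    that discounts collinearity with the nuisance block.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if assume_correct_model:
        return float(np.sqrt(max(beta @ summary.I_beta @ beta, 0.0)))
    return resi_parameter(beta, np.zeros_like(beta), summary.Sigma_beta)
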