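"""Asymptotic bias of classical effect size estimators under heteroskedasticity.

The pooled-SD Cohen's-d estimator and the classical ``R²`` estimator converge
to limits that standardise by the *marginal* (pooled) variance, while the
robust index standardises by the sandwich variance of the target estimator.
When group variances differ and sampling is unbalanced (or, in regression,
when the conditional outcome variance depends on the covariate) the two
disagree; the ratio of the classical limit to the robust value quantifies
the asymptotic bias of the classical estimator.

Conventions: ``ratio = classical / robust``; percent bias is
``100 * (ratio - 1)``.  The pooled-SD (square-rooted) form of the limiting
Cohen's-d denominator is used — the one consistent with the printed ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeteroskedasticTwoSample",
    "HeteroskedasticRegression",
    "cohens_d_bias_ratio",
    "r2_bias_ratio",
    "bias_surface",
]


@dataclass(frozen=True)
class HeteroskedasticTwoSample:
    """Group-1 proportion and the two group variances."""

    pi1: float
    sigma1_sq: float
    sigma0_sq: float

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError("pi1 must lie in (0, 1)")
        if self.sigma1_sq <= 0 or self.sigma0_sq <= 0:
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class HeteroskedasticRegression:
    """Moments of a simple regression with covariate-dependent variance.

    Homoskedastic iff ``sigma_xy_sq == sigma_x_sq * sigma_y_sq`` (here
    ``sigma_y_sq`` denotes the mean conditional variance of the outcome and
    ``sigma_xy_sq = E[(X - mu_x)^2 Var(Y|X)]``).
    """

    sigma_x_sq: float
    sigma_y_sq: float
    sigma_xy_sq: float
    beta: float

    def __post_init__(self):
        if min(self.sigma_x_sq, self.sigma_y_sq, self.sigma_xy_sq) <= 0:
            raise ValueError("moments must be positive")


def cohens_d_bias_ratio(spec: HeteroskedasticTwoSample) -> float:
    """Ratio of the pooled-SD Cohen's-d limit to the robust d.

    ``d_C/d(S) = (pi1^{-1} + pi0^{-1})^{-1/2}
    * sqrt((pi1^{-1} s1^2 + pi0^{-1} s0^2) / (pi1 s1^2 + pi0 s0^2))``.
    Equals 1 when ``pi1 = 1/2`` or the variances are equal; symmetric about
    ``(0, 1/2)`` in (log2 variance ratio, pi1) coordinates.
    """
    p1, p0 = spec.pi1, 1.0 - spec.pi1
    s1, s0 = spec.sigma1_sq, spec.sigma0_sq
    lev = 1.0 / p1 + 1.0 / p0
    return float(
        lev ** (-0.5) * math.sqrt((s1 / p1 + s0 / p0) / (p1 * s1 + p0 * s0))
    )


def r2_bias_ratio(spec: HeteroskedasticRegression) -> float:
    """Ratio of the classical ``R^2`` limit to the robust ``R^2(S)``.

    ``R2_C/R2(S) = (sx^4 b^2 + sx^2 sy^2) / (sx^4 b^2 + sxy^2)``; equals 1
    under homoskedasticity and is strictly decreasing in ``sigma_xy_sq``.
    """
    num = spec.sigma_x_sq**2 * spec.beta**2 + spec.sigma_x_sq * spec.sigma_y_sq
    den = spec.sigma_x_sq**2 * spec.beta**2 + spec.sigma_xy_sq
    return float(num / den)


def bias_surface(
    index: str,
    log2_ratio: Sequence[float],
    pi1: Optional[Sequence[float]] = None,
    beta: float = 0.0,
    sigma_x_sq: float = 1.0,
    sigma_y_sq: float = 1.0,
) -> pd.DataFrame:
    """Percent-bias table ``100 * (ratio - 1)`` over a grid.

    For ``index='d'`` the grid is the Cartesian product of
    ``log2_ratio = log2(sigma1^2 / sigma0^2)`` (with ``sigma0^2 = 1``) and
    ``pi1``.  For ``index='r2'`` it is over
    ``log2_ratio = log2(sigma_xy^2 / (sigma_x^2 sigma_y^2))`` at the given
    ``beta`` and marginal moments.
    """
    log2_ratio = np.asarray(list(log2_ratio), dtype=float)
    rows = []
    if index == "d":
        if pi1 is None:
            raise ValueError("pi1 grid required for the Cohen's-d surface")
        for p in np.asarray(list(pi1), dtype=float):
            for x in log2_ratio:
                ratio = cohens_d_bias_ratio(
                    HeteroskedasticTwoSample(pi1=p, sigma1_sq=2.0**x, sigma0_sq=1.0)
                )
                rows.append(
                    {"index": "d", "log2_ratio": x, "pi1": p,
                     "percent_bias": 100.0 * (ratio - 1.0)}
                )
    elif index == "r2":
        for x in log2_ratio:
            spec = HeteroskedasticRegression(
                sigma_x_sq=sigma_x_sq,
                sigma_y_sq=sigma_y_sq,
                sigma_xy_sq=2.0**x * sigma_x_sq * sigma_y_sq,
                beta=beta,
            )
            rows.append(
                {"index": "r2", "log2_ratio": x, "pi1": np.nan,
                 "percent_bias": 100.0 * (r2_bias_ratio(spec) - 1.0)}
            )
    else:
        raise ValueError("index must be 'd' or 'r2'")
    return pd.DataFrame(rows)
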