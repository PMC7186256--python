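"""Model-free power and sample-size calculations from the robust index.

Because ``n S^2`` is the noncentrality of the robust Wald chi-squared
statistic, power depends on the model only through ``S`` and the target
degrees of freedom:

.. math::

    1 - t_2 = 1 - \\Phi_{df}\\{\\Phi_{df}^{-1}(1 - t_1; 0);\\; n S^2\\},

where ``Phi(.; lambda)`` is the noncentral chi-squared CDF and ``t1``/``t2``
the type-I/II error rates.  The equation is monotone in each argument, so
any one of (power, n, S, t1) can be solved from the others by bracketed
root search.  ``n`` is treated as continuous; use ``round_up`` for a
convenience ceiling.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2

__all__ = [
    "power_from_s",
    "n_from_power",
    "s_from_power",
    "t1_from_power",
    "power_curve",
]

_N_MAX = 1e9
_S_MAX = 100.0


def _check_t1(t1: float) -> float:
    t1 = float(t1)
    if not (0.0 < t1 < 1.0):
        raise ValueError("t1 must lie in (0, 1)")
    return t1


def _check_df(df: int) -> int:
    df = int(df)
    if df < 1:
        raise ValueError("df must be a positive integer")
    return df


def power_from_s(t1: float, df: int, s: float, n: float) -> float:
    """Power of the ``df``-degree chi-squared test at index ``s`` and size ``n``.

    Strictly increasing in ``s`` and (for ``s > 0``) in ``n``; equals ``t1``
    exactly at ``s = 0``.
    """
    t1 = _check_t1(t1)
    df = _check_df(df)
    s = float(s)
    if s < 0:
        raise ValueError("s must be nonnegative")
    if n < 1:
        raise ValueError("n must be at least 1")
    lam = n * s * s
    if lam == 0.0:
        return t1
    q = chi2.isf(t1, df)
    return float(ncx2.sf(q, df, lam))


def n_from_power(
    t1: float, df: int, s: float, power: float, round_up: bool = False
) -> float:
    """Smallest (real) ``n`` achieving the requested power.

    Bracketed root search on ``[1, 1e9]``; the round trip through
    :func:`power_from_s` is accurate to ~1e-8 in power.
    """
    t1 = _check_t1(t1)
    df = _check_df(df)
    if s <= 0:
        raise ValueError("s must be positive to reach power above t1")
    if not (t1 < power < 1.0):
        raise ValueError("power must lie in (t1, 1)")
    if power_from_s(t1, df, s, 1.0) >= power:
        return 1.0
    if power_from_s(t1, df, s, _N_MAX) < power:
        raise ValueError("requested power unreachable within the n bracket")
    n = brentq(
        lambda v: power_from_s(t1, df, s, v) - power,
        1.0,
        _N_MAX,
        xtol=1e-10,
        rtol=8.9e-16,
        maxiter=500,
    )
    return float(math.ceil(n)) if round_up else float(n)


def s_from_power(t1: float, df: int, n: float, power: float) -> float:
    """Index required for the requested power at fixed ``n`` and ``df``."""
    t1 = _check_t1(t1)
    df = _check_df(df)
    if n < 1:
        raise ValueError("n must be at least 1")
    power = float(power)
    if power < t1:
        raise ValueError("power below t1 is unreachable for s >= 0")
    if power >= 1.0:
        raise ValueError("power must be < 1")
    if power == t1:
        return 0.0
    s = brentq(
        lambda v: power_from_s(t1, df, v, n) - power,
        0.0,
        _S_MAX,
        xtol=1e-12,
        rtol=8.9e-16,
        maxiter=500,
    )
    return float(s)


def t1_from_power(df: int, s: float, n: float, power: float) -> float:
    """Type-I error rate at which the design attains the requested power."""
    df = _check_df(df)
    if s <= 0:
        raise ValueError("s must be positive")
    if not (0.0 < power < 1.0):
        raise ValueError("power must lie in (0, 1)")
    lo, hi = 1e-12, 1.0 - 1e-12
    f = lambda a: power_from_s(a, df, s, n) - power
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("requested power unreachable for any t1 in (0, 1)")
    return float(brentq(f, lo, hi, xtol=1e-14, maxiter=500))


def power_curve(
    t1: float, df: int, s: float, n_grid: Union[Sequence[float], np.ndarray]
) -> pd.DataFrame:
    """Tabulate power over a grid of sample sizes.

    Returns a data frame with columns ``n`` and ``power``; the power column
    is nondecreasing in ``n``.
    """
    n_grid = np.asarray(list(n_grid), dtype=float)
    if n_grid.size == 0:
        raise ValueError("n_grid must be non-empty")
    rows = [power_from_s(t1, df, s, n) for n in n_grid]
    return pd.DataFrame({"n": n_grid, "power": rows})
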