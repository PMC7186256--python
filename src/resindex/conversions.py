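"""Conversions among the robust index S, Cohen's d, f², and R².

Under homoskedasticity and a correctly specified model the robust index
induces the classical conversion formulas between effect size indices; every
conversion here routes through the same algebra, so all pairwise round trips
are exact identities.  ``pi1``/``pi0`` are the population group proportions
of a two-group comparison (they enter only the Cohen's-d conversions).

The unsubscripted ``f²``/``R²`` of the two-argument forms refer to the full
model including covariates; the single-argument convenience forms cover the
no-other-covariate case where the partial and full values coincide.

Magnitude convention: d-conversions return ``|d|``; callers carry the sign
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GroupProportions",
    "s_from_d",
    "d_from_s",
    "f2_from_s",
    "s_from_f2",
    "r2_from_s",
    "s_from_r2",
    "f2_from_d",
    "d_from_f2",
    "r2_from_d",
    "d_from_r2",
    "r2_from_f2",
    "f2_from_r2",
    "classify_effect_size",
    "convert",
    "EFFECT_SIZE_BANDS",
]


@dataclass(frozen=True)
class GroupProportions:
    """Population group proportions, ``pi0 = 1 - pi1``."""

    pi1: float

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError("pi1 must lie in (0, 1)")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def leverage(self) -> float:
        """``pi1^{-1} + pi0^{-1}``, the design factor in d conversions."""
        return 1.0 / self.pi1 + 1.0 / self.pi0


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be nonnegative and finite")
    return value


def _check_r2(r2_partial: float, r2_full: Optional[float]) -> tuple:
    r2_partial = float(r2_partial)
    r2_full = r2_partial if r2_full is None else float(r2_full)
    if not (0.0 <= r2_partial <= r2_full):
        raise ValueError("need 0 <= r2_partial <= r2_full")
    if r2_full >= 1.0:
        raise ValueError("r2_full must be < 1")
    return r2_partial, r2_full


def s_from_d(d: float, props: GroupProportions) -> float:
    """``S = (pi1^{-1} + pi0^{-1})^{-1/2} |d|``."""
    return abs(float(d)) / math.sqrt(props.leverage)


def d_from_s(s: float, props: GroupProportions) -> float:
    """``|d| = (pi1^{-1} + pi0^{-1})^{1/2} S`` (inverse of :func:`s_from_d`)."""
    return _check_nonneg(s, "s") * math.sqrt(props.leverage)


def f2_from_s(s: float) -> float:
    """``f^2 = S^2``."""
    return _check_nonneg(s, "s") ** 2


def s_from_f2(f2: float) -> float:
    """``S = sqrt(f^2)``."""
    return math.sqrt(_check_nonneg(f2, "f2"))


def r2_from_s(s: float) -> float:
    """``R^2 = S^2 / (1 + S^2)`` (no-other-covariate case)."""
    s2 = _check_nonneg(s, "s") ** 2
    return s2 / (1.0 + s2)


def s_from_r2(r2_partial: float, r2_full: Optional[float] = None) -> float:
    """``S = sqrt(R^2_beta / (1 - R^2))`` with full-model ``R^2``."""
    r2_partial, r2_full = _check_r2(r2_partial, r2_full)
    return math.sqrt(r2_partial / (1.0 - r2_full))


def f2_from_d(d: float, props: GroupProportions) -> float:
    """``f^2 = (pi1^{-1} + pi0^{-1})^{-1} d^2``."""
    return float(d) ** 2 / props.leverage


def d_from_f2(f2: float, props: GroupProportions) -> float:
    """``|d| = (pi1^{-1} + pi0^{-1})^{1/2} sqrt(f^2)``."""
    return math.sqrt(props.leverage * _check_nonneg(f2, "f2"))


def r2_from_d(d: float, props: GroupProportions) -> float:
    """``R^2 = d^2 / ((pi1^{-1} + pi0^{-1}) + d^2)``."""
    d2 = float(d) ** 2
    return d2 / (props.leverage + d2)


def d_from_r2(
    r2_partial: float, props: GroupProportions, r2_full: Optional[float] = None
) -> float:
    """``|d| = (pi1^{-1} + pi0^{-1})^{1/2} sqrt(R^2_beta / (1 - R^2))``."""
    return math.sqrt(props.leverage) * s_from_r2(r2_partial, r2_full)


def r2_from_f2(f2_partial: float, f2_full: Optional[float] = None) -> float:
    """``R^2 = f^2_beta / (1 + f^2)`` with full-model ``f^2``."""
    f2_partial = _check_nonneg(f2_partial, "f2_partial")
    f2_full = f2_partial if f2_full is None else _check_nonneg(f2_full, "f2_full")
    return f2_partial / (1.0 + f2_full)


def f2_from_r2(r2_partial: float, r2_full: Optional[float] = None) -> float:
    """``f^2 = R^2_beta / (1 - R^2)`` with full-model ``R^2``."""
    r2_partial, r2_full = _check_r2(r2_partial, r2_full)
    return r2_partial / (1.0 - r2_full)


#: Qualitative bands on the S scale (right-closed intervals); the top band is
#: open-ended — an extrapolation beyond the published thresholds.
EFFECT_SIZE_BANDS = (
    ("none-small", 0.0, 0.1),
    ("small-medium", 0.1, 0.25),
    ("medium-large", 0.25, 0.4),
    ("large", 0.4, math.inf),
)


def classify_effect_size(s: float) -> str:
    """Map an index value to its qualitative band.

    ``[0, 0.1] -> none-small``, ``(0.1, 0.25] -> small-medium``,
    ``(0.25, 0.4] -> medium-large``, ``> 0.4 -> large`` (extrapolated,
    open-ended).  Interval endpoints are closed on the right.
    """
    s = float(s)
    if not math.isfinite(s) or s < 0:
        raise ValueError("s must be nonnegative and finite")
    for label, lo, hi in EFFECT_SIZE_BANDS:
        if s <= hi:
            return label
    return EFFECT_SIZE_BANDS[-1][0]  # pragma: no cover


def convert(
    value: float,
    source: str,
    target: str,
    pi1: Optional[float] = None,
    r2_full: Optional[float] = None,
) -> float:
    """Dispatch a single conversion between named indices.

    ``source``/``target`` are among ``{'d', 'f2', 'r2', 'S'}``.  ``pi1`` is
    required whenever ``d`` is involved; ``r2_full`` applies when the source
    is ``r2``.
    """
    source, target = source.lower(), target.lower()
    names = {"d", "f2", "r2", "s"}
    if source not in names or target not in names:
        raise ValueError(f"indices must be one of {sorted(names)}")
    if source == target:
        return float(value)
    props = None
    if "d" in (source, target):
        if pi1 is None:
            raise ValueError("pi1 is required for conversions involving d")
        props = GroupProportions(pi1)
    table = {
        ("d", "s"): lambda v: s_from_d(v, props),
        ("d", "f2"): lambda v: f2_from_d(v, props),
        ("d", "r2"): lambda v: r2_from_d(v, props),
        ("s", "d"): lambda v: d_from_s(v, props),
        ("s", "f2"): f2_from_s,
        ("s", "r2"): r2_from_s,
        ("f2", "s"): s_from_f2,
        ("f2", "d"): lambda v: d_from_f2(v, props),
        ("f2", "r2"): r2_from_f2,
        ("r2", "s"): lambda v: s_from_r2(v, r2_full),
        ("r2", "d"): lambda v: d_from_r2(v, props, r2_full),
        ("r2", "f2"): lambda v: f2_from_r2(v, r2_full),
    }
    return float(table[(source, target)](value))
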