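"""Pearson chi-square goodness-of-fit against a uniform expectation.

The test asks whether observed per-chromosome mention counts are consistent
with every chromosome being equally likely.  With k cells and total count N,
the expected count per cell is E = N/k, the statistic is

    X^2 = sum_i (O_i - E)^2 / E,      df = k - 1,

and the p-value is the upper tail of the chi-square distribution,
P(X^2_{df} >= x) = Q(df/2, x/2), where Q is the regularized upper incomplete
gamma function.  Q is implemented here from first principles (series
expansion below the a+1 crossover, Lentz continued fraction above it) so the
test carries no statistical-library dependency; the implementation is
validated elsewhere against an independent survival-function oracle.

No continuity correction is applied (plain Pearson statistic).  Expected
counts need not be integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChiSquareResult",
    "chi_square_uniform",
    "chisq_upper_tail",
    "format_p_value",
]

_EPS = 1e-16
_MAX_ITER = 1000
P_VALUE_FLOOR = 1e-15


def _gamma_p_series(a: float, x: float) -> float:
    """Lower regularized incomplete gamma P(a, x) by series; for x < a + 1."""
    term = 1.0 / a
    total = term
    n = 0
    while n < _MAX_ITER:
        n += 1
        term *= x / (a + n)
        total += term
        if abs(term) < abs(total) * _EPS:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gamma_q_contfrac(a: float, x: float) -> float:
    """Upper regularized incomplete gamma Q(a, x) by Lentz continued
    fraction; for x >= a + 1."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, _MAX_ITER + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


def _gamma_q(a: float, x: float) -> float:
    if x == 0.0:
        return 1.0
    if x < a + 1.0:
        # series converges fast here and Q = 1 - P loses no precision,
        # because Q is bounded away from 0 in this regime
        return 1.0 - _gamma_p_series(a, x)
    return _gamma_q_contfrac(a, x)


def chisq_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability P(X >= x) for a chi-square variable with *df*
    degrees of freedom, i.e. Q(df/2, x/2).

    Monotone non-increasing in x; equals 1 at x = 0.
    """
    if x < 0:
        raise ValueError(f"chi-square statistic must be nonnegative, got {x}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return _gamma_q(df / 2.0, x / 2.0)


def format_p_value(p: float) -> str:
    """Render a p-value to 3 significant digits, flooring at 1e-15.

    Below the floor the digits are numerical noise, so the value is reported
    as an inequality.
    """
    if p < P_VALUE_FLOOR:
        return "< 1e-15"
    return f"{p:.3g}"


@dataclass(frozen=True)
class ChiSquareResult:
    """Outcome of a chi-square goodness-of-fit test."""

    statistic: float
    df: int
    p_value: float
    observed: tuple[int, ...]
    expected: tuple[float, ...]

    @property
    def p_display(self) -> str:
        return format_p_value(self.p_value)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_display": self.p_display,
            "observed": list(self.observed),
            "expected": list(self.expected),
        }


def chi_square_uniform(observed: Sequence[int]) -> ChiSquareResult:
    """Test observed cell counts against a uniform expectation.

    Parameters
    ----------
    observed
        Nonnegative integer counts, one per cell (length >= 2).  For the
        chromosome analysis this is the length-20 vector of unique-mention
        totals.

    Raises
    ------
    ValueError
        If fewer than 2 cells, negative counts, or a zero total (the test
        is undefined with no observations).
    """
    obs = np.asarray(observed)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need a 1-D vector of at least 2 cell counts")
    if (obs < 0).any():
        raise ValueError("observed counts must be nonnegative")
    total = int(obs.sum())
    if total == 0:
        raise ValueError("chi-square test undefined for an all-zero count vector")
    k = len(obs)
    expected = total / k
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chisq_upper_tail(statistic, df),
        observed=tuple(int(o) for o in obs),
        expected=tuple([expected] * k),
    )
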