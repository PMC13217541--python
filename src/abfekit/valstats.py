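"""Correlation and regression statistics for protocol validation.

Pearson and Spearman coefficients between experimental and computed binding
free energies, Fisher-z confidence intervals, ordinary-least-squares
trendlines, and the correlation-vs-trajectory-length convergence table used
to pick a sampling budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RegressionLine",
    "pearson",
    "spearman",
    "fisher_ci",
    "linear_fit",
    "convergence_table",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of reported percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class RegressionLine:
    slope: float
    intercept: float


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x, y = _check_xy(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation; ties receive average ranks."""
    x, y = _check_xy(x, y)
    return float(stats.spearmanr(x, y).statistic)


def fisher_ci(r: float, n: int, level: float = 0.95,
              decimals: int | None = 3) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson coefficient.

    z = atanh(r), half-width = z*_{level}/√(n−3), bounds tanh(z ∓ hw).
    Bounds are rounded to ``decimals`` places (None for unrounded).
    """
    if n <= 3:
        raise ValueError("Fisher interval requires n > 3")
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = np.arctanh(r)
    half_width = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half_width), np.tanh(z + half_width)
    if decimals is not None:
        lo = round_half_away(lo, decimals)
        hi = round_half_away(hi, decimals)
    return float(lo), float(hi)


def correlation_with_ci(x, y, level: float = 0.95,
                        decimals: int | None = 3) -> CorrelationResult:
    x, y = _check_xy(x, y)
    r = pearson(x, y)
    lo, hi = fisher_ci(r, x.size, level, decimals)
    return CorrelationResult(r=r, n=x.size, ci_low=lo, ci_high=hi, level=level)


def linear_fit(x, y) -> RegressionLine:
    """Ordinary-least-squares trendline y = slope·x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 aligned points")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return RegressionLine(slope=float(res.slope), intercept=float(res.intercept))


def convergence_table(estimates_by_length: dict, experimental,
                      level: float = 0.95,
                      decimals: int | None = 3) -> list[dict]:
    """Correlation vs trajectory length, one row per sampling length.

    ``estimates_by_length`` maps a length label (e.g. ns) to a ΔG vector
    aligned with ``experimental``.
    """
    experimental = np.asarray(experimental, dtype=float)
    rows = []
    for length in sorted(estimates_by_length):
        computed = np.asarray(estimates_by_length[length], dtype=float)
        if computed.size != experimental.size:
            raise ValueError(
                f"length {length}: {computed.size} estimates vs "
                f"{experimental.size} experimental values")
        res = correlation_with_ci(experimental, computed, level, decimals)
        rows.append({"length": length, "r": res.r, "n": res.n,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    return rows
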