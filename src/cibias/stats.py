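"""Statistics for intersexual fitness correlations.

The central quantity is the intersexual correlation for fitness, ``r_mf``:
the Pearson product-moment correlation between male and female fitness
measured on the same set of genotypes.  Strongly negative values are the
conventional signature of intralocus sexual conflict.  This module provides
that correlation with its t-based significance test, the companion OLS slope
and standard error, a t test for comparing two regression slopes, sign and
significance tallies over replicate correlations, a Pearson chi-square
independence test, and an exact binomial sign test.

All p-values are two-tailed.  Distribution functions come from
:mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "SlopeComparison",
    "CorrelationTallies",
    "DegenerateDataError",
    "pearson_rmf",
    "compare_slopes",
    "tally_correlations",
    "chi_square_independence",
    "binomial_sign_test",
]


class DegenerateDataError(ValueError):
    """Raised when a correlation is undefined (zero variance in an input)."""


@dataclass(frozen=True)
class CorrelationResult:
    """One male-vs-female correlation/regression.

    Attributes
    ----------
    r : float
        Pearson correlation, in [-1, 1].
    t_stat : float
        ``r * sqrt(n - 2) / sqrt(1 - r**2)``; signed like ``r``.
    df : int
        Degrees of freedom, ``n - 2``.
    p_two_tailed : float
        Two-tailed p from the t distribution with ``df`` degrees of freedom.
    slope : float
        OLS slope of the second (female) variable on the first (male).
    slope_se : float
        Standard error of that slope.
    n : int
        Number of paired observations.
    """

    r: float
    t_stat: float
    df: int
    p_two_tailed: float
    slope: float
    slope_se: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_tailed < alpha


@dataclass(frozen=True)
class SlopeComparison:
    """t test for the difference between two independent regression slopes."""

    b1: float
    b2: float
    se1: float
    se2: float
    t_stat: float
    df: int
    p_two_tailed: float


@dataclass(frozen=True)
class CorrelationTallies:
    """Sign and significance counts over a batch of correlations."""

    n_positive: int
    n_negative: int
    n_sig_positive: int
    n_sig_negative: int
    n_undefined: int = 0

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative + self.n_undefined


def _as_float_vector(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_rmf(
    male_values: Sequence[float], female_values: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between male and female fitness, with significance.

    Parameters
    ----------
    male_values, female_values : sequence of float
        Paired per-genotype fitness values; equal length ``n >= 3`` and
        nonzero variance in each.

    Returns
    -------
    CorrelationResult
        ``r``, its t statistic on ``n - 2`` df, the two-tailed p, and the
        OLS slope (and SE) of female fitness on male fitness.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, or length mismatch.
    DegenerateDataError
        Either vector has zero variance (the correlation is undefined).
    """
    x = _as_float_vector(male_values, "male_values")
    y = _as_float_vector(female_values, "female_values")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} male vs {y.size} female values")
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to estimate a correlation, got {n}")

    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0:
        raise DegenerateDataError("male_values have zero variance; r is undefined")
    if syy == 0.0:
        raise DegenerateDataError("female_values have zero variance; r is undefined")
    sxy = float(xd @ yd)

    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 2

    slope = sxy / sxx
    # residual variance of the regression of y on x
    rss = syy - slope * sxy
    slope_se = math.sqrt(max(rss, 0.0) / df / sxx)

    if abs(r) >= 1.0:
        t_stat = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t_stat = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return CorrelationResult(
        r=r, t_stat=t_stat, df=df, p_two_tailed=p, slope=slope, slope_se=slope_se, n=n
    )


def compare_slopes(
    b1: float, se1: float, n1: int, b2: float, se2: float, n2: int
) -> SlopeComparison:
    """Compare two independent regression slopes.

    ``t = (b1 - b2) / sqrt(se1**2 + se2**2)`` on ``n1 + n2 - 4`` degrees of
    freedom (two slopes and two intercepts estimated).

    If both standard errors are zero the statistic degenerates: equal slopes
    give ``t = 0``; unequal slopes give a signed infinite ``t`` with ``p = 0``
    (reported explicitly rather than raising, so batch callers can filter).
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("slope standard errors must be non-negative")
    if n1 < 3 or n2 < 3:
        raise ValueError("each regression needs at least 3 points")
    df = n1 + n2 - 4
    denom = math.hypot(se1, se2)
    if denom == 0.0:
        t_stat = 0.0 if b1 == b2 else math.copysign(math.inf, b1 - b2)
        p = 1.0 if b1 == b2 else 0.0
    else:
        t_stat = (b1 - b2) / denom
        p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    return SlopeComparison(
        b1=b1, b2=b2, se1=se1, se2=se2, t_stat=t_stat, df=df, p_two_tailed=p
    )


def tally_correlations(
    results: Iterable[CorrelationResult | None], alpha: float = 0.05
) -> CorrelationTallies:
    """Count correlations by sign and two-tailed significance at ``alpha``.

    ``r == 0`` (a measure-zero event for continuous data) counts as positive.
    ``None`` entries — replicates whose correlation was undefined — are
    skipped and reported in ``n_undefined``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n_pos = n_neg = n_sig_pos = n_sig_neg = n_undef = 0
    for res in results:
        if res is None:
            n_undef += 1
            continue
        sig = res.p_two_tailed < alpha
        if res.r >= 0:
            n_pos += 1
            n_sig_pos += sig
        else:
            n_neg += 1
            n_sig_neg += sig
    return CorrelationTallies(
        n_positive=n_pos,
        n_negative=n_neg,
        n_sig_positive=n_sig_pos,
        n_sig_negative=n_sig_neg,
        n_undefined=n_undef,
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction. ``df = (rows - 1) * (cols - 1)``.

    Returns ``(chi2, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError(f"contingency table must be 2-dimensional, got {obs.ndim}")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"table must be at least 2x2, got {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} of the contingency table is all zeros")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} of the contingency table is all zeros")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def binomial_sign_test(
    k: int, n: int, p0: float = 0.5
) -> tuple[float, float]:
    """Normal-approximation z and exact two-sided p for a binomial sign test.

    ``z = (k - n*p0) / sqrt(n*p0*(1 - p0))`` with no continuity correction.
    The exact two-sided p sums every binomial point mass not exceeding the
    mass at ``k`` (the "minimum-likelihood" two-sided test).

    Returns ``(z, p_exact_two_sided)``.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    z = (k - n * p0) / math.sqrt(n * p0 * (1.0 - p0))
    p = float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    return z, p
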