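"""Nonparametric statistics shared by the flow-cytometry and single-cell pipelines.

The statistics here (Mann-Whitney U, Pearson chi-squared tests, Spearman rank
correlation, Bonferroni adjustment, robust median/MAD summaries) are authored
in this module so that each can be validated against brute-force enumeration
oracles in the test suite.  SciPy is used only for reference distribution
functions (normal, chi-squared, Student t survival functions) and midrank
computation, never for the test logic itself.

Conventions
-----------
* ``mann_whitney_u`` reports the U statistic of the *first* sample
  (number of (x, y) pairs with x > y, counting ties as 1/2).  Small tie-free
  samples are handled by exact enumeration of the U null distribution;
  otherwise a normal approximation with tie and continuity corrections is
  used.
* Two-sided exact p-values are ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
* Spearman p-values use the t approximation with ``n - 2`` degrees of
  freedom by default; an exact permutation branch is available for small
  samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "RobustSummary",
    "mann_whitney_u",
    "chi_squared_gof",
    "chi_squared_independence",
    "spearman_corr",
    "bonferroni_adjust",
    "robust_summaries",
]

Alternative = Literal["two_sided", "less", "greater"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (U for Mann-Whitney, Pearson X² for the
        chi-squared tests).
    p_value : float
        In [0, 1].
    method : str
        ``"exact"`` when the null distribution was enumerated,
        ``"normal_approx"`` for the large-sample Mann-Whitney branch,
        ``"chi2"`` for Pearson chi-squared tests.
    n1, n2 : int
        Sample sizes (for goodness-of-fit tests ``n1`` is the total count
        and ``n2`` the number of categories; for independence tests the
        table dimensions).
    """

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of labelings of ``n1 + n2`` distinct values per U value.

    ``_u_counts(n1, n2)[u]`` is the number of ways to choose which ``n1`` of
    the pooled ranks belong to x such that U(x) == u.  Recursion on whether
    the largest pooled value belongs to x (then it beats all n2 y's) or to y.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    with_x = _u_counts(n1 - 1, n2)
    with_y = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(with_x):
        out[u + n2] += c
    for u, c in enumerate(with_y):
        out[u] += c
    return tuple(out)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two_sided",
    exact_limit: int = 16,
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact p by full enumeration of the U null distribution when
    ``n1 + n2 <= exact_limit`` and the pooled sample is tie-free; otherwise
    the normal approximation with tie correction and a 0.5 continuity
    correction.

    Parameters
    ----------
    x, y : sequences of real values, both non-empty.
    alternative : "two_sided" | "less" | "greater"
        ``"less"`` tests whether x is stochastically smaller than y.
    exact_limit : int
        Largest pooled size for which the exact branch is attempted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if (n1 + n2) <= exact_limit and not has_ties:
        counts = np.asarray(_u_counts(n1, n2), dtype=float)
        total = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / total
        sf = counts[ui:].sum() / total
        if alternative == "less":
            p = cdf
        elif alternative == "greater":
            p = sf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(u, float(p), "exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_sizes = np.unique(pooled, return_counts=True)
    tie_term = float((tie_sizes**3 - tie_sizes).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0.0:  # every value tied with every other
        return TestResult(u, 1.0, "normal_approx", n1, n2)
    sd = math.sqrt(var)
    if alternative == "two_sided":
        z = max(abs(u - mu) - 0.5, 0.0) / sd
        p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = float(_sps.norm.sf(z))
    else:
        z = (u - mu + 0.5) / sd
        p = float(_sps.norm.cdf(z))
    return TestResult(u, p, "normal_approx", n1, n2)


def chi_squared_gof(
    observed: Sequence[float],
    expected_proportions: Sequence[float],
) -> TestResult:
    """Pearson chi-squared goodness-of-fit test.

    ``df = k - 1``; expected counts are ``sum(observed) * proportions``.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.ndim != 1 or obs.size != props.size:
        raise ValueError("observed and expected_proportions must be 1-D of equal length")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("sum of observed counts must be positive")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = total * props
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(_sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, p, "chi2", int(total), obs.size)


def chi_squared_independence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("every row and column total must be positive")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_sps.chi2.sf(stat, df))
    return TestResult(stat, p, "chi2", t.shape[0], t.shape[1])


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum()) * float((ry**2).sum()))
    if denom == 0.0:
        raise ValueError("constant input: Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def spearman_corr(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["approx", "exact"] = "approx",
    exact_limit: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation with midrank tie handling.

    Returns ``(rho, p)``.  ``rho`` is the Pearson correlation of midranks.
    With ``method="approx"`` the two-sided p uses the t approximation with
    ``n - 2`` df; ``method="exact"`` enumerates all permutations of one rank
    vector (only for ``n <= exact_limit``) and reports the fraction of
    permutations with ``|rho| >= |rho_observed|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman_corr requires length >= 3")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    rho = _rank_pearson(rx, ry)

    if method == "exact":
        if n > exact_limit:
            raise ValueError(f"exact Spearman p limited to n <= {exact_limit}")
        obs = abs(rho)
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_pearson(rx, ry[list(perm)])
            hits += abs(r) >= obs - 1e-12
            total += 1
        return rho, hits / total

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return rho, min(1.0, p)


def bonferroni_adjust(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)``, order preserving.

    ``m`` defaults to ``len(p)`` and must be at least that.
    """
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


@dataclass(frozen=True)
class RobustSummary:
    """Median/MAD quality-control summary over grouped measurements.

    ``mad`` is the scaled median absolute deviation of the pooled values
    around the grand median of the pool; ``madm`` is the scaled median
    absolute deviation of the per-unit medians around their own median.
    The scale constant defaults to 1.0 (descriptive use); 1.4826 makes both
    consistent for the normal distribution.
    """

    medians: Mapping[str, float]
    grand_median: float
    mad: float
    madm: float
    scale_constant: float = 1.0


def robust_summaries(
    groups: Mapping[str, Sequence[float]],
    scale_constant: float = 1.0,
) -> RobustSummary:
    """Per-unit medians plus grand median / MAD / MADM of a grouped sample."""
    if not groups:
        raise ValueError("robust_summaries requires at least one unit")
    medians: dict[str, float] = {}
    pooled_parts = []
    for unit, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"unit {unit!r} has no values")
        medians[str(unit)] = float(np.median(v))
        pooled_parts.append(v)
    pooled = np.concatenate(pooled_parts)
    grand = float(np.median(pooled))
    mad = scale_constant * float(np.median(np.abs(pooled - grand)))
    med_arr = np.asarray(list(medians.values()))
    madm = scale_constant * float(np.median(np.abs(med_arr - np.median(med_arr))))
    return RobustSummary(medians, grand, mad, madm, scale_constant)
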