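"""Nonparametric comparison statistics used throughout the cohort analysis.

The three tests here — Fisher's exact test, the Mann–Whitney U test and the
Kruskal–Wallis test — are implemented directly rather than delegated, because
the analysis pins specific conventions (two-sided probability-mass Fisher
p-values computed in log space, exact small-sample Mann–Whitney tails by
enumeration of the rank distribution, midrank tie handling) that must be
stable and testable against brute-force oracles.  SciPy's implementations are
used as independent cross-checks in the test suite, never as the computation.

No multiple-testing correction is applied by default: each test returns a raw
two-sided p-value and the caller decides what to do with it.  Significance in
the pipeline report is flagged at p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm, rankdata

log = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "fisher_exact",
    "mann_whitney_u",
    "kruskal_wallis",
    "median_iqr",
    "bonferroni",
]

#: relative tolerance when comparing hypergeometric table probabilities in the
#: two-sided Fisher sum; tables whose probability is within this factor of the
#: observed table's are counted as "at least as extreme".
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table: rows are groups, columns outcome +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"table cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_hypergeom_pmf(k: np.ndarray, n: int, row1: int, col1: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(total n, row1 draws, col1 successes)."""
    return (
        gammaln(row1 + 1)
        - gammaln(k + 1)
        - gammaln(row1 - k + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - k + 1)
        - gammaln(n - row1 - col1 + k + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )


def fisher_exact(table: TwoByTwo | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Conditions on both margins; the two-sided p-value is the sum of
    hypergeometric probabilities of every table with the same margins whose
    probability does not exceed that of the observed table (up to a 1 + 1e-7
    relative tolerance guarding against floating-point ties).  All
    probabilities are computed in log space, so tables far into the tail do
    not underflow to zero.

    Returns a p-value in (0, 1].
    """
    if not isinstance(table, TwoByTwo):
        table = TwoByTwo(*table)
    n = table.total
    row1 = table.a + table.b
    col1 = table.a + table.c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n, row1, col1)
    log_obs = _log_hypergeom_pmf(np.array([table.a]), n, row1, col1)[0]
    keep = logp <= log_obs + math.log1p(_FISHER_REL_TOL)
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def _mwu_exact_cdf_counts(n: int, m: int) -> np.ndarray:
    """Counts of rank assignments giving each U value, U in 0..n*m.

    Classic recurrence c(u; n, m) = c(u - m; n - 1, m) + c(u; n, m - 1),
    equivalent to enumerating all C(n+m, n) placements of the first sample's
    ranks (valid only without ties).
    """
    counts = np.zeros(n * m + 1, dtype=float)
    counts[0] = 1.0
    # build the generating function prod_{i=1..n} (1 - x^(m+i)) / (1 - x^i)
    # via iterative polynomial updates; equivalent to the recurrence above.
    for i in range(1, n + 1):
        new = np.zeros_like(counts)
        # multiply by 1/(1-x^i): prefix-sum with stride i
        for u in range(len(counts)):
            new[u] = counts[u] + (new[u - i] if u >= i else 0.0)
        # multiply by (1 - x^(m+i))
        shifted = np.zeros_like(new)
        shifted[m + i:] = new[: len(new) - (m + i)] if m + i < len(new) else 0.0
        counts = new - shifted
    return counts


def mann_whitney_u(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    U is computed from midranks of the pooled sample (so ties are handled).
    The p-value is exact — from the enumerated null distribution of U — when
    ``mode`` is ``"exact"``, or under ``"auto"`` when n*m <= 400 and the
    pooled data contain no ties.  Otherwise a normal approximation with tie
    correction and a 0.5 continuity correction is used.  Exact mode refuses
    ties and falls back to the normal approximation with a log message.

    Returns ``(U, p)`` where U is the first sample's statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"auto", "exact", "normal"}:
        raise ValueError(f"unknown mode {mode!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n].sum())
    u = r1 - n * (n + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    want_exact = mode == "exact" or (mode == "auto" and n * m <= 400)
    if want_exact and has_ties:
        if mode == "exact":
            log.info("ties present: exact Mann-Whitney unavailable, using normal approximation")
        want_exact = False

    if want_exact:
        counts = _mwu_exact_cdf_counts(n, m)
        total = counts.sum()
        k = int(round(u))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)

    mean_u = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var_u <= 0:  # all observations identical
        return u, 1.0
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return u, p


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H test across two or more groups.

    H is computed from pooled midranks with the standard tie correction; the
    p-value comes from the chi-square distribution with k-1 degrees of
    freedom.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(samples)
    big_n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for s in samples:
        rsum = ranks[start : start + s.size].sum()
        h += rsum**2 / s.size
        start += s.size
    h = 12.0 / (big_n * (big_n + 1)) * h - 3 * (big_n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    correction = 1.0 - tie_term / (big_n**3 - big_n)
    if correction == 0.0:  # every observation equal
        return 0.0, 1.0
    h /= correction
    p = float(chi2.sf(h, df=len(samples) - 1))
    return float(h), p


def median_iqr(values) -> tuple[float, float, float]:
    """Median and interquartile bounds (median, q25, q75).

    Uses linear interpolation between order statistics — the same quantile
    convention as :func:`t1dgrs.calibration.centile` — so summary tables and
    threshold calibration agree on what a quantile means.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr of empty sample")
    med, q25, q75 = np.quantile(values, [0.5, 0.25, 0.75])
    return float(med), float(q25), float(q75)


def bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Optional Bonferroni family-wise correction (off by default everywhere).

    Returns, for each p-value, whether it stays significant after multiplying
    by the number of tests.  The main pipeline deliberately reports raw
    p-values; this helper exists for users who want the corrected view.
    """
    ps = list(p_values)
    k = len(ps)
    return [p * k < alpha for p in ps]
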