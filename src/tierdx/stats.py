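"""Diagnostic yields and paired-proportion tests.

Yields are evaluated on the whole cohort at every tier (not on the shrinking
pool of still-undiagnosed patients), which is what makes the tier indicators
a set of paired binary outcomes on the same n subjects: Cochran's Q is the
omnibus test for equality of the k paired proportions and McNemar's test
(no continuity correction) the post-hoc pairwise comparison.  Pairwise
comparisons use the MARGINAL tier indicators — diagnosed *at* tier j —
not the cumulative ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortValidationError, OutcomeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "YieldTable",
    "CochranQResult",
    "PairedTestResult",
    "yield_table",
    "cochran_q",
    "mcnemar_test",
    "pairwise_mcnemar",
    "format_percent",
]


@dataclass(frozen=True)
class YieldTable:
    """Marginal and cumulative diagnostic yields per tier."""

    n: int
    tier_labels: tuple[str, ...]
    marginal_counts: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.marginal_counts)

    @property
    def marginal_yields(self) -> tuple[float, ...]:
        return tuple(d / self.n for d in self.marginal_counts)

    @property
    def cumulative_counts(self) -> tuple[int, ...]:
        return tuple(np.cumsum(self.marginal_counts).tolist())

    @property
    def cumulative_yields(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.cumulative_counts)

    @property
    def overall_count(self) -> int:
        return self.cumulative_counts[-1]

    @property
    def overall_yield(self) -> float:
        """Fraction of the cohort diagnosed by the final tier."""
        return self.overall_count / self.n

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tier": list(self.tier_labels),
                "marginal_count": list(self.marginal_counts),
                "marginal_yield": list(self.marginal_yields),
                "cumulative_count": list(self.cumulative_counts),
                "cumulative_yield": list(self.cumulative_yields),
            }
        )


def yield_table(matrix: OutcomeMatrix) -> YieldTable:
    """Tier-wise diagnostic yields of an outcome matrix."""
    if matrix.n == 0:
        raise CohortValidationError("cannot compute yields on an empty matrix")
    return YieldTable(
        n=matrix.n,
        tier_labels=matrix.tier_labels,
        marginal_counts=tuple(int(c) for c in matrix.column_sums),
    )


def format_percent(proportion: float, decimals: int = 1, truncate: bool = False) -> str:
    """Format a proportion as a percentage string.

    Rounds half-up to ``decimals`` places by default; with ``truncate=True``
    the value is floored at the last kept digit instead (both conventions
    occur in published summaries of the same table).  A trailing ``.0`` is
    dropped so integer-precision values print as integers.
    """
    q = Decimal(1).scaleb(-decimals)
    mode = ROUND_DOWN if truncate else ROUND_HALF_UP
    value = (Decimal(repr(proportion)) * 100).quantize(q, rounding=mode)
    text = format(value.normalize(), "f")
    return text


@dataclass(frozen=True)
class CochranQResult:
    """Cochran's Q omnibus test over k paired binary indicators."""

    statistic: float
    df: int
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def cochran_q(matrix: OutcomeMatrix) -> CochranQResult:
    """Cochran's Q test for equality of the k marginal tier proportions.

    Q = (k-1) * [k * sum_j C_j^2 - (sum_j C_j)^2] / [k * sum_i R_i - sum_i R_i^2]
    with C_j the column sums and R_i the row sums of the marginal matrix;
    the p-value is the upper chi-square tail at k-1 degrees of freedom.
    A matrix whose rows are all concordant (denominator 0) is degenerate:
    Q = 0, p = 1, with a logged warning.
    """
    m = matrix.marginal
    k = matrix.k
    if k < 2:
        raise CohortValidationError("Cochran's Q requires at least two tiers")
    C = m.sum(axis=0).astype(np.float64)
    R = m.sum(axis=1).astype(np.float64)
    denom = k * R.sum() - (R**2).sum()
    df = k - 1
    if denom == 0:
        logger.warning("Cochran's Q degenerate: all rows concordant; Q=0, p=1")
        return CochranQResult(statistic=0.0, df=df, p_value=1.0, degenerate=True)
    q = (k - 1) * (k * (C**2).sum() - C.sum() ** 2) / denom
    p = float(sps.chi2.sf(q, df))
    return CochranQResult(statistic=float(q), df=df, p_value=p)


@dataclass(frozen=True)
class PairedTestResult:
    """McNemar comparison of two paired binary indicators.

    ``b`` counts patients positive at the first tier only, ``c`` the
    reverse; concordant pairs carry no information and are discarded.
    """

    tier_pair: tuple[int, int]
    b: int
    c: int
    statistic: float
    df: int
    p_value: float
    method: str
    significant: bool | None = None


def mcnemar_test(
    matrix: OutcomeMatrix, j: int, m: int, exact: bool = False
) -> PairedTestResult:
    """McNemar's test between the marginal indicators of tiers ``j`` and ``m``.

    The default is the asymptotic chi-square form without continuity
    correction, statistic (b-c)^2 / (b+c) on 1 df; ``exact=True`` instead
    uses the two-sided exact binomial test of b successes in b+c trials at
    p=1/2.  When b+c = 0 there is no discordance and the test returns
    statistic 0, p = 1.  Tiers are 1-based.
    """
    if j == m:
        raise CohortValidationError("tiers to compare must differ")
    k = matrix.k
    if not (1 <= j <= k and 1 <= m <= k):
        raise CohortValidationError(f"tiers must lie in 1..{k}")
    x = matrix.marginal[:, j - 1]
    y = matrix.marginal[:, m - 1]
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if b + c == 0:
        stat, p = 0.0, 1.0
        method = "mcnemar-exact" if exact else "mcnemar-chi2"
    elif exact:
        stat = float(min(b, c))
        p = float(sps.binomtest(b, b + c, 0.5).pvalue)
        method = "mcnemar-exact"
    else:
        stat = (b - c) ** 2 / (b + c)
        p = float(sps.chi2.sf(stat, 1))
        method = "mcnemar-chi2"
    return PairedTestResult(
        tier_pair=(j, m), b=b, c=c, statistic=stat, df=1, p_value=p, method=method
    )


def pairwise_mcnemar(
    matrix: OutcomeMatrix, alpha: float = 0.05, exact: bool = False
) -> list[PairedTestResult]:
    """All unordered tier-pair McNemar tests, in lexicographic pair order.

    Each result is flagged significant iff its p-value is at most ``alpha``.
    No multiplicity correction is applied across the pairs.
    """
    if not 0 < alpha < 1:
        raise CohortValidationError("alpha must lie strictly between 0 and 1")
    results = []
    for j in range(1, matrix.k + 1):
        for m in range(j + 1, matrix.k + 1):
            r = mcnemar_test(matrix, j, m, exact=exact)
            results.append(
                PairedTestResult(
                    tier_pair=r.tier_pair,
                    b=r.b,
                    c=r.c,
                    statistic=r.statistic,
                    df=r.df,
                    p_value=r.p_value,
                    method=r.method,
                    significant=bool(r.p_value <= alpha),
                )
            )
    return results
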