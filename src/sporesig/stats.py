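"""Exact and rank statistics used throughout the pipeline.

Fisher's exact test is computed by direct integer enumeration of the
hypergeometric support (all 2x2 tables with the observed margins), which keeps
p-values exact for the table sizes this pipeline produces and makes tie
handling in the two-sided test unambiguous: a table enters the two-sided sum
iff its (integer) hypergeometric weight is <= the observed table's weight.

Rank and t statistics wrap scipy; multiple-testing adjustments wrap
statsmodels. The Wilcoxon rank-sum test uses the exact null distribution when
both samples have <= 20 observations and no ties are present, and the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import ContingencyTable, TestResult

__all__ = [
    "fisher_exact",
    "hochberg",
    "benjamini_hochberg",
    "ranksum",
    "welch_t",
    "spearman",
    "PermutationEngine",
]

EXACT_RANKSUM_MAX_N = 20


def fisher_exact(table: ContingencyTable, sided: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    ``sided``: ``"two-sided"``, ``"greater"`` (association enriching cell a),
    or ``"less"``. The statistic reported is the sample odds ratio
    (``inf``/``nan`` for degenerate margins).
    """
    if sided not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d  # row margins
    c1 = a + c  # first column margin
    n = table.total

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total_w = sum(weights)
    w_obs = weights[a - lo]

    if sided == "greater":
        num = sum(weights[k - lo] for k in range(a, hi + 1))
    elif sided == "less":
        num = sum(weights[k - lo] for k in range(lo, a + 1))
    else:
        num = sum(w for w in weights if w <= w_obs)
    # integer ratio -> float keeps full double precision
    p = num / total_w

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        statistic=odds, p_value=min(p, 1.0), sidedness=sided, method="fisher-exact"
    )


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values (FWER control), in input order."""
    p = _check_pvalues(p_values)
    return multipletests(p, method="simes-hochberg")[1]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (FDR control), in input order."""
    p = _check_pvalues(p_values)
    return multipletests(p, method="fdr_bh")[1]


def ranksum(
    x: Sequence[float], y: Sequence[float], sided: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test.

    Exact null distribution when both n <= 20 and there are no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sided]
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= EXACT_RANKSUM_MAX_N and y.size <= EXACT_RANKSUM_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=sided,
        method="wilcoxon-ranksum-exact" if exact else "wilcoxon-ranksum-normal",
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t needs >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: constant groups; t undefined, decide by the means
        equal = x.mean() == y.mean()
        return TestResult(
            statistic=0.0 if equal else math.inf,
            p_value=1.0 if equal else 0.0,
            sidedness="two-sided",
            method="welch-t",
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness="two-sided",
        method="welch-t",
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("spearman needs two equal-length samples with n >= 2")
    return float(sps.spearmanr(x, y).statistic)


class PermutationEngine:
    """Seeded permutation/subsampling engine; same seed -> identical draws."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    def equalized_fraction(
        self,
        larger: Sequence[float],
        smaller: Sequence[float],
        n_perm: int,
        statistic: Callable[[np.ndarray], float] = np.median,
    ) -> float:
        """Fraction of permutations where ``statistic`` of a size-matched
        subsample of ``larger`` exceeds ``statistic(smaller)``.

        Each permutation draws ``len(smaller)`` values from ``larger`` without
        replacement (strictly greater counts).
        """
        larger = np.asarray(larger, dtype=float)
        smaller = np.asarray(smaller, dtype=float)
        if larger.size < smaller.size:
            raise ValueError(
                f"cannot subsample {smaller.size} from {larger.size} values"
            )
        ref = statistic(smaller)
        hits = 0
        for _ in range(n_perm):
            sub = self._rng.choice(larger, size=smaller.size, replace=False)
            if statistic(sub) > ref:
                hits += 1
        return hits / n_perm

    def null_fraction(
        self,
        x: Sequence[float],
        y: Sequence[float],
        n_perm: int,
        statistic: Callable[[np.ndarray], float] = np.median,
    ) -> float:
        """Label-permutation null: fraction of permutations in which group 1's
        statistic exceeds group 2's after shuffling pooled labels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pooled = np.concatenate([x, y])
        hits = 0
        for _ in range(n_perm):
            perm = self._rng.permutation(pooled)
            if statistic(perm[: x.size]) > statistic(perm[x.size :]):
                hits += 1
        return hits / n_perm
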