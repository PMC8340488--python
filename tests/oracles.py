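"""Independent brute-force oracles used only by the tests.

Everything here is written from first principles (definitions, exhaustive
enumeration, naive loops) and never calls into the implementation paths it
checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def fisher_p_enumeration(a, b, c, d, sided="two-sided") -> Fraction:
    """Fisher's exact p by exhaustive enumeration over fixed margins,
    computed in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    obs = probs[a]
    if sided == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    if sided == "less":
        return sum(p for k, p in probs.items() if k <= a)
    return sum(p for p in probs.values() if p <= obs)


def hochberg_by_definition(pvals):
    """Step-up Hochberg adjusted p-values, straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):  # from the largest p down
        i = order[rank - 1]
        val = min(prev, (m - rank + 1) * p[i])
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


def bh_by_definition(pvals):
    """Benjamini-Hochberg q-values, straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, m * p[i] / rank)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


def ranksum_exact_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by enumerating all rank splits."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for subset in combinations(pooled, n1):
        w = sum(ranks[v] for v in subset)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def depth_vector_scatter(rows, length):
    """Naive per-row fill of a depth vector from (pos_1based, depth) rows."""
    vec = np.zeros(length, dtype=np.int64)
    for pos, depth in rows:
        vec[pos - 1] = depth
    return vec


def aitchison_contributions_naive(matrix):
    """Per-species beta-diversity shares by a naive double loop.

    ``matrix`` is species x samples, strictly positive (already
    zero-replaced). CLR is computed per sample by definition.
    """
    mat = np.asarray(matrix, dtype=float)
    n_species, n_samples = mat.shape
    clr_cols = []
    for j in range(n_samples):
        logs = np.log(mat[:, j])
        clr_cols.append(logs - logs.mean())
    shares = np.zeros(n_species)
    n_pairs = 0
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            sq = (clr_cols[i] - clr_cols[j]) ** 2
            if sq.sum() == 0:
                continue
            shares += sq / sq.sum()
            n_pairs += 1
    return shares / n_pairs


def stage_presence_count_naive(df, genes, genomes):
    """Nested-loop count of True cells over given genes x genomes."""
    count = 0
    for g in genomes:
        for gene in genes:
            if bool(df.loc[g, gene]):
                count += 1
    return count


def equalized_fraction_exhaustive(sf_values, fsf_values):
    """Exact fraction of subsets of SF values (size n_FSF) whose median
    exceeds the FSF median; enumerates all C(n_SF, n_FSF) subsets."""
    sf = list(sf_values)
    k = len(fsf_values)
    ref = float(np.median(fsf_values))
    hits = total = 0
    for subset in combinations(sf, k):
        total += 1
        if np.median(subset) > ref:
            hits += 1
    return hits / total
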