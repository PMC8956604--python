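"""Independent brute-force oracles used to cross-check the implementation.

Each function here deliberately avoids the code path it validates: the
rank-aggregation oracle sums binomial tails directly, the ssGSEA oracle is a
plain double loop over ordered genes, the hypergeometric oracle enumerates
draws combinatorially, and the pruning/promoter oracles are all-pairs scans.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats


def rho_binomial_tail(ranks, alpha: float) -> float:
    """alpha-RRA score via the summed binomial tail P(Bin(k, r_j) >= j)."""
    r = sorted(ranks)
    k = len(r)
    best = 1.0
    for j, rj in enumerate(r, start=1):
        if rj > alpha:
            continue
        tail = sum(
            math.comb(k, i) * rj**i * (1 - rj) ** (k - i) for i in range(j, k + 1)
        )
        best = min(best, tail)
    return best


def ssgsea_es_bruteforce(expr: pd.Series, signature: set[str], weight: float) -> float:
    """Enrichment score by direct iteration over the ranked gene list."""
    ranks = pd.Series(stats.rankdata(expr.to_numpy(), method="average"), index=expr.index)
    order = sorted(expr.index, key=lambda g: (-ranks[g], g))
    in_sum = sum(abs(ranks[g]) ** weight for g in order if g in signature)
    n = len(order)
    m = sum(1 for g in order if g in signature)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for g in order:
        if g in signature:
            cum_in += abs(ranks[g]) ** weight / in_sum
        else:
            cum_out += 1.0 / (n - m)
        es += cum_in - cum_out
    return es


def hypergeom_upper_tail_enumeration(
    candidates: set[str], pathway: set[str], universe: set[str]
) -> float:
    """P(X >= k) by enumerating every possible candidate draw from the universe."""
    uni = sorted(universe)
    n = len(candidates & universe)
    k_obs = len(candidates & pathway & universe)
    hits = 0
    total = 0
    for draw in itertools.combinations(uni, n):
        total += 1
        if len(set(draw) & pathway) >= k_obs:
            hits += 1
    return hits / total


def prune_bruteforce(
    ordered_ids, member_sets: dict[str, set[str]], threshold: float, retained_only: bool
) -> list[bool]:
    """All-ordered-pairs redundancy filter over FDR-sorted pathway ids."""
    flags: list[bool] = []
    for i, sid in enumerate(ordered_ids):
        a = member_sets[sid]
        keep = True
        for j in range(i):
            if retained_only and not flags[j]:
                continue
            b = member_sets[ordered_ids[j]]
            if a and len(a & b) / len(a) > threshold:
                keep = False
        flags.append(keep)
    return flags


def promoter_calls_bruteforce(peaks: pd.DataFrame, tss: pd.DataFrame,
                              upstream: int = 2000, downstream: int = 500) -> set[str]:
    """All-pairs closed-interval check of peaks against promoter windows."""
    called = set()
    for t in tss.itertuples(index=False):
        if t.strand == "+":
            lo, hi = t.pos - upstream, t.pos + downstream
        else:
            lo, hi = t.pos - downstream, t.pos + upstream
        for p in peaks.itertuples(index=False):
            if p.chrom == t.chrom and p.start <= hi and p.end >= lo:
                called.add(t.gene)
                break
    return called


def gini_pairwise(values) -> float:
    """Gini by the literal double sum over all ordered pairs."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean()))
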