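"""Guide-level enrichment scoring and robust rank aggregation.

Turns sgRNA counts into per-replicate gene scores: sample normalization,
log2 fold change of the selected arm over its paired unselected control,
normalized guide ranks, and a gene-level alpha-RRA score (minimum
order-statistic tail probability over the gene's best guide ranks) with a
permutation p-value drawn from pooled ranks per gene size class.  Also the
Gini coefficient used to track library distribution skew across selection
rounds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_counts",
    "compute_sgrna_lfc",
    "rra_rho_from_ranks",
    "rra_gene_score",
    "rank_genes",
    "collapse_to_genes",
    "gini",
]

_META_COLS = ("guide_id", "target_id", "gene_symbol")


def _split_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    meta = [c for c in _META_COLS if c in counts.columns]
    if "guide_id" not in meta:
        raise ValueError("count table must carry a guide_id column")
    value_cols = [c for c in counts.columns if c not in meta]
    return counts[meta], value_cols


def normalize_counts(counts: pd.DataFrame, method: str = "median_ratio") -> pd.DataFrame:
    """Normalize sample columns for library size.

    ``total_count`` scales every sample to the mean library size.
    ``median_ratio`` divides each sample by the median, over guides with
    all-positive rows, of count / geometric row mean (the size-factor
    estimator standard in count-based sequencing analyses).  Either method
    preserves the ordering of guides within a sample.
    """
    meta, value_cols = _split_counts(counts)
    x = counts[value_cols].to_numpy(dtype=float)
    if method == "total_count":
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every sample needs a positive total count")
        factors = totals.mean() / totals
    elif method == "median_ratio":
        positive = (x > 0).all(axis=1)
        if not positive.any():
            raise ValueError(
                "median_ratio requires at least one guide with positive counts in "
                "every sample; use method='total_count'"
            )
        logref = np.log(x[positive]).mean(axis=1)
        size = np.exp(np.median(np.log(x[positive]) - logref[:, None], axis=0))
        factors = 1.0 / size
    else:
        raise ValueError(f"unknown normalization method: {method}")
    out = meta.copy()
    out[value_cols] = x * factors[None, :]
    return out


def compute_sgrna_lfc(
    normalized: pd.DataFrame,
    selected_sample: str,
    control_sample: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2 fold change and normalized enrichment ranks.

    ``lfc = log2((selected + pc) / (control + pc))``.  ``normalized_rank``
    ranks guides by descending LFC (rank 1/N = most enriched, midranks for
    ties), so it lies in (0, 1].
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for s in (selected_sample, control_sample):
        if s not in normalized.columns:
            raise KeyError(f"sample not found in count table: {s}")
    meta, _ = _split_counts(normalized)
    sel = normalized[selected_sample].to_numpy(dtype=float)
    ctl = normalized[control_sample].to_numpy(dtype=float)
    lfc = np.log2((sel + pseudocount) / (ctl + pseudocount))
    n = len(lfc)
    ranks = stats.rankdata(-lfc, method="average") / n
    out = meta.copy()
    out["control"] = ctl
    out["selected"] = sel
    out["lfc"] = lfc
    out["normalized_rank"] = ranks
    return out


def rra_rho_from_ranks(ranks: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized alpha-RRA score for a (m, k) array of normalized ranks.

    For each row with sorted ranks r(1) <= ... <= r(k), guides with
    r(j) > alpha are skipped and rho = min over retained j of
    P(Beta(j, k-j+1) <= r(j)); rows with no retained guide score 1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    r = np.sort(np.atleast_2d(np.asarray(ranks, dtype=float)), axis=1)
    k = r.shape[1]
    j = np.arange(1, k + 1)
    cdf = stats.beta.cdf(r, j, k - j + 1)
    cdf = np.where(r <= alpha, cdf, np.inf)
    rho = cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def rra_gene_score(
    enrichment: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
    group_col: str = "gene_symbol",
) -> pd.DataFrame:
    """Aggregate guide ranks into gene scores with a permutation null.

    The null for a gene with k guides draws k ranks (with replacement) from
    the pooled normalized-rank list, once per gene size class;
    ``perm_p = (1 + #{null rho <= observed rho}) / (1 + n_permutations)`` so
    p is floored above 0.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_permutations < 100:
        logger.warning("n_permutations=%d is small; permutation p-values will be coarse",
                       n_permutations)
    if group_col not in enrichment.columns:
        raise KeyError(f"enrichment table lacks grouping column {group_col!r}")

    pooled = enrichment["normalized_rank"].to_numpy(dtype=float)
    lfc = enrichment["lfc"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    codes, labels = pd.factorize(enrichment[group_col], sort=True)
    n_groups = len(labels)
    sizes = np.bincount(codes, minlength=n_groups)
    mean_lfc = np.bincount(codes, weights=lfc, minlength=n_groups) / sizes

    order = np.argsort(codes, kind="stable")
    split_ranks = np.split(pooled[order], np.cumsum(sizes)[:-1])

    rho = np.empty(n_groups)
    perm_p = np.empty(n_groups)
    for k in np.unique(sizes):
        members = np.flatnonzero(sizes == k)
        obs = np.vstack([split_ranks[i] for i in members])
        rho_obs = rra_rho_from_ranks(obs, alpha)
        null_ranks = rng.choice(pooled, size=(n_permutations, k), replace=True)
        rho_null = np.sort(rra_rho_from_ranks(null_ranks, alpha))
        hits = np.searchsorted(rho_null, rho_obs, side="right")
        rho[members] = rho_obs
        perm_p[members] = (1.0 + hits) / (1.0 + n_permutations)

    return pd.DataFrame(
        {
            group_col: labels,
            "n_guides": sizes,
            "mean_lfc": mean_lfc,
            "rho": rho,
            "perm_p": perm_p,
        }
    )


def _score_sort(scores: pd.DataFrame, group_col: str) -> pd.DataFrame:
    tmp = scores.assign(_neg_lfc=-scores["mean_lfc"])
    tmp = tmp.sort_values(
        ["perm_p", "rho", "_neg_lfc", group_col],
        ascending=[True, True, True, True],
        kind="mergesort",
    )
    return tmp.drop(columns="_neg_lfc")


def rank_genes(scores: pd.DataFrame, group_col: str = "gene_symbol") -> pd.DataFrame:
    """Total order by (perm_p asc, rho asc, mean_lfc desc, symbol asc).

    Returns the table sorted with a 1-based gap-free ``gene_rank`` column;
    deterministic under permutation of the input rows.
    """
    out = _score_sort(scores, group_col).reset_index(drop=True)
    out["gene_rank"] = np.arange(1, len(out) + 1)
    return out


def collapse_to_genes(target_scores: pd.DataFrame, gene_map: pd.Series | dict) -> pd.DataFrame:
    """Collapse target-level (isoform) scores to gene symbols.

    Each gene keeps its best target: minimum perm_p, ties broken by rho then
    mean_lfc (descending) then target id.  ``gene_map`` maps target_id ->
    gene_symbol.
    """
    mapping = pd.Series(gene_map)
    tbl = target_scores.copy()
    unknown = sorted(set(tbl["target_id"]) - set(mapping.index))
    if unknown:
        raise KeyError(f"targets missing from gene map: {unknown[:5]}")
    tbl["gene_symbol"] = tbl["target_id"].map(mapping)
    tbl = _score_sort(tbl, "target_id")
    best = tbl.drop_duplicates("gene_symbol", keep="first")
    agg = tbl.groupby("gene_symbol")["n_guides"].sum()
    best = best.drop(columns="target_id").set_index("gene_symbol")
    best["n_guides"] = agg
    return best.reset_index()


def gini(values) -> float:
    """Gini coefficient of a count vector: sum_ij |xi - xj| / (2 n^2 mu)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("gini requires a 1-d vector of length >= 2")
    if (x < 0).any():
        raise ValueError("gini is defined for non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero sample")
    xs = np.sort(x)
    n = len(xs)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))
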