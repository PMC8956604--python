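"""Hit calling over per-replicate gene rankings.

Implements the screen's own statistics: an empirical false-discovery rate
measured against a designated housekeeping negative-control gene set, the
top-fraction / minimum-replicate-overlap candidate rule (acute and chronic
replicates pooled into one list), and top-N replicate-overlap diagnostics.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["empirical_fdr", "select_candidates", "top_n_overlap"]


def empirical_fdr(scores: pd.DataFrame, controls: set[str]) -> pd.Series:
    """Per-gene empirical FDR against negative-control genes.

    ``fdr(g)`` is the fraction of control genes whose mean guide log2 fold
    change strictly exceeds gene g's.  Controls absent from the score table
    are dropped with a warning; with no control present this is an error.
    """
    genes = scores["gene_symbol"]
    present = sorted(set(controls) & set(genes))
    absent = sorted(set(controls) - set(genes))
    if absent:
        logger.warning("%d control genes absent from score table; dropped", len(absent))
    if not present:
        raise ValueError("no negative-control gene present in the score table")

    lfc = scores.set_index("gene_symbol")["mean_lfc"]
    ctrl = np.sort(lfc[present].to_numpy(dtype=float))
    values = lfc[genes].to_numpy(dtype=float)
    ties = np.isin(values, ctrl).sum()
    if ties > len(present):  # the controls themselves always tie with themselves
        logger.info("%d genes tie exactly with a control mean LFC", int(ties - len(present)))
    higher = len(ctrl) - np.searchsorted(ctrl, values, side="right")
    return pd.Series(higher / len(ctrl), index=genes.to_numpy(), name="empirical_fdr")


def select_candidates(
    rankings: list[pd.DataFrame],
    top_fraction: float = 0.01,
    min_replicates: int = 2,
    empirical_fdrs: list[pd.Series] | None = None,
) -> pd.DataFrame:
    """Genes ranked in the top fraction of at least ``min_replicates`` replicates.

    Per replicate the top set is genes with ``gene_rank <= ceil(top_fraction *
    n_genes)`` (inclusive reading of "top 1%").  Acute and chronic screen
    replicates enter as one pooled list.  Optionally attaches the minimum
    per-replicate empirical FDR of each candidate.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if min_replicates < 1 or min_replicates > len(rankings):
        raise ValueError(
            f"min_replicates={min_replicates} incompatible with {len(rankings)} rankings"
        )
    if empirical_fdrs is not None and len(empirical_fdrs) != len(rankings):
        raise ValueError("one empirical FDR series per ranking is required")

    top_sets = []
    for tbl in rankings:
        cutoff = math.ceil(top_fraction * len(tbl))
        top_sets.append(set(tbl.loc[tbl["gene_rank"] <= cutoff, "gene_symbol"]))

    support: dict[str, int] = {}
    for s in top_sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    candidates = sorted(g for g, c in support.items() if c >= min_replicates)

    out = pd.DataFrame({"gene_symbol": candidates})
    out["support"] = [support[g] for g in candidates]
    for i, s in enumerate(top_sets, start=1):
        out[f"in_top_rep{i}"] = [g in s for g in candidates]
    if empirical_fdrs is not None:
        mins = []
        for g in candidates:
            vals = [f[g] for f in empirical_fdrs if g in f.index]
            mins.append(min(vals) if vals else np.nan)
        out["min_empirical_fdr"] = mins
    return out


def top_n_overlap(ranking_a: pd.DataFrame, ranking_b: pd.DataFrame, n: int) -> float:
    """Fraction of the top-N genes shared by two replicate rankings."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(ranking_a) < n or len(ranking_b) < n:
        raise ValueError(f"both rankings must cover at least n={n} genes")
    top_a = set(ranking_a.loc[ranking_a["gene_rank"] <= n, "gene_symbol"])
    top_b = set(ranking_b.loc[ranking_b["gene_rank"] <= n, "gene_symbol"])
    return len(top_a & top_b) / n
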