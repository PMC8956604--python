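"""Gene-set enrichment of the candidate set with redundancy pruning.

Hypergeometric over-representation of candidate genes in GMT gene sets
restricted to a 5-200 size band within the screened universe, Benjamini-
Hochberg control over the tested family, and a redundancy filter that drops
any pathway sharing more than 30% of its genes with a lower-FDR pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_test",
    "benjamini_hochberg",
    "enrich_pathways",
    "prune_redundant",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique ids, non-empty member lists."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"gene sets must be non-empty: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> set[str]:
        return self.sets[set_id]


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs id, description, members): {line!r}")
            set_id, desc, *members = parts
            if set_id in sets:
                raise ValueError(f"duplicate gene-set id: {set_id}")
            sets[set_id] = {m for m in members if m}
            descriptions[set_id] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, members in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def hypergeometric_test(candidates: set[str], pathway: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) of the observed overlap.

    N = |universe|, K = |pathway ∩ universe|, n = |candidates ∩ universe|,
    k = |candidates ∩ pathway ∩ universe|.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    big_n = len(universe)
    big_k = len(pathway & universe)
    n = len(candidates & universe)
    k = len(candidates & pathway & universe)
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def benjamini_hochberg(pvalues) -> list[float]:
    """Step-up BH adjustment, order-stable (values attached to input positions)."""
    p = list(pvalues)
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_pathways(
    candidates: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_size: int = 5,
    max_size: int = 200,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment over a size-banded gene-set family.

    Sets are filtered to ``min_size <= |set ∩ universe| <= max_size`` before
    testing; BH runs over the tested family only; rows with FDR below the
    threshold are returned sorted by (FDR, p, set id).
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    tested = []
    for set_id in sorted(collection.sets):
        size = len(collection[set_id] & universe)
        if min_size <= size <= max_size:
            overlap = len(candidates & collection[set_id] & universe)
            p = hypergeometric_test(candidates, collection[set_id], universe)
            tested.append((set_id, size, overlap, p))
    if not tested:
        logger.warning("no gene set within the %d-%d size band; empty result", min_size, max_size)
        return pd.DataFrame(columns=["set_id", "size", "overlap", "p", "fdr"])
    rows = pd.DataFrame(tested, columns=["set_id", "size", "overlap", "p"])
    rows["fdr"] = benjamini_hochberg(rows["p"])
    rows = rows[rows["fdr"] < fdr_threshold]
    return rows.sort_values(["fdr", "p", "set_id"], kind="mergesort").reset_index(drop=True)


def prune_redundant(
    rows: pd.DataFrame,
    collection: GeneSetCollection,
    overlap_threshold: float = 0.30,
    universe: set[str] | None = None,
    retained_only: bool = False,
) -> pd.DataFrame:
    """Flag redundant pathways against lower-FDR pathways.

    Rows are sorted by (FDR, p, set id); pathway A is excluded iff
    ``|A ∩ B| / |A| > overlap_threshold`` for some pathway B strictly earlier
    in that order — by default against *all* earlier pathways (literal
    reading of the rule); with ``retained_only=True`` only already-retained
    pathways can exclude (greedy variant).  The overlap denominator is the
    examined pathway's in-universe size.
    """
    if not 0 < overlap_threshold < 1:
        raise ValueError("overlap_threshold must lie in (0, 1)")
    missing = sorted(set(rows["set_id"]) - set(collection.sets))
    if missing:
        raise KeyError(f"set ids missing from collection: {missing[:5]}")

    ordered = rows.sort_values(["fdr", "p", "set_id"], kind="mergesort").reset_index(drop=True)
    members = {
        sid: (collection[sid] & universe if universe is not None else set(collection[sid]))
        for sid in ordered["set_id"]
    }
    retained_flags: list[bool] = []
    for i, sid in enumerate(ordered["set_id"]):
        a = members[sid]
        keep = True
        for j in range(i):
            if retained_only and not retained_flags[j]:
                continue
            b = members[ordered["set_id"].iloc[j]]
            if a and len(a & b) / len(a) > overlap_threshold:
                keep = False
                break
        retained_flags.append(keep)
    ordered["retained"] = retained_flags
    return ordered
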