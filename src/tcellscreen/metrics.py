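"""Small closed-form study metrics and supporting rules.

Percent survival of tumor cells in the cytotoxicity co-culture, the caliper
tumor-volume formula, the bulk RNA-seq differential-expression rule
(detection filter, per-gene t test, BH control, fold-change flag), and the
strand-aware peak-to-promoter overlap call used to nominate transcription-
factor regulators of candidate genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pathways import benjamini_hochberg

__all__ = [
    "percent_survival",
    "tumor_volume",
    "differential_expression",
    "promoter_window",
    "promoter_overlap_calls",
    "read_bed",
]


def percent_survival(viability_with_t, viability_without_t):
    """100 * (viability with T cells) / (paired no-T-cell viability).

    May exceed 100 when the co-cultured cells outgrow the control.
    """
    w = np.asarray(viability_with_t, dtype=float)
    wo = np.asarray(viability_without_t, dtype=float)
    if np.any(wo <= 0):
        raise ValueError("control (no T cell) viability must be positive")
    out = 100.0 * w / wo
    return float(out) if out.ndim == 0 else out


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume estimate (L * W^2) / 2, L the longest dimension."""
    if width_mm < 0 or length_mm < 0:
        raise ValueError("dimensions must be non-negative")
    if width_mm > length_mm:
        raise ValueError("width exceeds length; length must be the longest dimension")
    return length_mm * width_mm**2 / 2.0


def differential_expression(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    detect_min_tpm: float = 10.0,
    detect_min_libraries: int = 3,
    fdr_level: float = 0.01,
    lfc_cutoff: float = 1.0,
    detect_on_log: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential expression between two replicate log2(TPM+1) matrices.

    Genes are kept when detected (TPM >= ``detect_min_tpm``, or the log value
    itself when ``detect_on_log``) in at least ``detect_min_libraries``
    libraries pooled across both conditions; a two-sample t test per gene on
    the log scale is BH-corrected at ``fdr_level``; the ``significant`` flag
    additionally requires |log2 FC| > ``lfc_cutoff`` when the cutoff is
    positive.  The log fold change is mean(a) - mean(b).
    """
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("each condition needs at least 2 replicate libraries")
    common = expr_a.index.intersection(expr_b.index)
    a = expr_a.loc[common].to_numpy(dtype=float)
    b = expr_b.loc[common].to_numpy(dtype=float)

    pooled = np.hstack([a, b])
    level = pooled if detect_on_log else 2.0**pooled - 1.0
    detected = (level >= detect_min_tpm).sum(axis=1) >= detect_min_libraries
    if not detected.any():
        return pd.DataFrame(
            columns=["gene", "mean_a", "mean_b", "lfc", "t", "p", "fdr", "significant"]
        )
    a, b = a[detected], b[detected]
    genes = common[detected]

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance genes with equal means
    fdr = np.asarray(benjamini_hochberg(p))
    lfc = a.mean(axis=1) - b.mean(axis=1)
    significant = fdr < fdr_level
    if lfc_cutoff > 0:
        significant &= np.abs(lfc) > lfc_cutoff
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "lfc": lfc,
            "t": np.nan_to_num(t, nan=0.0),
            "p": p,
            "fdr": fdr,
            "significant": significant,
        }
    ).reset_index(drop=True)


def promoter_window(
    tss: int, strand: str, upstream: int = 2000, downstream: int = 500
) -> tuple[int, int]:
    """Closed 1-based promoter interval around a TSS, strand-aware.

    On the + strand the window runs [tss - upstream, tss + downstream]; on
    the - strand upstream extends toward larger coordinates, giving
    [tss - downstream, tss + upstream].
    """
    if strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream, tss + upstream
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def read_bed(path) -> pd.DataFrame:
    """Read peak intervals from BED (0-based half-open) as 1-based closed."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                      names=["chrom", "start", "end"])
    if (bed["end"] < bed["start"]).any():
        raise ValueError("malformed BED interval with end < start")
    bed["start"] = bed["start"] + 1  # 0-based half-open -> 1-based closed
    return bed


def promoter_overlap_calls(
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 500,
) -> set[str]:
    """Genes whose promoter window intersects any peak by >= 1 bp.

    ``peaks`` carries 1-based closed (chrom, start, end); ``tss_table``
    carries (gene, chrom, pos, strand).  Intersection is closed-interval, so
    a peak ending exactly at the window start counts.
    """
    if (peaks["end"] < peaks["start"]).any():
        raise ValueError("malformed interval with end < start")
    called: set[str] = set()
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for row in tss_table.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        lo, hi = promoter_window(int(row.pos), row.strand, upstream, downstream)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # candidate peaks: start <= hi; among them any end >= lo intersects
        idx = np.searchsorted(starts, hi, side="right")
        if idx > 0 and (ends[:idx] >= lo).any():
            called.add(row.gene)
    return called
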