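"""Tumor-cohort association analyses.

Two downstream checks of screen candidates against patient expression data:

* cytolytic-activity correlation — per-sample immune activity is the
  geometric mean of GZMA and PRF1 expression; each gene's Pearson
  correlation with that score is tested per tumor type via the Fisher
  transformation and Benjamini-Hochberg control, then summarized pan-cancer;
* ssGSEA responder stratification — a rank-weighted ECDF enrichment score of
  the candidate signature per sample, normalized across samples, z-scored
  within each dataset, and compared between immunotherapy responders and
  nonresponders with a two-tailed t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pathways import benjamini_hochberg
from .simulate import CYT_MARKERS, ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "cytolytic_activity",
    "correlate_gene_cytolytic",
    "summarize_pan_cancer",
    "average_patient_replicates",
    "ssgsea_score",
    "zscore_by_dataset",
    "compare_response_groups",
    "ResponseComparison",
]


def cytolytic_activity(cohort: ExpressionCohort, offset: float = 0.01) -> pd.Series:
    """Cytolytic activity CYT = sqrt((GZMA + offset) * (PRF1 + offset)).

    Computed on the linear expression scale (log input is back-transformed as
    2**x - 1, floored at zero); the offset tolerates zero expression.
    """
    missing = [g for g in CYT_MARKERS if g not in cohort.expr.index]
    if missing:
        raise KeyError(f"marker gene(s) missing from cohort: {missing}")
    lin = cohort.linear()
    gzma = lin.loc[CYT_MARKERS[0]].to_numpy(dtype=float)
    prf1 = lin.loc[CYT_MARKERS[1]].to_numpy(dtype=float)
    cyt = np.sqrt((gzma + offset) * (prf1 + offset))
    return pd.Series(cyt, index=cohort.expr.columns, name="cytolytic_activity")


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of x against the vector y (NaN if degenerate)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return r


def correlate_gene_cytolytic(
    cohort: ExpressionCohort,
    cyt: pd.Series,
    fdr_threshold: float = 0.05,
    log_cyt: bool | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-tumor-type correlation with cytolytic activity.

    Pearson r is computed on the cohort's stored scale; by default the
    cytolytic score is put on the same scale (log2(CYT + 1) for log cohorts)
    before correlating — set ``log_cyt=False`` to correlate against the
    linear score.  Significance: z = atanh(r) * sqrt(n - 3) against the
    standard normal, two-sided; BH within tumor type; ``significant_positive``
    requires r > 0 and FDR below the threshold.  Zero-variance genes get
    r = NaN, p = 1 with a logged note.
    """
    if log_cyt is None:
        log_cyt = cohort.scale == "log2"
    cyt_values = np.log2(cyt + 1.0) if log_cyt else cyt.astype(float)

    expr = cohort.expr if genes is None else cohort.expr.loc[genes]
    tiny = np.finfo(float).tiny
    out = []
    for group, meta_g in cohort.meta.groupby("group", sort=True):
        samples = [s for s in expr.columns if s in meta_g.index]
        n = len(samples)
        if n < 4:
            raise ValueError(f"group {group!r} has n={n} < 4 samples")
        x = expr[samples].to_numpy(dtype=float)
        y = cyt_values[samples].to_numpy(dtype=float)
        r = _pearson_rows(x, y)
        degenerate = ~np.isfinite(r)
        if degenerate.any():
            logger.info("%d zero-variance genes in group %s; p set to 1", degenerate.sum(), group)
        z = np.arctanh(np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)) * np.sqrt(n - 3)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(degenerate, 1.0, np.maximum(p, tiny))
        fdr = np.asarray(benjamini_hochberg(p))
        grp = pd.DataFrame(
            {
                "gene_symbol": expr.index,
                "group": group,
                "n": n,
                "r": r,
                "p": p,
                "fdr": fdr,
                "significant_positive": (np.nan_to_num(r) > 0) & (fdr < fdr_threshold),
            }
        )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def summarize_pan_cancer(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-gene count/fraction of tumor types with significant positive r."""
    if rows.empty:
        raise ValueError("no correlation rows to summarize")
    n_types = rows["group"].nunique()
    agg = rows.groupby("gene_symbol")["significant_positive"].sum().rename("n_types_significant")
    out = agg.reset_index()
    out["n_types_tested"] = n_types
    out["fraction"] = out["n_types_significant"] / n_types
    out["significant_any_type"] = out["n_types_significant"] >= 1
    out["significant_gt25pct"] = out["fraction"] > 0.25
    return out


def average_patient_replicates(
    cohort: ExpressionCohort, patient_map: dict[str, str]
) -> ExpressionCohort:
    """Average replicate samples of the same patient on the stored scale.

    Metadata collapses with the replicates; conflicting response labels or
    dataset assignments within one patient raise an error.
    """
    missing = sorted(set(cohort.expr.columns) - set(patient_map))
    if missing:
        raise ValueError(f"patient map does not cover samples: {missing[:5]}")
    patients = pd.Series({s: patient_map[s] for s in cohort.expr.columns})
    expr = cohort.expr.T.groupby(patients).mean().T

    meta_rows = []
    for patient, samples in patients.groupby(patients):
        sub = cohort.meta.loc[samples.index]
        for col in ("group", "response"):
            if col in sub.columns and sub[col].nunique(dropna=True) > 1:
                raise ValueError(f"conflicting {col!r} within patient {patient}")
        meta_rows.append(
            {
                "sample_id": patient,
                "group": sub["group"].iloc[0],
                "response": sub["response"].iloc[0] if "response" in sub.columns else None,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample_id").loc[expr.columns]
    return ExpressionCohort(expr=expr, meta=meta, scale=cohort.scale, group_kind=cohort.group_kind)


def _ssgsea_es_one_sample(
    values: np.ndarray, in_set: np.ndarray, order: np.ndarray, weight: float
) -> float:
    v = np.abs(values[order]) ** weight
    mask = in_set[order]
    win = np.where(mask, v, 0.0)
    denom_in = win.sum()
    if denom_in == 0:  # all in-set rank values zero: fall back to uniform steps
        win = mask.astype(float)
        denom_in = win.sum()
    p_in = np.cumsum(win) / denom_in
    p_out = np.cumsum(~mask) / (len(mask) - mask.sum())
    return float((p_in - p_out).sum())


def ssgsea_score(
    cohort: ExpressionCohort,
    signature: set[str],
    weight: float = 0.25,
    rank_norm: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment of a signature.

    Per sample, genes are ordered by expression descending (ties broken by
    gene name for determinism); the enrichment score is the sum over rank
    positions of the difference between the weighted in-set ECDF (steps
    proportional to |rank value|**weight, rank values being the per-sample
    expression ranks when ``rank_norm`` is set) and the uniform out-of-set
    ECDF.  NES divides ES by the (max - min) ES range across the samples of
    the run, so it needs more than one sample.
    """
    genes = cohort.expr.index
    in_set = np.asarray(genes.isin(sorted(signature)))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("signature does not intersect the cohort's genes")
    if n_in == len(genes):
        raise ValueError("signature covers every gene; out-of-set ECDF undefined")
    if cohort.expr.shape[1] < 2:
        raise ValueError("NES needs at least two samples; provide a multi-sample cohort")

    # stable tie-break on gene name so scores are permutation-invariant
    name_order = np.argsort(genes.to_numpy(), kind="mergesort")
    es = {}
    for sample in cohort.expr.columns:
        x = cohort.expr[sample].to_numpy(dtype=float)
        values = stats.rankdata(x, method="average") if rank_norm else x
        order = name_order[np.argsort(-values[name_order], kind="mergesort")]
        es[sample] = _ssgsea_es_one_sample(values, in_set, order, weight)

    out = pd.DataFrame({"sample_id": list(es), "es": list(es.values())})
    span = out["es"].max() - out["es"].min()
    if span == 0:
        raise ValueError("all enrichment scores identical; NES undefined")
    out["nes"] = out["es"] / span
    out["group"] = cohort.meta.loc[out["sample_id"], "group"].to_numpy()
    if "response" in cohort.meta.columns:
        out["response"] = cohort.meta.loc[out["sample_id"], "response"].to_numpy()
    return out


def zscore_by_dataset(scores: pd.DataFrame) -> pd.DataFrame:
    """z-score NES within each dataset (ddof=1) and concatenate."""
    out = scores.copy()
    zs = np.empty(len(out), dtype=float)
    for group, sub in out.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValueError(f"dataset {group!r} has fewer than 2 samples")
        sd = sub["nes"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"dataset {group!r} has zero NES variance")
        zs[out.index.get_indexer(sub.index)] = (sub["nes"] - sub["nes"].mean()) / sd
    out["z"] = zs
    return out


@dataclass(frozen=True)
class ResponseComparison:
    t: float
    p: float
    mean_responder: float
    mean_nonresponder: float

    @property
    def higher_group(self) -> str:
        return "responder" if self.mean_responder >= self.mean_nonresponder else "nonresponder"


def compare_response_groups(
    scores: pd.DataFrame, value_col: str = "z", equal_var: bool = True
) -> ResponseComparison:
    """Two-sample two-tailed t test of (z-scored) NES between response groups."""
    resp = scores.loc[scores["response"] == "responder", value_col].to_numpy(dtype=float)
    nonresp = scores.loc[scores["response"] == "nonresponder", value_col].to_numpy(dtype=float)
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("both response groups need at least 2 samples")
    t, p = stats.ttest_ind(resp, nonresp, equal_var=equal_var)
    return ResponseComparison(
        t=float(t),
        p=float(p),
        mean_responder=float(resp.mean()),
        mean_nonresponder=float(nonresp.mean()),
    )
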