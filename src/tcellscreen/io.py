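"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import pandas as pd

from .simulate import ExpressionCohort

__all__ = [
    "read_counts",
    "write_counts",
    "read_gene_list",
    "write_gene_list",
    "read_expression_cohort",
    "read_gene_scores",
    "RESPONDER_LABELS",
]

# clinical response labels mapped onto the responder / nonresponder dichotomy:
# complete or partial response, clinical benefit, no progression -> responder;
# stable or progressive disease, no clinical benefit, progression -> nonresponder
RESPONDER_LABELS = {
    "CR": "responder",
    "PR": "responder",
    "clinical benefit": "responder",
    "no progression": "responder",
    "responder": "responder",
    "SD": "nonresponder",
    "PD": "nonresponder",
    "no clinical benefit": "nonresponder",
    "progression": "nonresponder",
    "nonresponder": "nonresponder",
}


def read_counts(path) -> pd.DataFrame:
    """Guide count TSV: guide_id [, target_id, gene_symbol], sample columns."""
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        }


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_cohort(
    expr_path, meta_path, scale: str = "log2", group_kind: str = "dataset"
) -> ExpressionCohort:
    """Load a gene x sample TSV plus a sample metadata TSV.

    The metadata needs ``sample_id`` and a group column (``dataset_id`` or
    ``tumor_type``, stored as ``group``); a ``response_label`` column is
    mapped through :data:`RESPONDER_LABELS` when present.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    for col in ("dataset_id", "tumor_type"):
        if col in meta.columns:
            meta = meta.rename(columns={col: "group"})
            group_kind = "dataset" if col == "dataset_id" else "tumor_type"
            break
    if "response_label" in meta.columns:
        unknown = set(meta["response_label"].dropna()) - set(RESPONDER_LABELS)
        if unknown:
            raise ValueError(f"unrecognized response labels: {sorted(unknown)}")
        meta["response"] = meta["response_label"].map(RESPONDER_LABELS)
    return ExpressionCohort(expr=expr, meta=meta, scale=scale, group_kind=group_kind)
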