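"""Call candidate resistance genes across the pooled screening replicates.

Applies the screen's hit-calling rule — genes ranked in the top 1% of at
least two of the four pooled replicates (acute and chronic combined) — and
attaches each candidate's minimum per-replicate empirical FDR, measured as
the fraction of housekeeping negative-control genes with higher average
guide enrichment.  Reports how many planted resistance genes the rule
recovers.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from tcellscreen import hits, io  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--top-fraction", type=float, default=0.01)
    parser.add_argument("--min-replicates", type=int, default=2)
    args = parser.parse_args()

    score_dir = ROOT / "scratch" / "scores"
    screen_dir = ROOT / "scratch" / "screen"
    if not score_dir.exists():
        sys.exit("run analysis/02_score_replicates.py first")

    controls = io.read_gene_list(screen_dir / "negative_controls.txt")
    paths = sorted(score_dir.glob("*.tsv"))
    rankings = [io.read_gene_scores(p) for p in paths]
    fdrs = [hits.empirical_fdr(r, controls) for r in rankings]
    cand = hits.select_candidates(rankings, top_fraction=args.top_fraction,
                                  min_replicates=args.min_replicates,
                                  empirical_fdrs=fdrs)

    effects = pd.read_csv(screen_dir / "chronic_effects.tsv", sep="\t")
    planted = set(effects.loc[effects["effect"] > 1, "gene_symbol"])
    recovered = set(cand["gene_symbol"]) & planted
    cand["planted"] = cand["gene_symbol"].isin(planted)

    cand.to_csv(ROOT / "results" / "candidates.tsv", sep="\t", index=False)
    io.write_gene_list(cand["gene_symbol"], ROOT / "results" / "candidate_genes.txt")
    print(f"{len(cand)} candidates from {len(rankings)} pooled replicates "
          f"(top {args.top_fraction:.0%}, >= {args.min_replicates} replicates)")
    print(f"planted-gene recovery: {len(recovered)}/{len(planted)} "
          f"({len(recovered) / len(planted):.0%})")
    print(f"candidates with empirical FDR < 0.1: "
          f"{(cand['min_empirical_fdr'] < 0.1).sum()}/{len(cand)}")


if __name__ == "__main__":
    main()
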