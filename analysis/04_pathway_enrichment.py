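"""Pathway enrichment of the candidate set with redundancy pruning.

Builds a synthetic gene-set collection over the screened universe — one
pathway planted from the true resistance genes, two partially overlapping
"relatives" of it, and random decoy sets — then runs size-banded (5-200)
hypergeometric enrichment with BH control at FDR < 0.05 and excludes any
pathway sharing more than 30% of its genes with a lower-FDR pathway.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from tcellscreen import io, pathways  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    screen_dir = ROOT / "scratch" / "screen"
    cand_path = ROOT / "results" / "candidate_genes.txt"
    if not cand_path.exists():
        sys.exit("run analysis/03_call_candidates.py first")

    candidates = io.read_gene_list(cand_path)
    library = pd.read_csv(screen_dir / "library.tsv", sep="\t")
    universe = set(library["gene_symbol"])
    effects = pd.read_csv(screen_dir / "chronic_effects.tsv", sep="\t")
    planted = sorted(effects.loc[effects["effect"] > 1, "gene_symbol"])

    rng = np.random.default_rng(args.seed)
    genes = sorted(universe)
    sets = {
        "resistance_program": set(rng.choice(planted, size=40, replace=False)),
    }
    # two redundant relatives sharing most of the planted program
    core = sorted(sets["resistance_program"])
    sets["resistance_program_related_a"] = set(core[:30]) | set(
        rng.choice(genes, size=10, replace=False))
    sets["resistance_program_related_b"] = set(core[10:]) | set(
        rng.choice(genes, size=15, replace=False))
    for j in range(40):
        sets[f"decoy{j:02d}"] = set(rng.choice(genes, size=int(rng.integers(5, 200)),
                                               replace=False))
    coll = pathways.GeneSetCollection(sets=sets)
    pathways.write_gmt(coll, ROOT / "scratch" / "synthetic_sets.gmt")

    rows = pathways.enrich_pathways(candidates, coll, universe,
                                    min_size=5, max_size=200, fdr_threshold=0.05)
    pruned = pathways.prune_redundant(rows, coll, overlap_threshold=0.30,
                                      universe=universe)
    pruned.to_csv(ROOT / "results" / "pathway_enrichment.tsv", sep="\t", index=False)

    print(f"{len(pruned)} pathways enriched at FDR < 0.05; "
          f"{int(pruned['retained'].sum())} retained after 30%-overlap pruning")
    for row in pruned.itertuples(index=False):
        flag = "retained" if row.retained else "pruned  "
        print(f"  {flag}  {row.set_id:32s} overlap {row.overlap:3d}/{row.size:3d} "
              f"FDR {row.fdr:.2e}")


if __name__ == "__main__":
    main()
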