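"""Simulate the two selection screens the pipeline analyzes.

Generates a genome-scale-style activation library (10,000 gene targets x 3
guides, 300 housekeeping negative controls) and two screens against it with
50 planted resistance genes at a per-round fitness effect of 2.0: an acute
screen (one round of T cell selection) and a chronic screen (three rounds),
each with two replicates.  Full count matrices go to scratch/ (they are
regenerated on demand); a small design summary goes to results/.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))
from tcellscreen import io, simulate  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    outdir = ROOT / "scratch" / "screen"
    outdir.mkdir(parents=True, exist_ok=True)

    lib = simulate.generate_library(10_000, 3, n_negative_controls=300, seed=args.seed)
    lib.to_tsv(outdir / "library.tsv")
    io.write_gene_list(lib.negative_control_genes, outdir / "negative_controls.txt")

    rows = []
    for name, rounds in (("acute", 1), ("chronic", 3)):
        cfg = simulate.ScreenSimConfig(
            n_resistance_genes=50, effect_size=2.0, rounds=rounds,
            sequencing_depth=500, nb_dispersion=0.2, n_replicates=2, seed=args.seed,
        )
        res = simulate.simulate_screen(lib, cfg)
        io.write_counts(res.counts, outdir / f"{name}_counts.tsv")
        res.samples.to_csv(outdir / f"{name}_samples.tsv", sep="\t", index=False)
        pd.Series(res.effects, name="effect").rename_axis("gene_symbol").to_csv(
            outdir / f"{name}_effects.tsv", sep="\t")
        rows.append({
            "screen": name, "rounds": rounds, "replicates": 2,
            "guides": lib.n_guides, "genes": len(lib.genes),
            "negative_controls": len(lib.negative_control_genes),
            "planted_genes": len(res.resistance_genes),
            "median_final_selected_count": res.counts[
                res.sample_name("selected", 1)].median(),
        })
        print(f"{name}: {lib.n_guides} guides, {rounds} round(s), "
              f"{len(res.resistance_genes)} planted resistance genes")

    summary = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "screen_design_summary.tsv", sep="\t", index=False)
    print("count matrices written to scratch/screen/")


if __name__ == "__main__":
    main()
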