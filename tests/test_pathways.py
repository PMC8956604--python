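"""Hypergeometric enrichment, BH adjustment, redundancy pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellscreen.pathways import (
    GeneSetCollection,
    benjamini_hochberg,
    enrich_pathways,
    hypergeometric_test,
    prune_redundant,
    read_gmt,
    write_gmt,
)

from oracles import hypergeom_upper_tail_enumeration, prune_bruteforce


class TestHypergeometric:
    def test_worked_example_enumeration_value(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        candidates = {"g0", "g1", "g2", "g10", "g11"}
        p = hypergeometric_test(candidates, pathway, universe)
        assert p == pytest.approx(1126 / 15504, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        assert hypergeometric_test({"g0"}, {"g9"}, universe) == 1.0

    def test_pathway_equal_to_universe_is_certain(self):
        universe = {f"g{i}" for i in range(8)}
        assert hypergeometric_test({"g0", "g1"}, set(universe), universe) == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            big_n = int(rng.integers(8, 15))
            universe = {f"g{i}" for i in range(big_n)}
            pathway = set(rng.choice(sorted(universe), size=rng.integers(2, 6), replace=False))
            cand = set(rng.choice(sorted(universe), size=rng.integers(2, 5), replace=False))
            mine = hypergeometric_test(cand, pathway, universe)
            oracle = hypergeom_upper_tail_enumeration(cand, pathway, universe)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_anti_monotone_in_overlap(self):
        # larger observed overlap can only shrink the upper-tail p
        from scipy.stats import hypergeom
        ps = [float(hypergeom.sf(k - 1, 100, 20, 15)) for k in range(0, 16)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_test({"a"}, {"a"}, set())


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant_inputs(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_permutation_stability(self, p):
        base = benjamini_hochberg(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        permuted = benjamini_hochberg([p[i] for i in perm])
        assert permuted == pytest.approx([base[i] for i in perm])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def _collection(sets):
    return GeneSetCollection(sets={k: set(v) for k, v in sets.items()})


class TestEnrichPathways:
    def test_size_band_filter(self):
        coll = _collection({"small": ["a", "b", "c", "d"]})
        out = enrich_pathways({"a"}, coll, {"a", "b", "c", "d", "e"}, min_size=5, max_size=200)
        assert out.empty

    def test_perfect_overlap_ranks_first(self, rng):
        universe = {f"g{i}" for i in range(1000)}
        target = {f"g{i}" for i in range(20)}
        decoys = {
            f"decoy{j}": set(rng.choice(sorted(universe), size=30, replace=False))
            for j in range(5)
        }
        coll = _collection({"target": target, **decoys})
        out = enrich_pathways(target, coll, universe, fdr_threshold=1.0)
        assert out.iloc[0]["set_id"] == "target"

    def test_collection_order_invariance(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"p1": {f"g{i}" for i in range(10)}, "p2": {f"g{i}" for i in range(5, 15)}}
        cand = {f"g{i}" for i in range(8)}
        a = enrich_pathways(cand, _collection(sets), universe, fdr_threshold=1.0)
        b = enrich_pathways(cand, _collection(dict(reversed(sets.items()))), universe,
                            fdr_threshold=1.0)
        pd.testing.assert_frame_equal(a, b)


class TestPruneRedundant:
    def _rows(self, entries):
        return pd.DataFrame(entries, columns=["set_id", "size", "overlap", "p", "fdr"])

    def test_worked_overlap_example(self):
        coll = _collection({
            "P1": ["a", "b", "c", "d", "e"],
            "P2": ["a", "b", "c", "x", "y"],
            "P3": [f"z{i}" for i in range(10)],
        })
        rows = self._rows([
            ("P1", 5, 5, 1e-4, 0.001),
            ("P2", 5, 4, 1e-3, 0.01),
            ("P3", 10, 3, 2e-3, 0.02),
        ])
        out = prune_redundant(rows, coll, overlap_threshold=0.30).set_index("set_id")
        assert bool(out.loc["P1", "retained"])
        assert not bool(out.loc["P2", "retained"])  # 3/5 = 60% overlap with P1
        assert bool(out.loc["P3", "retained"])

    def test_identical_sets_drop_higher_fdr_copy(self):
        coll = _collection({"A": ["x", "y", "z", "w", "v"], "B": ["x", "y", "z", "w", "v"]})
        rows = self._rows([("A", 5, 3, 0.001, 0.01), ("B", 5, 3, 0.002, 0.02)])
        out = prune_redundant(rows, coll).set_index("set_id")
        assert bool(out.loc["A", "retained"]) and not bool(out.loc["B", "retained"])

    @pytest.mark.parametrize("retained_only", [False, True])
    def test_matches_bruteforce_on_random_collections(self, rng, retained_only):
        for _ in range(5):
            n_sets = int(rng.integers(5, 50))
            genes = [f"g{i}" for i in range(60)]
            sets = {
                f"S{j:02d}": set(rng.choice(genes, size=rng.integers(3, 20), replace=False))
                for j in range(n_sets)
            }
            fdrs = rng.uniform(0, 0.05, n_sets)
            rows = self._rows([
                (sid, len(s), 1, fdr / 2, fdr)
                for (sid, s), fdr in zip(sets.items(), fdrs)
            ])
            out = prune_redundant(rows, _collection(sets), overlap_threshold=0.30,
                                  retained_only=retained_only)
            expected = prune_bruteforce(list(out["set_id"]), sets, 0.30, retained_only)
            assert list(out["retained"]) == expected

    def test_missing_set_id_errors(self):
        rows = self._rows([("ghost", 5, 1, 0.01, 0.01)])
        with pytest.raises(KeyError):
            prune_redundant(rows, _collection({"A": ["x"]}))


class TestGmtIo:
    def test_roundtrip(self, tmp_path):
        coll = _collection({"S1": ["a", "b"], "S2": ["c", "d", "e"]})
        coll.descriptions.update({"S1": "first", "S2": "second"})
        p = tmp_path / "sets.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_malformed_line_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("only_id\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(p)
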