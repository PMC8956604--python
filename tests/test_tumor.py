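"""Cytolytic correlation and ssGSEA responder analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellscreen.simulate import CohortSimConfig, ExpressionCohort, simulate_expression_cohort
from tcellscreen.tumor import (
    average_patient_replicates,
    compare_response_groups,
    correlate_gene_cytolytic,
    cytolytic_activity,
    ssgsea_score,
    summarize_pan_cancer,
    zscore_by_dataset,
)

from oracles import ssgsea_es_bruteforce


def _cohort(expr: dict, scale="linear", groups=None, responses=None):
    df = pd.DataFrame(expr)
    samples = df.columns
    meta = pd.DataFrame({
        "group": groups or ["t1"] * len(samples),
        "response": responses or [None] * len(samples),
    }, index=samples)
    return ExpressionCohort(expr=df, meta=meta, scale=scale, group_kind="tumor_type")


class TestCytolyticActivity:
    def test_geometric_mean_identity_and_worked_example(self):
        cohort = _cohort({"s1": {"GZMA": 7.0, "PRF1": 7.0}, "s2": {"GZMA": 4.0, "PRF1": 9.0}})
        cyt = cytolytic_activity(cohort, offset=0.0)
        assert cyt["s1"] == pytest.approx(7.0)
        assert cyt["s2"] == pytest.approx(6.0)

    def test_offset_floors_zero_expression(self):
        cohort = _cohort({"s1": {"GZMA": 0.0, "PRF1": 0.0}})
        assert cytolytic_activity(cohort, offset=0.01)["s1"] == pytest.approx(0.01)

    def test_log_scale_back_transform(self):
        cohort = _cohort({"s1": {"GZMA": 2.0, "PRF1": 2.0}}, scale="log2")
        assert cytolytic_activity(cohort, offset=0.0)["s1"] == pytest.approx(3.0)  # 2^2 - 1

    def test_missing_marker_named_in_error(self):
        cohort = _cohort({"s1": {"GZMA": 1.0, "OTHER": 1.0}})
        with pytest.raises(KeyError, match="PRF1"):
            cytolytic_activity(cohort)


class TestCorrelation:
    def test_fisher_z_worked_example(self):
        # r = 0.5, n = 103 -> z = atanh(0.5) * 10 ~ 5.4931, p ~ 3.96e-8
        z = np.arctanh(0.5) * np.sqrt(100)
        p = 2 * stats.norm.sf(z)
        assert z == pytest.approx(5.4931, abs=1e-4)
        assert p == pytest.approx(3.96e-8, rel=0.01)

    def test_perfect_and_zero_correlation(self, rng):
        n = 50
        y = rng.normal(size=n)
        expr = pd.DataFrame({
            f"s{i}": {"GZMA": 0.0, "PRF1": 0.0, "mirror": y[i], "flat": 1.0} for i in range(n)
        })
        expr.loc["GZMA"] = y
        expr.loc["PRF1"] = y
        cohort = _cohort(expr.to_dict(), scale="log2")
        cyt = pd.Series(y, index=expr.columns)
        rows = correlate_gene_cytolytic(cohort, cyt, log_cyt=False).set_index("gene_symbol")
        assert rows.loc["mirror", "r"] == pytest.approx(1.0)
        assert rows.loc["mirror", "p"] > 0.0  # underflow floored, never exactly zero
        assert np.isnan(rows.loc["flat", "r"]) and rows.loc["flat", "p"] == 1.0

    def test_planted_correlation_recovered_and_flagged(self):
        cfg = CohortSimConfig(n_genes=400, n_samples_per_group=200, n_groups=1,
                              planted_correlation=0.5, group_kind="tumor_type", seed=5)
        sig = {f"GENE{i:05d}" for i in range(25)}
        cohort = simulate_expression_cohort(cfg, sig)
        cyt = cytolytic_activity(cohort)
        rows = correlate_gene_cytolytic(cohort, cyt, fdr_threshold=0.05, genes=sorted(sig))
        assert rows["r"].mean() == pytest.approx(0.5, abs=0.1)
        assert rows["significant_positive"].all()

    def test_fisher_z_close_to_permutation_p(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(size=n)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_fisher = 2 * stats.norm.sf(abs(np.arctanh(r_obs)) * np.sqrt(n - 3))
        null = np.empty(10_000)
        for i in range(10_000):
            null[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (1 + (np.abs(null) >= abs(r_obs)).sum()) / (1 + len(null))
        assert 0.5 < p_fisher / p_perm < 2.0

    def test_small_group_errors(self):
        cohort = _cohort({f"s{i}": {"GZMA": 1.0, "PRF1": 1.0, "g": float(i)} for i in range(3)})
        with pytest.raises(ValueError, match="n=3"):
            correlate_gene_cytolytic(cohort, cytolytic_activity(cohort))


class TestPanCancerSummary:
    def test_fraction_and_flags(self):
        rows = pd.DataFrame({
            "gene_symbol": ["g1"] * 33 + ["g2"] * 33 + ["g3"] * 33,
            "group": [f"t{i}" for i in range(33)] * 3,
            "significant_positive": [True] * 9 + [False] * 24
            + [True] + [False] * 32
            + [False] * 33,
        })
        out = summarize_pan_cancer(rows).set_index("gene_symbol")
        assert out.loc["g1", "fraction"] == pytest.approx(9 / 33)
        assert bool(out.loc["g1", "significant_gt25pct"])
        assert bool(out.loc["g2", "significant_any_type"])
        assert not bool(out.loc["g2", "significant_gt25pct"])
        assert not bool(out.loc["g3", "significant_any_type"])


class TestPatientAveraging:
    def test_replicates_averaged_and_singletons_unchanged(self):
        cohort = _cohort({"a1": {"g": 2.0, "GZMA": 1.0, "PRF1": 1.0},
                          "a2": {"g": 4.0, "GZMA": 1.0, "PRF1": 1.0},
                          "b1": {"g": 5.0, "GZMA": 1.0, "PRF1": 1.0}},
                         responses=["responder", "responder", "nonresponder"])
        out = average_patient_replicates(cohort, {"a1": "A", "a2": "A", "b1": "B"})
        assert out.expr.loc["g", "A"] == pytest.approx(3.0)
        assert out.expr.loc["g", "B"] == pytest.approx(5.0)
        assert out.meta.loc["A", "response"] == "responder"

    def test_conflicting_labels_error(self):
        cohort = _cohort({"a1": {"g": 1.0}, "a2": {"g": 2.0}},
                         responses=["responder", "nonresponder"])
        with pytest.raises(ValueError, match="response"):
            average_patient_replicates(cohort, {"a1": "A", "a2": "A"})


class TestSsgsea:
    def test_top_gene_singleton_set_weight_zero(self):
        # ECDF sum by hand: (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2
        cohort = _cohort({
            "s1": {"g1": 10.0, "g2": 3.0, "g3": 2.0, "g4": 1.0},
            "s2": {"g1": 1.0, "g2": 10.0, "g3": 3.0, "g4": 2.0},
        })
        out = ssgsea_score(cohort, {"g1"}, weight=0.0).set_index("sample_id")
        assert out.loc["s1", "es"] == pytest.approx(2.0)

    def test_signature_covering_all_genes_errors(self):
        cohort = _cohort({"s1": {"g1": 1.0, "g2": 2.0}, "s2": {"g1": 2.0, "g2": 1.0}})
        with pytest.raises(ValueError, match="out-of-set"):
            ssgsea_score(cohort, {"g1", "g2"})

    def test_single_sample_errors(self):
        cohort = _cohort({"s1": {"g1": 1.0, "g2": 2.0}})
        with pytest.raises(ValueError, match="sample"):
            ssgsea_score(cohort, {"g1"})

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=(30, 4))
        genes = [f"g{i}" for i in range(30)]
        base = {f"s{j}": dict(zip(genes, vals[:, j])) for j in range(4)}
        shifted = {f"s{j}": dict(zip(genes, np.exp(vals[:, j]))) for j in range(4)}
        sig = set(genes[:6])
        a = ssgsea_score(_cohort(base, scale="log2"), sig, weight=0.25)
        b = ssgsea_score(_cohort(shifted, scale="log2"), sig, weight=0.25)
        np.testing.assert_allclose(a["es"], b["es"], atol=1e-12)

    def test_matches_bruteforce_reimplementation(self, rng):
        genes = [f"g{i}" for i in range(50)]
        sig = set(rng.choice(genes, size=12, replace=False))
        expr = pd.DataFrame(rng.normal(size=(50, 6)), index=genes,
                            columns=[f"s{j}" for j in range(6)])
        cohort = _cohort(expr.to_dict(), scale="log2")
        mine = ssgsea_score(cohort, sig, weight=0.25).set_index("sample_id")
        for s in expr.columns:
            oracle = ssgsea_es_bruteforce(expr[s], sig, weight=0.25)
            assert mine.loc[s, "es"] == pytest.approx(oracle, abs=1e-9)

    def test_matches_gseapy_reference(self, rng):
        gseapy = pytest.importorskip("gseapy")
        genes = [f"g{i}" for i in range(40)]
        sig = sorted(rng.choice(genes, size=10, replace=False))
        expr = pd.DataFrame(rng.lognormal(size=(40, 5)), index=genes,
                            columns=[f"s{j}" for j in range(5)])
        ref = gseapy.ssgsea(data=expr, gene_sets={"SIG": sig}, outdir=None,
                            sample_norm_method="rank", weight=0.25, min_size=1)
        mine = ssgsea_score(_cohort(expr.to_dict()), set(sig), weight=0.25)
        merged = mine.set_index("sample_id").join(
            ref.res2d.set_index("Name")[["ES", "NES"]].astype(float))
        np.testing.assert_allclose(merged["es"], merged["ES"], rtol=1e-6)
        np.testing.assert_allclose(merged["nes"], merged["NES"], rtol=1e-6)


class TestZscoreAndComparison:
    def test_zscore_worked_example_and_centering(self):
        scores = pd.DataFrame({
            "sample_id": list("abcdef"),
            "group": ["d1"] * 3 + ["d2"] * 3,
            "nes": [1.0, 2.0, 3.0, 11.0, 12.0, 16.0],
        })
        out = zscore_by_dataset(scores)
        np.testing.assert_allclose(out.loc[out["group"] == "d1", "z"], [-1, 0, 1])
        assert out.groupby("group")["z"].mean().abs().max() < 1e-12

    def test_zero_variance_dataset_errors(self):
        scores = pd.DataFrame({"sample_id": ["a", "b"], "group": ["d1", "d1"],
                               "nes": [1.0, 1.0]})
        with pytest.raises(ValueError, match="variance"):
            zscore_by_dataset(scores)

    def test_identical_groups_give_t_zero_p_one(self):
        scores = pd.DataFrame({
            "response": ["responder"] * 3 + ["nonresponder"] * 3,
            "z": [0.1, 0.5, 0.9, 0.1, 0.5, 0.9],
        })
        cmp = compare_response_groups(scores)
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_label_swap_flips_sign_keeps_p(self, rng):
        z = rng.normal(size=40)
        labels = ["responder"] * 20 + ["nonresponder"] * 20
        a = compare_response_groups(pd.DataFrame({"response": labels, "z": z}))
        b = compare_response_groups(pd.DataFrame({"response": labels[::-1], "z": z}))
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_tiny_group_errors(self):
        scores = pd.DataFrame({"response": ["responder", "nonresponder", "nonresponder"],
                               "z": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_response_groups(scores)
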