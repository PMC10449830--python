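import numpy as np
import pandas as pd
import pytest

from clonoshift.errors import DataError, StatsError
from clonoshift.scoring import (
    GeneSignature,
    balance_group_sizes,
    build_cluster_signature,
    combined_signature,
    composition_enrichment,
    enrichment_score,
    enrichment_scores,
    load_cdc1_signature,
    sample_balanced_cells,
    scale_scores,
    signature_mean_score,
)

import oracles


def _de(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p", "pct"])


class TestBuildClusterSignature:
    SC = _de(
        [
            ("g1", 1.2, 1e-5, 0.9),   # passes both
            ("g2", 0.8, 1e-4, 0.8),   # passes sc, fails bulk p
            ("g3", 0.3, 1e-5, 0.9),   # fails sc log2fc
            ("g4", 1.5, 0.5, 0.9),    # fails sc p
            ("g5", 0.9, 1e-3, 0.7),   # passes both
        ]
    )
    BULK = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            # fold change > 1.3 means log2fc > log2(1.3) ~ 0.378
            "log2fc": [0.9, 0.6, 0.9, 0.9, 0.5],
            "adj_p": [1e-3, 0.5, 1e-3, 1e-3, 1e-3],
        }
    )

    def test_manual_filter_application(self):
        sig = build_cluster_signature(self.SC, self.BULK, name="c1")
        assert set(sig.genes) == {"g1", "g5"}
        assert sig.weights["g1"] == pytest.approx(1.2)
        assert sig.weights["g5"] == pytest.approx(0.9)

    def test_vacuous_thresholds_keep_all_up_genes(self):
        sig = build_cluster_signature(
            self.SC, self.BULK, sc_log2fc_min=-np.inf, p_max=1.1, bulk_fc_min=0.0
        )
        assert set(sig.genes) == {"g1", "g2", "g3", "g4", "g5"}

    def test_and_semantics(self):
        sig = build_cluster_signature(self.SC, self.BULK)
        assert "g2" not in sig.weights  # sc pass, bulk fail

    def test_empty_signature_reports_attrition(self):
        with pytest.raises(DataError, match="single-cell filter"):
            build_cluster_signature(self.SC, self.BULK, sc_log2fc_min=99.0)


class TestCombinedSignature:
    def test_disjoint_union(self):
        a = GeneSignature("a", {"g1": 1.0, "g2": 2.0, "g3": 0.5})
        b = GeneSignature("b", {"g4": 1.0, "g5": 1.0, "g6": 1.0, "g7": 1.0})
        assert combined_signature([a, b], "ab").n == 7

    def test_shared_gene_keeps_max_weight(self):
        a = GeneSignature("a", {"g1": 1.2})
        b = GeneSignature("b", {"g1": 0.8, "g2": 1.0})
        combo = combined_signature([a, b], "ab")
        assert combo.weights["g1"] == pytest.approx(1.2)

    def test_self_combination_is_identity(self):
        a = GeneSignature("a", {"g1": 1.2, "g2": 0.7})
        assert combined_signature([a, a], "aa").weights == a.weights


class TestEnrichmentScore:
    EXPR = pd.DataFrame(
        {"s1": [2.0, 4.0], "s2": [0.0, 0.0]}, index=["g1", "g2"]
    )

    def test_direct_evaluation(self):
        sig = GeneSignature("s", {"g1": 1.0, "g2": 2.0})
        assert enrichment_score(self.EXPR, sig, "s1") == pytest.approx(5.0)

    def test_zero_expression_scores_zero(self):
        sig = GeneSignature("s", {"g1": 1.0, "g2": 2.0})
        assert enrichment_score(self.EXPR, sig, "s2") == 0.0

    def test_weight_homogeneity(self):
        sig = GeneSignature("s", {"g1": 1.0, "g2": 2.0})
        doubled = GeneSignature("s2", {"g1": 2.0, "g2": 4.0})
        assert enrichment_score(self.EXPR, doubled, "s1") == pytest.approx(
            2 * enrichment_score(self.EXPR, sig, "s1")
        )

    def test_missing_genes_dropped(self):
        sig = GeneSignature("s", {"g1": 1.0, "g9": 5.0})
        assert enrichment_score(self.EXPR, sig, "s1") == pytest.approx(2.0)

    def test_no_genes_present_errors(self):
        sig = GeneSignature("s", {"g8": 1.0})
        with pytest.raises(DataError):
            enrichment_score(self.EXPR, sig, "s1")

    def test_gene_order_irrelevant_matches_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=genes,
            columns=list("abcd"),
        )
        weights = {g: float(rng.uniform(0.5, 2)) for g in genes}
        sig = GeneSignature("s", weights)
        shuffled = GeneSignature(
            "s2", {g: weights[g] for g in reversed(genes)}
        )
        for sample in "abcd":
            expected = oracles.enrichment_score(
                expr[sample].to_dict(), weights
            )
            assert enrichment_score(expr, sig, sample) == pytest.approx(expected)
            assert enrichment_score(expr, shuffled, sample) == pytest.approx(
                expected
            )


class TestScaleScores:
    def test_simple_vector(self):
        np.testing.assert_allclose(scale_scores([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_constant_vector_errors(self):
        with pytest.raises(StatsError):
            scale_scores([2.0, 2.0, 2.0])

    def test_output_standardized(self, rng):
        z = scale_scores(rng.normal(5, 3, size=100))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestSignatureMeanScore:
    def test_per_sample_mean(self):
        expr = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 2.0]},
                            index=["g1", "g2"])
        groups = pd.Series({"s1": "a", "s2": "b"})
        with pytest.raises(StatsError):
            signature_mean_score(expr, ["g1", "g2"], groups)

    def test_mirrored_groups_null(self, rng):
        # both groups contain the same three sample profiles -> t = 0, p = 1
        profiles = [rng.normal(5, 1, size=10) for _ in range(3)]
        expr = pd.DataFrame(
            {f"s{i}": profiles[i % 3] for i in range(6)},
            index=[f"g{i}" for i in range(10)],
        )
        groups = pd.Series(
            ["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)]
        )
        means, t, p = signature_mean_score(
            expr, [f"g{i}" for i in range(10)], groups
        )
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert means["s0"] == pytest.approx(profiles[0].mean())

    def test_planted_shift_detected(self, rng):
        genes = load_cdc1_signature()
        assert len(genes) == 21
        n = 5
        cols = [f"t{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        data = rng.normal(6, 0.3, size=(len(genes), 2 * n))
        data[:, :n] += 1.0
        expr = pd.DataFrame(data, index=genes, columns=cols)
        groups = pd.Series(["rx"] * n + ["ctrl"] * n, index=cols)
        _, _, p = signature_mean_score(expr, genes, groups)
        assert p < 0.05


class TestCompositionEnrichment:
    def test_exact_enumeration_example(self):
        results = composition_enrichment({"c0": [[8, 2], [2, 8]]})
        res = results[0]
        odds, p = oracles.fisher_two_sided([[8, 2], [2, 8]])
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.p == pytest.approx(0.0230, abs=5e-5)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_no_association(self):
        res = composition_enrichment({"c0": [[5, 5], [5, 5]]})[0]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_bh_adjustment_monotone(self, rng):
        tables = {}
        for i in range(20):
            a = int(rng.integers(1, 10))
            b = int(rng.integers(1, 10))
            tables[f"c{i}"] = [[a, b], [10 - a + 1, 10 - b + 1]]
        results = composition_enrichment(tables)
        by_p = sorted(results, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert all(r.q >= r.p for r in results)
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_depletion_is_reciprocal(self):
        res = composition_enrichment({"c0": [[2, 30], [30, 2]]})[0]
        assert res.odds_ratio < 1 / 1.5
        assert res.significant

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            composition_enrichment({"c0": [[0, 0], [5, 5]]})

    def test_haldane_correction_on_zero_cell(self):
        res = composition_enrichment({"c0": [[5, 0], [5, 10]]})[0]
        assert np.isfinite(res.odds_ratio)
        assert res.odds_ratio == pytest.approx((5.5 * 10.5) / (0.5 * 5.5))


class TestBalanceGroupSizes:
    def test_downsample_to_minimum(self):
        sizes = {"untreated": 1920, "ctla4": 2317, "rt": 3363, "rt_ctla4": 2447}
        retained, total = balance_group_sizes(sizes, per_group="min")
        assert retained == {k: 1920 for k in sizes}
        assert total == 7680

    def test_single_group_identity(self):
        retained, total = balance_group_sizes({"only": 55}, per_group="min")
        assert retained == {"only": 55}
        assert total == 55

    def test_strict_mode(self):
        with pytest.raises(DataError):
            balance_group_sizes({"a": 10, "b": 5}, per_group=8, strict=True)

    def test_seeded_sampling_reproducible(self):
        cells = pd.Series(
            ["a"] * 30 + ["b"] * 20,
            index=[f"cell{i}" for i in range(50)],
        )
        keep1 = sample_balanced_cells(cells, seed=3)
        keep2 = sample_balanced_cells(cells, seed=3)
        assert list(keep1) == list(keep2)
        assert cells[keep1].value_counts().to_dict() == {"a": 20, "b": 20}


def test_enrichment_scores_linearity(rng):
    genes = [f"g{i}" for i in range(10)]
    expr = pd.DataFrame(
        rng.normal(size=(10, 3)), index=genes, columns=list("xyz")
    )
    sig = GeneSignature("s", {g: 1.0 for g in genes})
    doubled = enrichment_scores(2 * expr, sig)
    single = enrichment_scores(expr, sig)
    np.testing.assert_allclose(doubled.values, 2 * single.values)
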