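"""Set classification, DMR-DEG overlap, TE links and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from lightmeth.integration import (
    COMPARISON_ORDER,
    chi_squared_2x2,
    classify_light_features,
    dm_feature_ids,
    link_te_to_genes,
    meth_expr_correlation,
    overlap_dmr_deg,
    te_methylation_change,
)

A, B, C, D = COMPARISON_ORDER


def classify_oracle(sets):
    """Brute-force membership-bitmask classification."""
    universe = set().union(*sets.values())
    out = {"constitutive": set(), "frequency": set(), "intensity": set()}
    for k in COMPARISON_ORDER:
        out[f"unique_{k}"] = set()
    for x in universe:
        mask = tuple(x in sets[k] for k in COMPARISON_ORDER)
        if all(mask):
            out["constitutive"].add(x)
        if mask[0] and mask[1] and not mask[2] and not mask[3]:
            out["frequency"].add(x)
        if mask[2] and mask[3] and not mask[0] and not mask[1]:
            out["intensity"].add(x)
        for i, k in enumerate(COMPARISON_ORDER):
            if mask[i] and sum(mask) == 1:
                out[f"unique_{k}"].add(x)
    return out


class TestClassifyLightFeatures:
    def test_hand_worked_example(self):
        sets = {A: {1, 2, 3, 4}, B: {1, 2, 3, 5}, C: {1, 4, 8}, D: {1, 8, 9}}
        out = classify_light_features(sets)
        assert out["constitutive"] == {1}
        assert out["frequency"] == {2, 3}
        assert out["intensity"] == {8}
        assert out["unique_SQLvFLL"] == {5}
        assert out["unique_FLHvFLL"] == {9}

    def test_equal_sets_are_all_constitutive(self):
        s = {1, 2, 3}
        out = classify_light_features({k: set(s) for k in COMPARISON_ORDER})
        assert out["constitutive"] == s
        assert out["frequency"] == out["intensity"] == set()

    def test_disjoint_sets_are_all_unique(self):
        sets = dict(zip(COMPARISON_ORDER, [{1}, {2}, {3}, {4}]))
        out = classify_light_features(sets)
        assert out["constitutive"] == set()
        for k, s in sets.items():
            assert out[f"unique_{k}"] == s

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError):
            classify_light_features({A: set(), B: set(), C: set()})

    @given(st.lists(st.sets(st.integers(0, 25)), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_agrees_with_bitmask_oracle(self, four):
        sets = dict(zip(COMPARISON_ORDER, four))
        assert classify_light_features(sets) == classify_oracle(sets)

    @given(st.lists(st.sets(st.integers(0, 20)), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetric_under_ab_and_cd_swap(self, four):
        sets = dict(zip(COMPARISON_ORDER, four))
        swapped = {A: sets[B], B: sets[A], C: sets[D], D: sets[C]}
        out, out_sw = classify_light_features(sets), classify_light_features(swapped)
        for k in ("constitutive", "frequency", "intensity"):
            assert out[k] == out_sw[k]


class TestChiSquared:
    def test_perfect_independence(self):
        stat, p, reliable = chi_squared_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0) and reliable

    def test_hand_computed_table(self):
        stat, p, _ = chi_squared_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)
        assert p == pytest.approx(0.00982, abs=1e-4)

    def test_matches_scipy_without_correction(self, rng):
        for _ in range(50):
            t = rng.integers(1, 60, size=(2, 2))
            stat, p, _ = chi_squared_2x2(t)
            ref = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_expected_cell_flagged_unreliable(self):
        _, _, reliable = chi_squared_2x2([[0, 1], [1, 50]])
        assert not reliable


def _genes(*rows):
    return pd.DataFrame(
        [dict(chrom="Chr1", start=s, end=e, strand=st_, id=i, kind="gene")
         for s, e, st_, i in rows]
    )


class TestOverlapDmrDeg:
    def _de(self, genes, degs):
        return pd.DataFrame(
            {"gene": genes, "p_value": 0.01, "log2_fc": 1.0,
             "p_adj": 0.01, "is_deg": [g in degs for g in genes]}
        )

    def test_dmr_touching_last_base_overlaps(self):
        genes = _genes((100, 200, "+", "g1"))
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 199, "end": 250,
                              "context": "CpG"}])
        out = overlap_dmr_deg(dmrs, self._de(["g1"], {"g1"}), genes)
        assert out["genes"] == {"g1"}

    def test_dmr_abutting_gene_does_not_overlap(self):
        genes = _genes((100, 200, "+", "g1"))
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 200, "end": 250,
                              "context": "CpG"}])
        out = overlap_dmr_deg(dmrs, self._de(["g1"], {"g1"}), genes)
        assert out["genes"] == set()

    def test_promoter_region_strand_aware(self):
        genes = _genes((5000, 6000, "+", "g1"), (5000, 6000, "-", "g2"))
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 6100, "end": 6200,
                              "context": "CpG"}])
        out = overlap_dmr_deg(dmrs, self._de(["g1", "g2"], {"g1", "g2"}),
                              genes, region="promoter")
        assert out["genes"] == {"g2"}  # downstream window only for minus strand

    def test_chi2_table_counts_partition_universe(self):
        genes = _genes((0, 100, "+", "g1"), (200, 300, "+", "g2"),
                       (400, 500, "+", "g3"))
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 50, "end": 60,
                              "context": "CpG"}])
        out = overlap_dmr_deg(dmrs, self._de(["g1", "g2", "g3"], {"g2"}), genes)
        assert out["table"].sum() == 3


class TestTeLinks:
    def _tes(self):
        return pd.DataFrame(
            [dict(chrom="Chr1", start=1000, end=1500, kind="TE", id="te1",
                  strand="+", parent="", te_superfamily="Gypsy",
                  te_family="Gypsy_1", te_class="retrotransposon")]
        )

    def test_methylation_change_is_overlap_weighted(self):
        dmrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 900, "end": 1200, "prop_diff": -0.4},
             {"chrom": "Chr1", "start": 1400, "end": 1500, "prop_diff": 0.2}]
        )
        ch = te_methylation_change(dmrs, self._tes())
        # overlaps 200 bp at -0.4 and 100 bp at +0.2
        assert ch.loc[0, "te_meth_diff"] == pytest.approx(
            (200 * -0.4 + 100 * 0.2) / 300
        )

    def test_window_gap_rule(self):
        ch = pd.DataFrame([{"te_id": "te1", "chrom": "Chr1", "start": 1000,
                            "end": 1500, "te_meth_diff": -0.3, "n_dmrs": 1}])
        genes = _genes((6400, 7000, "+", "gA"))
        lfc = pd.Series({"gA": 1.2})
        linked = link_te_to_genes(ch, genes, lfc, window_bp=5000)
        assert len(linked) == 1 and linked.loc[0, "distance"] == 4900
        assert link_te_to_genes(ch, genes, lfc, window_bp=2000).empty

    def test_hypomethylated_te_with_upregulated_gene_is_concordant(self):
        ch = pd.DataFrame([{"te_id": "te1", "chrom": "Chr1", "start": 1000,
                            "end": 1500, "te_meth_diff": -0.3, "n_dmrs": 1}])
        genes = _genes((2000, 2600, "+", "gA"), (3000, 3500, "+", "gB"))
        lfc = pd.Series({"gA": 1.2, "gB": -0.8})
        linked = link_te_to_genes(ch, genes, lfc, window_bp=5000)
        by_gene = linked.set_index("gene_id")["concordant"]
        assert bool(by_gene["gA"]) is True     # hypo TE, gene up
        assert bool(by_gene["gB"]) is False    # hypo TE, gene down

    def test_overlapping_te_gene_distance_zero(self):
        ch = pd.DataFrame([{"te_id": "te1", "chrom": "Chr1", "start": 1000,
                            "end": 1500, "te_meth_diff": 0.3, "n_dmrs": 1}])
        genes = _genes((1400, 2000, "+", "gA"))
        linked = link_te_to_genes(ch, genes, pd.Series({"gA": -1.0}), 5000)
        assert linked.loc[0, "distance"] == 0


class TestCorrelation:
    def test_perfect_negative_line(self):
        links = pd.DataFrame(
            {"te_meth_diff": [-0.4, -0.2, 0.0, 0.2],
             "gene_log2_fc": [0.8, 0.4, 0.0, -0.4],
             "te_chromatin_state": "euchromatin", "te_class": "retrotransposon",
             "concordant": True, "te_id": "t", "gene_id": "g", "distance": 0}
        )
        out = meth_expr_correlation(links)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_small_stratum_not_computable(self):
        links = pd.DataFrame(
            {"te_meth_diff": [0.1, -0.2], "gene_log2_fc": [1.0, 2.0],
             "te_chromatin_state": "euchromatin", "te_class": "retrotransposon",
             "concordant": True, "te_id": "t", "gene_id": "g", "distance": 0}
        )
        out = meth_expr_correlation(links)
        assert not out.loc[0, "computable"]

    def test_zero_variance_not_computable(self):
        links = pd.DataFrame(
            {"te_meth_diff": [0.3, 0.3, 0.3], "gene_log2_fc": [1.0, 2.0, 0.5],
             "te_chromatin_state": "x", "te_class": "y",
             "concordant": True, "te_id": "t", "gene_id": "g", "distance": 0}
        )
        assert not meth_expr_correlation(links).loc[0, "computable"]

    def test_recovers_generative_correlation(self, rng):
        # bivariate normal with rho = -0.6, n = 200: Fisher-z 95% interval
        n, rho = 200, -0.6
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        links = pd.DataFrame(
            {"te_meth_diff": 0.2 * x, "gene_log2_fc": 1.5 * y,
             "te_chromatin_state": "euchromatin", "te_class": "retrotransposon",
             "concordant": False, "te_id": "t", "gene_id": "g", "distance": 0}
        )
        r = meth_expr_correlation(links).loc[0, "r"]
        assert -0.72 < r < -0.48

    def test_stratification_splits_rows(self):
        links = pd.DataFrame(
            {"te_meth_diff": [0.1, 0.2, -0.1, -0.3, 0.4, 0.2],
             "gene_log2_fc": [1, -1, 0.5, 2, -2, 1.0],
             "te_chromatin_state": ["a"] * 3 + ["b"] * 3,
             "te_class": "retrotransposon", "concordant": False,
             "te_id": "t", "gene_id": "g", "distance": 0}
        )
        out = meth_expr_correlation(links, stratify_by="chromatin_state")
        assert set(out["stratum"]) == {"a", "b"}
        assert (out["n"] == 3).all()

    def test_unknown_stratification_rejected(self):
        links = pd.DataFrame({"te_meth_diff": [0.1], "gene_log2_fc": [1.0],
                              "te_chromatin_state": "a", "te_class": "b",
                              "concordant": True, "te_id": "t",
                              "gene_id": "g", "distance": 0})
        with pytest.raises(ValueError):
            meth_expr_correlation(links, stratify_by="nonsense")


def test_dm_feature_ids_deduplicates_across_contexts(small_study):
    features = small_study.features
    gene = features.query("kind == 'gene'").iloc[0]
    d1 = pd.DataFrame([{"chrom": gene["chrom"], "start": gene["start"],
                        "end": gene["start"] + 150}])
    d2 = pd.DataFrame([{"chrom": gene["chrom"], "start": gene["start"] + 150,
                        "end": gene["start"] + 300}])
    ids = dm_feature_ids({"CpG": d1, "CpHpH": d2}, features)
    assert gene["id"] in ids
    assert sum(1 for x in ids if x == gene["id"]) == 1
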