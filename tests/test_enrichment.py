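"""Feature assignment precedence and observed/expected enrichment."""

import numpy as np
import pandas as pd
import pytest

from lightmeth.enrichment import (
    annotate_dmrs,
    feature_enrichment,
    genome_kind_fractions,
    permutation_expected,
    read_te_bed,
    sample_null_dmrs,
    te_superfamily_enrichment,
)
from lightmeth.simulate import write_te_bed


def feat(chrom, start, end, kind, id, **kw):
    base = dict(chrom=chrom, start=start, end=end, kind=kind, id=id,
                strand="+", parent="", te_superfamily="", te_family="", te_class="")
    base.update(kw)
    return base


@pytest.fixture
def toy_features():
    return pd.DataFrame(
        [
            feat("Chr1", 100, 400, "TE", "te1", te_superfamily="Gypsy",
                 te_family="Gypsy_1", te_class="retrotransposon"),
            feat("Chr1", 500, 700, "exon", "e1"),
            feat("Chr1", 700, 900, "intron", "i1"),
            feat("Chr1", 1000, 1200, "promoter", "p1"),
        ]
    )


class TestAnnotateDmrs:
    def test_dmr_inside_te_labelled_te(self, toy_features):
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 150, "end": 300}])
        ann = annotate_dmrs(dmrs, toy_features)
        assert (ann.loc[0, "kind"], ann.loc[0, "feature_id"]) == ("TE", "te1")

    def test_equal_overlap_tie_broken_by_precedence(self):
        features = pd.DataFrame(
            [feat("Chr1", 0, 100, "exon", "e1"),
             feat("Chr1", 100, 200, "TE", "te1", te_superfamily="Copia",
                  te_family="Copia_1", te_class="retrotransposon")]
        )
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 50, "end": 150}])
        assert annotate_dmrs(dmrs, features).loc[0, "kind"] == "TE"

    def test_largest_overlap_wins_over_precedence(self, toy_features):
        # 10 bp in the TE, 150 bp in the exon: exon wins despite lower rank
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 390, "end": 650}])
        assert annotate_dmrs(dmrs, toy_features).loc[0, "kind"] == "exon"

    def test_no_overlap_is_intergenic(self, toy_features):
        dmrs = pd.DataFrame([{"chrom": "Chr1", "start": 2000, "end": 2100}])
        ann = annotate_dmrs(dmrs, toy_features)
        assert ann.loc[0, "kind"] == "intergenic"
        assert ann.loc[0, "feature_id"] == ""

    def test_every_dmr_gets_exactly_one_label(self, toy_features, rng):
        starts = rng.integers(0, 1400, size=200)
        dmrs = pd.DataFrame({"chrom": "Chr1", "start": starts, "end": starts + 80})
        ann = annotate_dmrs(dmrs, toy_features)
        assert len(ann) == 200
        assert ann["kind"].notna().all()


class TestFeatureEnrichment:
    def _single_kind_setup(self, n_assigned):
        # one TE covering exactly 10% of a 10 kb genome
        features = pd.DataFrame(
            [feat("Chr1", 0, 1000, "TE", "te1", te_superfamily="Gypsy",
                  te_family="Gypsy_1", te_class="retrotransposon")]
        )
        rows = [{"chrom": "Chr1", "start": 10 + 5 * i, "end": 20 + 5 * i,
                 "kind": "TE", "feature_id": "te1"} for i in range(n_assigned)]
        rows += [{"chrom": "Chr1", "start": 2000 + 20 * i, "end": 2010 + 20 * i,
                  "kind": "intergenic", "feature_id": ""}
                 for i in range(100 - n_assigned)]
        return features, pd.DataFrame(rows)

    @pytest.mark.parametrize("n_assigned,expected_log2", [(10, 0.0), (20, 1.0)])
    def test_log2_ratio_values(self, n_assigned, expected_log2):
        features, dmrs = self._single_kind_setup(n_assigned)
        tab = feature_enrichment(dmrs, features, {"Chr1": 10_000})
        te = tab.set_index("category").loc["TE"]
        assert te["log2_ratio"] == pytest.approx(expected_log2, abs=1e-12)

    def test_zero_observed_flagged_undefined(self):
        features, dmrs = self._single_kind_setup(0)
        tab = feature_enrichment(dmrs, features, {"Chr1": 10_000})
        assert np.isnan(tab.set_index("category").loc["TE", "log2_ratio"])

    def test_observed_and_expected_both_sum_to_total(self, small_study, small_config):
        features = small_study.features
        dmrs = sample_null_dmrs(features, small_config.chrom_lengths(), 500, seed=3)
        ann = annotate_dmrs(dmrs, features)
        tab = feature_enrichment(ann, features, small_config.chrom_lengths())
        assert tab["observed"].sum() == 500
        assert tab["expected"].sum() == pytest.approx(500, abs=1e-9)

    def test_invariant_to_feature_row_order(self, small_study, small_config):
        features = small_study.features
        dmrs = sample_null_dmrs(features, small_config.chrom_lengths(), 300, seed=4)
        shuffled = features.sample(frac=1.0, random_state=9).reset_index(drop=True)
        t1 = feature_enrichment(annotate_dmrs(dmrs, features), features,
                                small_config.chrom_lengths())
        t2 = feature_enrichment(annotate_dmrs(dmrs, shuffled), shuffled,
                                small_config.chrom_lengths())
        pd.testing.assert_frame_equal(t1, t2)

    def test_requires_at_least_one_dmr(self, toy_features):
        with pytest.raises(ValueError):
            feature_enrichment(pd.DataFrame(columns=["chrom", "start", "end"]),
                               toy_features, {"Chr1": 10_000})

    def test_permutation_expectation_matches_analytic(self, small_study, small_config):
        features = small_study.features
        cl = small_config.chrom_lengths()
        dmrs = sample_null_dmrs(features, cl, 200, seed=5)
        ann = annotate_dmrs(dmrs, features)
        tab = feature_enrichment(ann, features, cl).set_index("category")
        perm = permutation_expected(dmrs, features, cl, n_shuffles=40, seed=6)
        # uniform re-placement assigns by largest overlap, the analytic model
        # by projected bp; they agree loosely on the dominant categories
        for kind in ("exon", "intergenic", "TE"):
            assert perm[kind] == pytest.approx(tab.loc[kind, "expected"], rel=0.35)


class TestTeSuperfamilyEnrichment:
    def test_single_superfamily_is_never_enriched(self):
        features = pd.DataFrame(
            [feat("Chr1", 0, 1000, "TE", "te1", te_superfamily="Gypsy",
                  te_family="Gypsy_1", te_class="retrotransposon")]
        )
        dmrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 10, "end": 60, "kind": "TE",
              "feature_id": "te1", "direction": "gain"}]
        )
        tab = te_superfamily_enrichment(dmrs, features)
        assert tab["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_concentrating_all_gains_in_quarter_superfamily_gives_log2_4(self):
        # Gypsy covers 25% of TE bp; every gain-DMR lands in it
        features = pd.DataFrame(
            [feat("Chr1", 0, 1000, "TE", "te1", te_superfamily="Gypsy",
                  te_family="Gypsy_1", te_class="retrotransposon"),
             feat("Chr1", 2000, 5000, "TE", "te2", te_superfamily="Helitron",
                  te_family="Helitron_1", te_class="DNA_transposon")]
        )
        dmrs = pd.DataFrame(
            [{"chrom": "Chr1", "start": 10 * i, "end": 10 * i + 5, "kind": "TE",
              "feature_id": "te1", "direction": "gain"} for i in range(40)]
        )
        tab = te_superfamily_enrichment(dmrs, features).set_index("category")
        assert tab.loc["Gypsy", "log2_ratio"] == pytest.approx(2.0, abs=1e-12)

    def test_directions_assessed_separately(self, small_study, small_config):
        features = small_study.features
        dmrs = sample_null_dmrs(features, small_config.chrom_lengths(), 400,
                                seed=8, kinds=["TE"])
        ann = annotate_dmrs(dmrs, features)
        rng = np.random.default_rng(8)
        ann["direction"] = rng.choice(["gain", "loss"], size=len(ann))
        tab = te_superfamily_enrichment(ann, features)
        for direction, grp in tab.groupby("direction"):
            assert grp["observed"].sum() == (ann["direction"] == direction).sum()
            assert grp["expected"].sum() == pytest.approx(grp["observed"].sum())


def test_te_bed_roundtrip_preserves_ids(small_study, tmp_path):
    p = tmp_path / "tes.bed"
    write_te_bed(small_study.features, p)
    back = read_te_bed(p)
    orig = small_study.features.query("kind == 'TE'").reset_index(drop=True)
    assert list(back["id"]) == list(orig["id"])
    assert list(back["te_superfamily"]) == list(orig["te_superfamily"])
    assert list(back["start"]) == list(orig["start"])
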