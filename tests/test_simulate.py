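"""Synthetic-study generator: determinism, planted effects, structure."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from lightmeth.simulate import (
    COMPARISONS,
    SimConfig,
    SizingError,
    TruthTable,
    plan_expression_truth,
    plan_truth,
    simulate_annotation,
    simulate_counts,
    simulate_methylomes,
    simulate_study,
    write_study,
)


class TestConfig:
    def test_context_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(seed=1, context_probs={"CpG": 0.5, "CpHpG": 0.2, "CpHpH": 0.2})

    @pytest.mark.parametrize(
        "kw",
        [
            {"dmr_effect": 0.0},
            {"dmr_effect": 1.5},
            {"coverage_mean": 0},
            {"cytosine_density": 1.5},
            {"frac_concordant_links": -0.1},
            {"comparisons": ("SQHvXXX",)},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(seed=1, **kw)

    def test_seed_mandatory_in_files(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("genome_length: 1000\n")
        with pytest.raises(ValueError, match="seed"):
            SimConfig.from_file(p)


class TestAnnotation:
    def test_degenerate_config_yields_only_intergenic_space(self):
        cfg = SimConfig(seed=1, genome_length=10_000, n_genes=0, n_tes=0)
        features, states = simulate_annotation(cfg)
        assert features.empty
        assert set(states["state"]) == {"intergenic_state"}
        assert (states["end"] - states["start"]).sum() == 10_000

    def test_state_track_partitions_genome(self, small_study, small_config):
        states = small_study.states
        for chrom, g in states.groupby("chrom"):
            g = g.sort_values("start")
            assert g["start"].iloc[0] == 0
            assert g["end"].iloc[-1] == small_config.genome_length
            # contiguous, non-overlapping
            assert (g["start"].iloc[1:].to_numpy() == g["end"].iloc[:-1].to_numpy()).all()

    def test_features_are_non_overlapping_at_top_level(self, small_study):
        top = small_study.features.query("kind in ('gene', 'TE')").sort_values("start")
        assert (top["start"].iloc[1:].to_numpy() >= top["end"].iloc[:-1].to_numpy()).all()

    def test_te_labels_complete(self, small_study):
        tes = small_study.features.query("kind == 'TE'")
        assert (tes["te_superfamily"] != "").all()
        assert set(tes["te_class"]) <= {"retrotransposon", "DNA_transposon"}

    def test_gene_parts_stay_inside_gene(self, small_study):
        f = small_study.features
        genes = f.query("kind == 'gene'").set_index("id")
        parts = f[f["kind"].isin(["five_prime_UTR", "exon", "intron", "three_prime_UTR"])]
        for r in parts.itertuples():
            g = genes.loc[r.parent]
            assert g["start"] <= r.start < r.end <= g["end"]

    def test_genome_too_small_raises_sizing_error(self):
        with pytest.raises(SizingError):
            simulate_annotation(SimConfig(seed=1, genome_length=20_000, n_genes=50, n_tes=0))

    def test_identical_config_writes_identical_files(self, tmp_path):
        cfg = dict(seed=7, genome_length=60_000, n_genes=10, n_tes=8,
                   n_dmrs_planted=2, n_degs_planted=3)
        write_study(simulate_study(SimConfig(**cfg)), tmp_path / "a")
        write_study(simulate_study(SimConfig(**cfg)), tmp_path / "b")
        names = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors and set(match) == set(names)


class TestMethylomes:
    def test_planted_effect_recovered_in_window(self, small_study, small_config):
        """Pooled empirical proportion difference inside a planted window
        matches the planted effect within binomial sampling error."""
        truth = small_study.truth
        planted = truth.dmrs[truth.dmrs["comparison"] == "SQHvFLH"]
        assert len(planted), "generator planted nothing for the first comparison"
        for r in planted.itertuples():
            diffs = []
            for cond in ("SQH", "FLH"):
                rec = small_study.tracks[cond].records
                sub = rec[
                    (rec["pos"] >= r.start + 1)
                    & (rec["pos"] <= r.end)
                    & (rec["context"] == r.context)
                ]
                diffs.append(sub["meth"].sum() / (sub["meth"] + sub["unmeth"]).sum())
            assert (diffs[1] - diffs[0]) == pytest.approx(r.effect, abs=0.07)

    def test_no_planted_effect_means_no_difference(self):
        cfg = SimConfig(seed=3, genome_length=100_000, n_genes=10, n_tes=10,
                        n_dmrs_planted=0, n_degs_planted=0, coverage_mean=60,
                        comparisons=("SQHvFLH",))
        features, _ = simulate_annotation(cfg)
        truth = plan_truth(cfg, features)
        tracks = simulate_methylomes(cfg, features, truth)
        props = []
        for cond in ("SQH", "FLH"):
            sub = tracks[cond].subset("CpG")
            props.append(sub["meth"].sum() / (sub["meth"] + sub["unmeth"]).sum())
        assert props[0] == pytest.approx(props[1], abs=0.01)

    def test_only_active_conditions_generated(self):
        cfg = SimConfig(seed=3, genome_length=50_000, n_genes=5, n_tes=5,
                        n_dmrs_planted=0, n_degs_planted=0, comparisons=("SQHvSQL",))
        features, _ = simulate_annotation(cfg)
        tracks = simulate_methylomes(cfg, features, plan_truth(cfg, features))
        assert set(tracks) == {"SQH", "SQL"}


class TestCounts:
    def test_zero_dispersion_gives_poisson_counts(self):
        cfg = SimConfig(seed=2, n_genes=3000, n_degs_planted=0, nb_dispersion=0.0,
                        libsize_log_sd=0.0, comparisons=("SQHvFLH",))
        counts, _ = simulate_counts(cfg, plan_expression_truth(cfg))
        sub = counts[[c for c in counts.columns if c.startswith("SQH")]]
        ratio = sub.var(axis=1, ddof=1) / sub.mean(axis=1)
        # variance/mean ratio averages to 1 over many genes
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_lfc_reflected_in_mean_ratio(self):
        cfg = SimConfig(seed=2, n_genes=2000, n_degs_planted=200, deg_lfc=1.0,
                        libsize_log_sd=0.0, comparisons=("SQHvFLH",))
        truth = plan_expression_truth(cfg)
        counts, _ = simulate_counts(cfg, truth)
        up = truth.degs.loc[truth.degs["log2_fc"] > 0, "gene_id"]
        a = counts.loc[up, [c for c in counts.columns if c.startswith("SQH")]].mean(axis=1)
        b = counts.loc[up, [c for c in counts.columns if c.startswith("FLH")]].mean(axis=1)
        assert np.median(b / a) == pytest.approx(2.0, rel=0.1)

    def test_same_seed_identical_matrix(self):
        cfg = SimConfig(seed=8, n_genes=100, n_degs_planted=10)
        t = plan_expression_truth(cfg)
        m1, _ = simulate_counts(cfg, t)
        m2, _ = simulate_counts(cfg, t)
        pd.testing.assert_frame_equal(m1, m2)


class TestTruth:
    def test_truth_is_referentially_consistent(self, small_study, small_config):
        small_study.truth.check_consistent(
            small_study.features, small_config.genome_length
        )

    def test_inconsistent_link_rejected(self, small_study, small_config):
        truth = small_study.truth
        bad = TruthTable(
            dmrs=truth.dmrs,
            degs=truth.degs,
            links=pd.DataFrame(
                [{"te_id": "te99999", "gene_id": "g00001",
                  "comparison": "SQHvFLH", "distance": 10, "concordant": True}]
            ),
        )
        with pytest.raises(ValueError, match="te99999"):
            bad.check_consistent(small_study.features, small_config.genome_length)

    def test_concordant_links_oppose_signs(self, small_study):
        truth = small_study.truth
        dmr_eff = truth.dmrs.set_index(["target_id", "comparison"])["effect"]
        deg_lfc = truth.degs.set_index(["gene_id", "comparison"])["log2_fc"]
        for r in truth.links.itertuples():
            eff = dmr_eff.loc[(r.te_id, r.comparison)]
            lfc = deg_lfc.loc[(r.gene_id, r.comparison)]
            assert eff * lfc < 0

    def test_roundtrip_through_json(self, small_study, tmp_path):
        p = tmp_path / "truth.json"
        small_study.truth.to_json(p)
        back = TruthTable.from_json(p)
        assert len(back.dmrs) == len(small_study.truth.dmrs)
        assert set(back.links["te_id"]) == set(small_study.truth.links["te_id"])
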