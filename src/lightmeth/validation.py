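"""Self-contained validation studies of every pipeline stage.

Each function generates synthetic data with planted ground truth under a
caller-supplied seed, runs the corresponding analysis stage, and returns
the measured quantities (sensitivities, error rates, calibration
fractions). They are the computational core behind the acceptance
checks and the numbered analysis scripts.

All expectations here are computed by independent routes: exact integer
enumeration for the Fisher test, bitmask membership for the set
classification, the textbook chi-squared formula, and planted truth for
everything simulated.
"""

from __future__ import annotations

import hashlib
import tempfile
import time
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from . import integration as integ
from .dmr import DmrParams, bin_table, bin_test, call_dmrs
from .de import fit_de
from .enrichment import annotate_dmrs, feature_enrichment, sample_null_dmrs
from .pipeline import RunConfig, run_pipeline
from .simulate import (
    SimConfig,
    plan_expression_truth,
    simulate_counts,
    simulate_study,
    write_study,
)


# ---------------------------------------------------------------------------
# Fisher exact test vs enumeration oracle


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration.

    Probabilities share the denominator C(N, n1); comparing integer
    numerators makes the "no more probable than observed" tie rule exact.
    """
    r1, r2, n1 = a + b, c + d, a + c
    lo, hi = max(0, n1 - r2), min(r1, n1)
    nums = [comb(r1, k) * comb(r2, n1 - k) for k in range(lo, hi + 1)]
    obs = comb(r1, a) * comb(r2, c)
    return float(Fraction(sum(x for x in nums if x <= obs), comb(r1 + r2, n1)))


def fisher_oracle_sweep(max_margin: int = 30) -> dict:
    """Compare the bin test against the oracle on every 2x2 table with
    row sums <= ``max_margin``; returns the largest absolute deviation."""
    worst = 0.0
    n_tables = 0
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            if r1 == 0 and r2 == 0:
                continue
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    p = bin_test(a, r1 - a, c, r2 - c)
                    p_ref = fisher_enumeration_oracle(a, r1 - a, c, r2 - c)
                    worst = max(worst, abs(p - p_ref))
                    n_tables += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


# ---------------------------------------------------------------------------
# DMR calling: null calibration and planted recovery


def dmr_null_calibration(seed: int, context: str = "CpG") -> dict:
    """Fraction of count-filtered bins with p <= 0.01 on methylomes with
    no planted differences (pre proportion filter)."""
    cfg = SimConfig(seed=seed, comparisons=("SQHvFLH",),
                    n_dmrs_planted=0, n_degs_planted=0)
    bundle = simulate_study(cfg)
    tab = bin_table(bundle.tracks["SQH"], bundle.tracks["FLH"], context,
                    DmrParams(), compute_p="counts_pass")
    ok = tab[tab["counts_pass"]]
    return {
        "fraction_p_le_01": float((ok["p_value"] <= 0.01).mean()),
        "n_bins": int(len(ok)),
    }


def dmr_planted_recovery(seed: int) -> dict:
    """Recovery of 50 planted CpG DMRs (effect 0.4, 600 bp, coverage 20)
    at the study thresholds.

    A planted region counts as recovered when a called DMR overlaps it
    reciprocally by >= 50%; a called DMR is a false positive when it lies
    entirely outside every planted region extended by one bin.
    """
    cfg = SimConfig(seed=seed, comparisons=("SQHvFLH",), n_dmrs_planted=50,
                    dmr_context_probs={"CpG": 1.0, "CpHpG": 0.0, "CpHpH": 0.0})
    bundle = simulate_study(cfg)
    params = DmrParams()
    called = call_dmrs(bundle.tracks["SQH"], bundle.tracks["FLH"], "CpG", params)
    planted = bundle.truth.dmrs.query("context == 'CpG'")
    recovered = 0
    for p in planted.itertuples():
        for c in called.itertuples():
            ov = min(p.end, c.end) - max(p.start, c.start)
            if ov > 0 and ov >= 0.5 * (p.end - p.start) and ov >= 0.5 * (c.end - c.start):
                recovered += 1
                break
    false_pos = 0
    pad = params.bin_bp
    for c in called.itertuples():
        near = ((planted["start"] - pad < c.end) & (planted["end"] + pad > c.start)).any()
        false_pos += 0 if near else 1
    return {
        "n_planted": int(len(planted)),
        "sensitivity": recovered / len(planted),
        "false_positives": int(false_pos),
        "n_called": int(len(called)),
    }


# ---------------------------------------------------------------------------
# Enrichment null


def enrichment_null(seed: int, n_dmrs: int = 20_000) -> dict:
    """Feature enrichment when DMRs are placed proportionally to each
    kind's bp share: every |log2(obs/exp)| should be small."""
    from .simulate import simulate_annotation

    cfg = SimConfig(seed=seed)
    features, _ = simulate_annotation(cfg)
    cl = cfg.chrom_lengths()
    dmrs = sample_null_dmrs(features, cl, n_dmrs, 150, seed=seed)
    ann = annotate_dmrs(dmrs, features)
    tab = feature_enrichment(ann, features, cl)
    return {
        "max_abs_log2": float(tab["log2_ratio"].abs().max()),
        "n_dmrs": int(n_dmrs),
        "n_categories": int(len(tab)),
    }


# ---------------------------------------------------------------------------
# Differential expression: planted recovery and null calibration


def de_planted_recovery(seed: int, n_genes: int = 12_000, n_planted: int = 2800) -> dict:
    """Recovery of planted |log2FC| = 1 at 3 vs 3 replicates, NB
    dispersion 0.05, at padj <= 0.05 and |lfc| >= 0.5."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_degs_planted=n_planted,
                    deg_lfc=1.0, nb_dispersion=0.05, comparisons=("SQHvFLH",))
    truth = plan_expression_truth(cfg)
    counts, samples = simulate_counts(cfg, truth)
    res = fit_de(counts, samples, "SQH", "FLH").set_index("gene")
    planted = truth.degs.set_index("gene_id")
    err = (res.loc[planted.index, "log2_fc"] - planted["log2_fc"]).abs()
    return {
        "sensitivity": float(res.loc[planted.index, "is_deg"].mean()),
        "median_abs_lfc_error": float(err.median()),
        "n_planted": int(n_planted),
    }


def de_null_calibration(seed: int, n_genes: int = 10_000) -> dict:
    """Raw p <= 0.05 fraction on a no-effect simulation (dispersion 0.1)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_degs_planted=0,
                    nb_dispersion=0.1, comparisons=("SQHvFLH",))
    counts, samples = simulate_counts(cfg, plan_expression_truth(cfg))
    res = fit_de(counts, samples, "SQH", "FLH")
    return {
        "type_i_fraction": float((res["p_value"] <= 0.05).mean()),
        "n_genes": int(n_genes),
    }


# ---------------------------------------------------------------------------
# Set classification vs bitmask oracle


def _classify_bitmask_oracle(sets: dict) -> dict:
    order = integ.COMPARISON_ORDER
    out = {"constitutive": set(), "frequency": set(), "intensity": set()}
    for k in order:
        out[f"unique_{k}"] = set()
    for x in set().union(*sets.values()):
        mask = tuple(x in sets[k] for k in order)
        if all(mask):
            out["constitutive"].add(x)
        if mask[0] and mask[1] and not (mask[2] or mask[3]):
            out["frequency"].add(x)
        if mask[2] and mask[3] and not (mask[0] or mask[1]):
            out["intensity"].add(x)
        if sum(mask) == 1:
            out[f"unique_{order[mask.index(True)]}"].add(x)
    return out


def classification_check(seed: int, n_quadruples: int = 1000) -> dict:
    """Hand-worked example plus random set quadruples against the
    bitmask oracle; returns the fraction of exact agreements."""
    order = integ.COMPARISON_ORDER
    hand = dict(zip(order, [{1, 2, 3, 4}, {1, 2, 3, 5}, {1, 4, 8}, {1, 8, 9}]))
    got = integ.classify_light_features(hand)
    hand_ok = (
        got["constitutive"] == {1}
        and got["frequency"] == {2, 3}
        and got["intensity"] == {8}
    )
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_quadruples):
        sets = {
            k: set(rng.choice(30, size=rng.integers(0, 12), replace=False).tolist())
            for k in order
        }
        if integ.classify_light_features(sets) == _classify_bitmask_oracle(sets):
            agree += 1
    return {
        "hand_example_exact": bool(hand_ok),
        "oracle_agreement": agree / n_quadruples,
        "n_quadruples": int(n_quadruples),
    }


def chi_squared_example() -> dict:
    """Textbook check of the 2x2 statistic on [[20,10],[10,20]]."""
    stat, p, _ = integ.chi_squared_2x2([[20, 10], [10, 20]])
    return {"chi2": float(stat), "p_value": float(p), "expected_chi2": 20 / 3}


# ---------------------------------------------------------------------------
# End-to-end study


def _dir_checksum(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def end_to_end_study(seed: int, workdir=None, check_determinism: bool = True) -> dict:
    """Full pipeline on the default synthetic genome.

    Measures the fraction of planted concordant TE-gene pairs that
    reappear as concordant links at the 5 kb window, and (optionally)
    that regenerating and rerunning under the same seed is
    byte-identical.
    """
    t_start = time.time()
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name if ctx else workdir)
    try:
        cfg = SimConfig(seed=seed)
        paths = write_study(simulate_study(cfg), base / "study")
        run_cfg = RunConfig(
            cx={c: paths[f"cx_{c}"] for c in ("SQH", "SQL", "FLH", "FLL")},
            counts=paths["counts"], samples=paths["samples"],
            gff3=paths["gff3"], te_bed=paths["te_bed"],
            state_bed=paths["state_bed"], outdir=str(base / "run"), seed=seed,
        )
        summary = run_pipeline(run_cfg)

        truth = simulate_study(cfg).truth  # regenerated, not cached: pure function
        n_planted = n_recovered = 0
        for comp in summary["dmr_counts"]:
            links = pd.read_csv(base / "run" / f"links_{comp}.tsv", sep="\t")
            planted = truth.links[truth.links["comparison"] == comp]
            conc = links[links["concordant"]]
            rec = set(zip(conc["te_id"], conc["gene_id"]))
            n_planted += len(planted)
            n_recovered += sum(
                (r.te_id, r.gene_id) in rec for r in planted.itertuples()
            )
        out = {
            "concordant_link_recovery": n_recovered / n_planted,
            "n_planted_links": int(n_planted),
            "dmr_total": int(
                sum(sum(v.values()) for v in summary["dmr_counts"].values())
            ),
            "deg_total": int(sum(summary["deg_counts"].values())),
        }
        if check_determinism:
            first = _dir_checksum(base / "run")
            run_pipeline(run_cfg)
            paths2 = write_study(simulate_study(SimConfig(seed=seed)), base / "study2")
            out["rerun_identical"] = float(
                _dir_checksum(base / "run") == first
                and _dir_checksum(base / "study") == _dir_checksum(base / "study2")
            )
        out["runtime_s"] = time.time() - t_start
        return out
    finally:
        if ctx:
            ctx.cleanup()
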