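#!/usr/bin/env python
"""Generate the synthetic four-condition light-acclimation study.

Emulates the study design: four light regimes (SQH, SQL, FLH, FLL), one
pooled methylome per regime at ~20x coverage over a 2 Mb genome, three
RNA replicates per regime, and planted truth — DMRs placed mostly in
TEs, DEGs, and concordant TE-gene pairs within 5 kb.

Writes CX reports, GFF3/BED annotation, the count matrix and the truth
table under scratch/study/ (large raw data; summary tables land in results/).
"""

from pathlib import Path

from lightmeth.simulate import SimConfig, simulate_study, write_study

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    cfg = SimConfig(seed=SEED)
    bundle = simulate_study(cfg)
    paths = write_study(bundle, ROOT / "scratch" / "study")

    genes = (bundle.features["kind"] == "gene").sum()
    tes = (bundle.features["kind"] == "TE").sum()
    print(f"genome: {cfg.n_chromosomes} x {cfg.genome_length:,} bp, "
          f"{genes} genes, {tes} TEs")
    print(f"planted: {len(bundle.truth.dmrs)} DMRs "
          f"({(bundle.truth.dmrs['target_kind'] == 'TE').mean():.0%} in TEs), "
          f"{len(bundle.truth.degs)} DEGs, "
          f"{len(bundle.truth.links)} concordant TE-gene links")
    for cond, track in sorted(bundle.tracks.items()):
        cov = (track.records["meth"] + track.records["unmeth"]).mean()
        print(f"  {cond}: {len(track):,} cytosines, mean coverage {cov:.1f}x")
    print("written:", ", ".join(sorted(Path(p).name for p in paths.values())))


if __name__ == "__main__":
    main()
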