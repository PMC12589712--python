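#!/usr/bin/env python
"""Link differentially methylated TEs to nearby DEGs; test concordance.

For each comparison: TEs hit by any DMR get a length-weighted
methylation change; DEGs within 1/2/5 kb become links; a link is
concordant when methylation loss meets up-regulation or methylation
gain meets down-regulation. Also: the DMR-DEG overlap chi-squared and
Pearson correlations of TE methylation change vs gene fold change,
stratified by chromatin state and TE class. Writes results/links/.
"""

from pathlib import Path

import pandas as pd

from lightmeth.enrichment import load_annotation, read_state_bed
from lightmeth.integration import (
    link_te_to_genes,
    meth_expr_correlation,
    overlap_dmr_deg,
    te_methylation_change,
)
from lightmeth.methylation import CONTEXTS
from lightmeth.simulate import COMPARISONS, SimConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
DMRS = ROOT / "results" / "dmrs"
DE = ROOT / "results" / "de"
OUT = ROOT / "results" / "links"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    features = load_annotation(STUDY / "genes.gff3", STUDY / "tes.bed")
    states = read_state_bed(STUDY / "chromatin_states.bed")
    truth = simulate_study(SimConfig(seed=SEED)).truth

    window_rows, n_pl_all, n_rec_all = [], 0, 0
    for comp in COMPARISONS:
        dmrs = pd.concat(
            [t for ctx in CONTEXTS
             if len(t := pd.read_csv(DMRS / f"{comp}_{ctx}.tsv", sep="\t"))],
            ignore_index=True,
        )
        de = pd.read_csv(DE / f"{comp}.tsv", sep="\t")
        ov = overlap_dmr_deg(dmrs, de, features)
        changes = te_methylation_change(dmrs, features)
        lfc = de.loc[de["is_deg"]].set_index("gene")["log2_fc"]
        for w in (1000, 2000, 5000):
            links = link_te_to_genes(changes, features, lfc, w,
                                     te_features=features, states=states)
            window_rows.append(dict(
                comparison=comp, window=w, n_links=len(links),
                n_concordant=int(links["concordant"].sum()),
            ))
            if w == 5000:
                links.to_csv(OUT / f"links_{comp}.tsv", sep="\t", index=False)
                cors = pd.concat(
                    [meth_expr_correlation(links, s).assign(stratify_by=s)
                     for s in ("none", "chromatin_state", "te_class")],
                    ignore_index=True,
                )
                cors.to_csv(OUT / f"correlations_{comp}.tsv", sep="\t",
                            index=False)
                planted = truth.links[truth.links["comparison"] == comp]
                conc = links[links["concordant"]]
                rec = set(zip(conc["te_id"], conc["gene_id"]))
                n_rec = sum((r.te_id, r.gene_id) in rec
                            for r in planted.itertuples())
                n_pl_all += len(planted)
                n_rec_all += n_rec
                r_all = cors.loc[cors["stratify_by"] == "none", "r"].iloc[0]
                print(f"{comp}: {len(links)} links at 5 kb, "
                      f"{int(links['concordant'].sum())} concordant; "
                      f"planted recovery {n_rec}/{len(planted)}; "
                      f"overall r = {r_all:+.2f}; "
                      f"DMR-DEG chi2 p = {ov['p_value']:.3f}")

    pd.DataFrame(window_rows).to_csv(OUT / "window_counts.tsv", sep="\t",
                                     index=False)
    print(f"\nconcordant planted pairs recovered: {n_rec_all}/{n_pl_all} "
          f"({n_rec_all / n_pl_all:.0%}) — planted anti-correlated pairs "
          "drive a negative methylation-expression correlation at 5 kb.")


if __name__ == "__main__":
    main()
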