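"""Joint analysis of DMRs and DEGs across the four pairwise comparisons.

Covers: classifying light-responsive features from the four comparison
sets (constitutive / frequency / intensity / per-comparison unique),
testing DMR-DEG overlap with a 2x2 chi-squared, linking differentially
methylated TEs to nearby genes within 1/2/5 kb windows, flagging
concordant pairs (hypomethylated TE with an upregulated gene, or
hypermethylated TE with a downregulated gene), and Pearson correlation
of TE methylation change vs nearby-gene fold change, optionally
stratified by chromatin state or TE class.

Sign conventions: in comparison "X vs Y" both the methylation proportion
difference and the expression log2 fold change are Y relative to X.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import pearsonr, spearmanr

from .intervals import interval_gap, overlap_length

#: canonical comparison labels, in A-D order
COMPARISON_ORDER = ["SQHvFLH", "SQLvFLL", "SQHvSQL", "FLHvFLL"]

LINK_COLUMNS = [
    "te_id", "gene_id", "distance", "te_meth_diff", "gene_log2_fc",
    "concordant", "te_chromatin_state", "te_class",
]


def classify_light_features(sets: dict[str, set]) -> dict[str, set]:
    """Partition features by which comparisons call them.

    ``sets`` maps the four comparison labels (A=SQHvFLH, B=SQLvFLL,
    C=SQHvSQL, D=FLHvFLL) to feature-id sets. Returns:

    * ``constitutive`` — in all four comparisons,
    * ``frequency`` — in both square-vs-fluctuating comparisons (A, B)
      and neither intensity comparison,
    * ``intensity`` — in both high-vs-low comparisons (C, D) and neither
      frequency comparison,
    * ``unique_<label>`` — in that comparison only.
    """
    missing = set(COMPARISON_ORDER) - set(sets)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    a, b, c, d = (sets[k] for k in COMPARISON_ORDER)
    out = {
        "constitutive": a & b & c & d,
        "frequency": (a & b) - (c | d),
        "intensity": (c & d) - (a | b),
    }
    for label in COMPARISON_ORDER:
        others = set().union(*(sets[k] for k in COMPARISON_ORDER if k != label))
        out[f"unique_{label}"] = sets[label] - others
    return out


def chi_squared_2x2(table) -> tuple[float, float, bool]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Returns (statistic, p, reliable); ``reliable`` is False when any
    expected cell is < 1 (counts are still returned).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    total = obs.sum()
    if total == 0:
        return 0.0, 1.0, False
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    reliable = bool((exp >= 1).all())
    if (exp == 0).any():
        return 0.0, 1.0, False
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(chi2_dist.sf(stat, df=1)), reliable


def overlap_dmr_deg(
    dmrs: pd.DataFrame,
    de_results: pd.DataFrame,
    genes: pd.DataFrame,
    region: str = "gene_body",
    promoter_bp: int = 1000,
) -> dict:
    """Genes both differentially methylated (body or promoter hit by any
    DMR) and differentially expressed, with a chi-squared association
    test over all tested genes.

    ``genes`` needs chrom/start/end/strand/id rows of kind "gene";
    ``de_results`` is a :func:`lightmeth.de.fit_de` table. Intersection
    uses half-open intervals: a DMR touching any gene base overlaps.
    """
    if region not in ("gene_body", "promoter"):
        raise ValueError(f"unknown region {region!r}")
    g = genes[genes["kind"] == "gene"][["chrom", "start", "end", "strand", "id"]].copy()
    if region == "promoter":
        plus = g["strand"] == "+"
        new_start = np.where(plus, np.maximum(0, g["start"] - promoter_bp), g["end"])
        new_end = np.where(plus, g["start"], g["end"] + promoter_bp)
        g["start"], g["end"] = new_start, new_end

    dm_genes: set = set()
    for chrom, gsub in g.groupby("chrom"):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        ds = dsub["start"].to_numpy()
        de_ = dsub["end"].to_numpy()
        for r in gsub.itertuples():
            if (overlap_length(r.start, r.end, ds, de_) > 0).any():
                dm_genes.add(r.id)

    tested = de_results.dropna(subset=["p_value"])
    de_genes = set(tested.loc[tested["is_deg"], "gene"])
    universe = set(tested["gene"])
    both = dm_genes & de_genes & universe
    dm_only = (dm_genes & universe) - de_genes
    de_only = de_genes - dm_genes
    neither = universe - dm_genes - de_genes
    table = np.array([[len(both), len(dm_only)], [len(de_only), len(neither)]])
    stat, p, reliable = chi_squared_2x2(table)
    return dict(
        genes=both, table=table, chi2=stat, p_value=p, reliable=reliable,
        n_dm=len(dm_genes & universe), n_de=len(de_genes),
    )


def te_methylation_change(
    dmrs: pd.DataFrame, te_features: pd.DataFrame
) -> pd.DataFrame:
    """Length-weighted mean DMR proportion difference per TE.

    A TE counts as differentially methylated when >=1 DMR (any context)
    overlaps it; weights are bp of DMR-TE overlap.
    """
    tes = te_features[te_features["kind"] == "TE"]
    rows = []
    for chrom, tsub in tes.groupby("chrom"):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        ds, de_ = dsub["start"].to_numpy(), dsub["end"].to_numpy()
        diffs = dsub["prop_diff"].to_numpy()
        for r in tsub.itertuples():
            ov = overlap_length(r.start, r.end, ds, de_)
            m = ov > 0
            if m.any():
                rows.append(dict(
                    te_id=r.id, chrom=chrom, start=r.start, end=r.end,
                    te_meth_diff=float(np.average(diffs[m], weights=ov[m])),
                    n_dmrs=int(m.sum()),
                ))
    return pd.DataFrame(rows, columns=["te_id", "chrom", "start", "end",
                                       "te_meth_diff", "n_dmrs"])


def link_te_to_genes(
    te_changes: pd.DataFrame,
    genes: pd.DataFrame,
    gene_lfc: pd.Series,
    window_bp: int = 5000,
    te_features: pd.DataFrame | None = None,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (differentially methylated TE, nearby gene) pair.

    ``te_changes`` comes from :func:`te_methylation_change`; ``gene_lfc``
    maps gene id -> log2 fold change for the genes to consider (typically
    the comparison's DEGs). A pair links when the interval gap is
    <= ``window_bp`` (overlap -> distance 0). Concordant means the signs
    of methylation change and expression change oppose each other
    strictly.
    """
    g = genes[genes["kind"] == "gene"]
    g = g[g["id"].isin(gene_lfc.index)]
    rows = []
    for chrom, tsub in te_changes.groupby("chrom"):
        gsub = g[g["chrom"] == chrom]
        if gsub.empty:
            continue
        gs, ge = gsub["start"].to_numpy(), gsub["end"].to_numpy()
        gids = gsub["id"].to_numpy()
        for r in tsub.itertuples():
            gaps = np.maximum(np.maximum(gs - r.end, r.start - ge), 0)
            for j in np.flatnonzero(gaps <= window_bp):
                lfc = float(gene_lfc[gids[j]])
                md = float(r.te_meth_diff)
                rows.append(dict(
                    te_id=r.te_id, gene_id=gids[j], distance=int(gaps[j]),
                    te_meth_diff=md, gene_log2_fc=lfc,
                    concordant=bool((md < 0 and lfc > 0) or (md > 0 and lfc < 0)),
                    te_chromatin_state="", te_class="",
                ))
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    if links.empty:
        return links
    if te_features is not None:
        cls = te_features[te_features["kind"] == "TE"].set_index("id")
        links["te_class"] = links["te_id"].map(cls["te_class"]).fillna("")
        if "te_superfamily" in cls.columns:
            links["te_superfamily"] = links["te_id"].map(cls["te_superfamily"]).fillna("")
    if states is not None:
        from .enrichment import assign_chromatin_state

        te_iv = te_changes.set_index("te_id")
        iv = pd.DataFrame({
            "chrom": links["te_id"].map(te_iv["chrom"]),
            "start": links["te_id"].map(te_iv["start"]),
            "end": links["te_id"].map(te_iv["end"]),
        })
        links["te_chromatin_state"] = assign_chromatin_state(iv, states).to_numpy()
    return links


def meth_expr_correlation(
    links: pd.DataFrame,
    stratify_by: str = "none",
    method: str = "pearson",
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlation of TE methylation change vs gene fold change per stratum.

    Strata with fewer than ``min_n`` links, or zero variance in either
    variable, are reported with ``computable=False``.
    """
    strat_col = {
        "none": None, "chromatin_state": "te_chromatin_state", "te_class": "te_class",
    }.get(stratify_by, stratify_by if stratify_by in links.columns else None)
    if stratify_by != "none" and strat_col is None:
        raise ValueError(f"unknown stratification {stratify_by!r}")
    corr = pearsonr if method == "pearson" else spearmanr
    groups = (
        [("all", links)] if strat_col is None else list(links.groupby(strat_col))
    )
    rows = []
    for name, grp in groups:
        x = grp["te_meth_diff"].to_numpy(dtype=float)
        y = grp["gene_log2_fc"].to_numpy(dtype=float)
        if len(grp) < min_n or np.std(x) == 0 or np.std(y) == 0:
            rows.append(dict(stratum=name, n=len(grp), r=np.nan, p_value=np.nan,
                             computable=False))
            continue
        r, p = corr(x, y)
        rows.append(dict(stratum=name, n=len(grp), r=float(r), p_value=float(p),
                         computable=True))
    return pd.DataFrame(rows, columns=["stratum", "n", "r", "p_value", "computable"])


def dm_feature_ids(
    dmrs_by_context: dict[str, pd.DataFrame], features: pd.DataFrame
) -> set:
    """Feature ids (genes and TEs) overlapped by >=1 DMR of any context.

    A feature differentially methylated in several contexts is counted
    once.
    """
    out: set = set()
    feats = features[features["kind"].isin(["gene", "TE"])]
    alld = pd.concat(
        [d for d in dmrs_by_context.values() if len(d)], ignore_index=True
    ) if any(len(d) for d in dmrs_by_context.values()) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    for chrom, fsub in feats.groupby("chrom"):
        dsub = alld[alld["chrom"] == chrom]
        if dsub.empty:
            continue
        ds, de_ = dsub["start"].to_numpy(), dsub["end"].to_numpy()
        for r in fsub.itertuples():
            if (overlap_length(r.start, r.end, ds, de_) > 0).any():
                out.add(r.id)
    return out
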