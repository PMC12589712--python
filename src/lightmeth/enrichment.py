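"""DMR-to-feature assignment and observed/expected enrichment.

Each DMR receives exactly one feature label: the overlapping kind with
the largest overlap, ties broken by the fixed precedence
TE > promoter > 5'UTR > 3'UTR > exon > intron; DMRs overlapping nothing
are intergenic. Expected counts are analytic — total DMRs times the
fraction of the genome covered by the kind, where coverage is computed
under the same precedence (so kinds partition the genome and expected
counts sum to the observed total). A permutation mode re-places DMR
intervals uniformly as a cross-check.

TE superfamily enrichment is computed within each direction of change
(gain/loss), with the expectation proportional to each superfamily's
share of total TE bp.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pyranges as pr

from .intervals import precedence_projection, total_length

#: assignment precedence, strongest first (intergenic is the fallback)
PRECEDENCE = ["TE", "promoter", "five_prime_UTR", "three_prime_UTR", "exon", "intron"]

#: superfamily -> Fig-style class grouping (LTR = Gypsy + Copia)
SUPERFAMILY_GROUP = {
    "Gypsy": "LTR",
    "Copia": "LTR",
    "LINE": "LINE",
    "SINE": "SINE",
    "RathE": "RathE",
    "Helitron": "Helitron",
    "DNA": "DNA",
    "Unassigned": "Unassigned",
}


def read_gff3_features(path) -> pd.DataFrame:
    """Genes/UTRs/exons/introns from GFF3 via pyranges (0-based half-open)."""
    df = pr.read_gff3(str(path)).df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "kind": df["Feature"].astype(str),
            "id": df.get("ID", pd.Series([""] * len(df))).astype(str),
            "strand": df["Strand"].astype(str),
            "parent": df.get("Parent", pd.Series([""] * len(df))).fillna("").astype(str),
        }
    )
    for col in ("te_superfamily", "te_family", "te_class"):
        out[col] = ""
    return out


def read_te_bed(path) -> pd.DataFrame:
    """BED6 TEs with name = family|superfamily|class."""
    df = pr.read_bed(str(path)).df
    # pyranges groups rows by (chromosome, strand); restore coordinate order
    # so the synthetic ids assigned below are stable and match the writer's
    df = df.sort_values(["Chromosome", "Start", "End"], kind="mergesort").reset_index(
        drop=True
    )
    parts = df["Name"].astype(str).str.split("|", expand=True)
    if parts.shape[1] != 3:
        raise ValueError(f"{path}: TE BED name field must be family|superfamily|class")
    return pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "kind": "TE",
            "id": [f"te{i + 1:05d}" for i in range(len(df))],
            "strand": df.get("Strand", pd.Series(["+"] * len(df))).astype(str),
            "parent": "",
            "te_family": parts[0].to_numpy(),
            "te_superfamily": parts[1].to_numpy(),
            "te_class": parts[2].to_numpy(),
        }
    )


def read_state_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "state"])
    return df


def load_annotation(gff3_path, te_bed_path) -> pd.DataFrame:
    """Combined feature table from a GFF3 and a TE BED.

    TE ids are te00001... in BED row order, matching the writer in
    :mod:`lightmeth.simulate`.
    """
    genes = read_gff3_features(gff3_path)
    tes = read_te_bed(te_bed_path)
    return pd.concat([genes, tes], ignore_index=True)


def annotate_dmrs(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Assign one (kind, feature_id) per DMR; no overlap -> intergenic.

    Returns a copy of ``dmrs`` with ``kind`` and ``feature_id`` columns.
    """
    out = dmrs.copy().reset_index(drop=True)
    out["kind"] = "intergenic"
    out["feature_id"] = ""
    if out.empty:
        return out
    feat = features[features["kind"].isin(PRECEDENCE)]
    if feat.empty:
        return out
    q = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": out["chrom"],
                "Start": out["start"],
                "End": out["end"],
                "dmr_row": np.arange(len(out)),
            }
        )
    )
    f = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": feat["chrom"],
                "Start": feat["start"],
                "End": feat["end"],
                "kind": feat["kind"].to_numpy(),
                "feature_id": feat["id"].to_numpy(),
            }
        )
    )
    j = q.join(f).df
    if j.empty:
        return out
    j["overlap"] = np.minimum(j["End"], j["End_b"]) - np.maximum(j["Start"], j["Start_b"])
    j["prec"] = j["kind"].map({k: i for i, k in enumerate(PRECEDENCE)})
    j = j.sort_values(["dmr_row", "overlap", "prec"],
                      ascending=[True, False, True], kind="mergesort")
    best = j.drop_duplicates("dmr_row", keep="first")
    out.loc[best["dmr_row"].to_numpy(), "kind"] = best["kind"].to_numpy()
    out.loc[best["dmr_row"].to_numpy(), "feature_id"] = best["feature_id"].to_numpy()
    return out


def genome_kind_fractions(
    features: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.Series:
    """bp fraction of the genome assigned to each kind under the precedence
    projection (plus the intergenic remainder); fractions sum to 1."""
    bp = {k: 0 for k in PRECEDENCE + ["intergenic"]}
    for chrom, length in chrom_lengths.items():
        sub = features[features["chrom"] == chrom]
        kind_ivs = {
            k: [(int(r.start), int(r.end)) for r in sub[sub["kind"] == k].itertuples()]
            for k in PRECEDENCE
        }
        proj = precedence_projection(kind_ivs, PRECEDENCE, length, "intergenic")
        for k, ivs in proj.items():
            bp[k] += total_length(ivs)
    total = sum(chrom_lengths.values())
    return pd.Series(bp, dtype=float) / total


def feature_enrichment(
    dmrs: pd.DataFrame,
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    mode: str = "bp",
) -> pd.DataFrame:
    """Observed vs expected DMR counts per feature kind, log2(obs/exp).

    ``mode="bp"``: expectation from the genomic bp share of each kind
    (precedence-projected). ``mode="count"``: expectation uniform over
    kinds with >=1 bp (a feature-count-free alternative reading).
    Kinds covering 0 bp are skipped with a warning. ``log2_ratio`` is NaN
    when observed is 0.
    """
    if dmrs.empty:
        raise ValueError("feature_enrichment needs at least one DMR")
    ann = dmrs if "kind" in dmrs.columns else annotate_dmrs(dmrs, features)
    frac = genome_kind_fractions(features, chrom_lengths)
    if mode == "count":
        present = frac[frac > 0]
        frac = pd.Series(0.0, index=frac.index)
        frac[present.index] = 1.0 / len(present)
    n = len(ann)
    rows = []
    for kind in PRECEDENCE + ["intergenic"]:
        f = frac[kind]
        observed = int((ann["kind"] == kind).sum())
        if f == 0:
            if observed:
                warnings.warn(f"kind {kind} covers 0 bp but has {observed} DMRs")
            continue
        expected = n * f
        log2_ratio = np.log2(observed / expected) if observed > 0 else np.nan
        rows.append(dict(category=kind, observed=observed, expected=expected,
                         log2_ratio=log2_ratio))
    return pd.DataFrame(rows)


def te_superfamily_enrichment(
    dmrs: pd.DataFrame, te_features: pd.DataFrame
) -> pd.DataFrame:
    """Per (superfamily, direction) enrichment of TE-assigned DMRs.

    Within each direction, expected = direction total x (superfamily bp /
    total TE bp).
    """
    tes = te_features[te_features["kind"] == "TE"]
    if tes.empty:
        raise ValueError("no TE features supplied")
    if "kind" in dmrs.columns:
        te_dmrs = dmrs[dmrs["kind"] == "TE"].copy()
    else:
        te_dmrs = annotate_dmrs(dmrs, te_features)
        te_dmrs = te_dmrs[te_dmrs["kind"] == "TE"].copy()
    sf_of = tes.set_index("id")["te_superfamily"]
    te_dmrs["superfamily"] = te_dmrs["feature_id"].map(sf_of)
    bp = tes.assign(length=tes["end"] - tes["start"]).groupby("te_superfamily")["length"].sum()
    frac = bp / bp.sum()
    rows = []
    for direction, grp in te_dmrs.groupby("direction"):
        n_dir = len(grp)
        for sf, f in frac.items():
            observed = int((grp["superfamily"] == sf).sum())
            expected = n_dir * f
            if expected == 0:
                warnings.warn(f"superfamily {sf} covers 0 bp")
                continue
            rows.append(dict(
                category=sf, direction=direction, observed=observed,
                expected=expected,
                log2_ratio=np.log2(observed / expected) if observed > 0 else np.nan,
            ))
    return pd.DataFrame(rows, columns=["category", "direction", "observed",
                                       "expected", "log2_ratio"])


def permutation_expected(
    dmrs: pd.DataFrame,
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Monte-Carlo expectation: mean kind counts over uniform re-placements
    of the DMR intervals (lengths preserved). Cross-check of the analytic
    bp expectation."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms])
    p = lens / lens.sum()
    counts = {k: 0 for k in PRECEDENCE + ["intergenic"]}
    sizes = (dmrs["end"] - dmrs["start"]).to_numpy()
    for _ in range(n_shuffles):
        ci = rng.choice(len(chroms), size=len(sizes), p=p)
        starts = (rng.random(len(sizes)) * np.maximum(1, lens[ci] - sizes)).astype(int)
        fake = pd.DataFrame(
            {"chrom": np.array(chroms)[ci], "start": starts, "end": starts + sizes}
        )
        ann = annotate_dmrs(fake, features)
        for k, v in ann["kind"].value_counts().items():
            counts[k] += int(v)
    return pd.Series(counts, dtype=float) / n_shuffles


def sample_null_dmrs(
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n: int,
    length: int = 150,
    seed: int = 0,
    kinds: list[str] | None = None,
) -> pd.DataFrame:
    """Draw DMR intervals proportionally to each kind's genomic bp share.

    Null model for calibrating enrichment: a kind is drawn multinomially
    with probability equal to its precedence-projected bp fraction, then
    the interval is placed uniformly inside one of that kind's projected
    segments (segments shorter than ``length`` are skipped, their mass
    going to the rest of the kind). Under this null the observed kind
    counts are multinomial around the analytic expectation. ``kinds``
    restricts placement to a subset (e.g. ["TE"] for superfamily nulls).
    """
    rng = np.random.default_rng(seed)
    seg_rows = []
    for chrom, clen in chrom_lengths.items():
        sub = features[features["chrom"] == chrom]
        kind_ivs = {
            k: [(int(r.start), int(r.end)) for r in sub[sub["kind"] == k].itertuples()]
            for k in PRECEDENCE
        }
        proj = precedence_projection(kind_ivs, PRECEDENCE, clen, "intergenic")
        for k, ivs in proj.items():
            seg_rows.extend(
                (k, chrom, s, e) for s, e in ivs if e - s >= length
            )
    segs = pd.DataFrame(seg_rows, columns=["kind", "chrom", "start", "end"])
    if segs.empty:
        raise ValueError("no projected segment can hold an interval of this length")
    frac = genome_kind_fractions(features, chrom_lengths)
    allowed = frac.index if kinds is None else [k for k in frac.index if k in kinds]
    kinds = [k for k in allowed if (segs["kind"] == k).any()]
    if not kinds:
        raise ValueError("no requested kind has placeable segments")
    p = (frac[kinds] / frac[kinds].sum()).to_numpy()
    per_kind = rng.multinomial(n, p)
    chroms, starts = [], []
    for kind, count in zip(kinds, per_kind):
        if count == 0:
            continue
        kind_segs = segs[segs["kind"] == kind].reset_index(drop=True)
        w = (kind_segs["end"] - kind_segs["start"] - length + 1).to_numpy(float)
        si = rng.choice(len(kind_segs), size=count, p=w / w.sum())
        lo = kind_segs["start"].to_numpy()[si]
        hi = kind_segs["end"].to_numpy()[si] - length + 1
        off = (rng.random(count) * (hi - lo)).astype(int)
        chroms.extend(kind_segs["chrom"].to_numpy()[si])
        starts.extend(lo + off)
    starts = np.asarray(starts, dtype=int)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + length})


def assign_chromatin_state(
    intervals: pd.DataFrame, states: pd.DataFrame
) -> pd.Series:
    """Largest-overlap chromatin state per interval (rows of ``intervals``
    with chrom/start/end)."""
    out = pd.Series("", index=intervals.index, dtype=object)
    if intervals.empty or states.empty:
        return out
    q = pr.PyRanges(pd.DataFrame({
        "Chromosome": intervals["chrom"], "Start": intervals["start"],
        "End": intervals["end"], "row": np.arange(len(intervals)),
    }))
    s = pr.PyRanges(pd.DataFrame({
        "Chromosome": states["chrom"], "Start": states["start"],
        "End": states["end"], "state": states["state"].to_numpy(),
    }))
    j = q.join(s).df
    if j.empty:
        return out
    j["overlap"] = np.minimum(j["End"], j["End_b"]) - np.maximum(j["Start"], j["Start_b"])
    j = j.sort_values(["row", "overlap"], ascending=[True, False], kind="mergesort")
    best = j.drop_duplicates("row", keep="first")
    out.iloc[best["row"].to_numpy()] = best["state"].to_numpy()
    return out
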