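"""Binned DMR calling between two pooled methylomes.

The genome is tiled into fixed-width bins (default 150 bp); per bin and
sequence context, methylated/unmethylated read counts of the two
conditions are pooled and compared with a two-sided Fisher exact test.
A bin survives iff

  (i)   it holds >= min_cytosines context cytosines in both samples,
  (ii)  mean reads per cytosine >= min_reads_per_cytosine in both,
  (iii) Fisher p <= p_threshold, and
  (iv)  |methylation proportion difference| >= the per-context minimum
        (0.2 for CpG/CpHpG, 0.1 for CpHpH by default).

Maximal runs of adjacent surviving bins with the same direction of
change are merged into single DMRs with re-pooled counts and a
re-computed p-value. Direction is that of condition B relative to A
("gain" when B is more methylated).

A normal-approximation score test is available as an alternative to the
exact test (``method="score"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .methylation import CONTEXTS, MethylomeTrack

#: relative tolerance when collecting tables "no more probable than observed";
#: guards against floating-point exclusion of exact ties (and of the observed
#: table itself).
_TIE_RTOL = 1e-7

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "n_cytosines",
    "meth_a", "unmeth_a", "meth_b", "unmeth_b",
    "prop_a", "prop_b", "prop_diff", "direction", "p_value",
]


@dataclass
class DmrParams:
    """Thresholds of the binned DMR caller (defaults follow the study design)."""

    bin_bp: int = 150
    p_threshold: float = 0.01
    min_cytosines: int = 4
    min_prop_diff: dict = field(
        default_factory=lambda: {"CpG": 0.2, "CpHpG": 0.2, "CpHpH": 0.1}
    )
    min_reads_per_cytosine: float = 4.0
    method: str = "fisher"  # or "score"
    adjust_p: bool = False  # optional BH over bin p-values (off: raw threshold)

    def __post_init__(self) -> None:
        if self.bin_bp <= 0 or self.p_threshold <= 0 or self.min_cytosines <= 0:
            raise ValueError("DmrParams thresholds must be positive")
        if self.min_reads_per_cytosine <= 0:
            raise ValueError("min_reads_per_cytosine must be positive")
        missing = set(CONTEXTS) - set(self.min_prop_diff)
        if missing:
            raise ValueError(f"min_prop_diff missing contexts: {missing}")
        if self.method not in ("fisher", "score"):
            raise ValueError(f"unknown test method {self.method!r}")


def bin_genome(chrom_lengths: dict[str, int], bin_bp: int) -> pd.DataFrame:
    """Tile each chromosome into consecutive [k*bin, (k+1)*bin) intervals.

    The final partial bin is retained. Returns (chrom, start, end, bin_idx).
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            continue
        starts = np.arange(0, length, bin_bp)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_bp, length),
                    "bin_idx": np.arange(len(starts)),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "bin_idx"]
    )


def fisher_two_sided(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for [[meth_a, unmeth_a], [meth_b, unmeth_b]].

    Sum of hypergeometric probabilities (margins fixed) of all tables no
    more probable than the observed one.
    """
    a, b, c, d = int(meth_a), int(unmeth_a), int(meth_b), int(unmeth_b)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    if r1 == 0 and r2 == 0:
        raise ValueError("both condition totals are zero")
    n1 = a + c
    n = r1 + r2
    lo, hi = max(0, n1 - r2), min(r1, n1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(n1 - k + 1) - gammaln(r2 - n1 + k + 1)
        - (gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()))


def score_two_sided(meth_a, unmeth_a, meth_b, unmeth_b):
    """Two-proportion z (score) test; vectorised; two-sided normal p."""
    meth_a = np.asarray(meth_a, dtype=float)
    unmeth_a = np.asarray(unmeth_a, dtype=float)
    meth_b = np.asarray(meth_b, dtype=float)
    unmeth_b = np.asarray(unmeth_b, dtype=float)
    na, nb = meth_a + unmeth_a, meth_b + unmeth_b
    p_pool = (meth_a + meth_b) / (na + nb)
    var = p_pool * (1 - p_pool) * (1 / na + 1 / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (meth_a / na - meth_b / nb) / np.sqrt(var), 0.0)
    return 2 * norm.sf(np.abs(z))


def bin_test(meth_a, unmeth_a, meth_b, unmeth_b, method: str = "fisher") -> float:
    """p-value comparing pooled bin counts of two conditions (scalar)."""
    if method == "fisher":
        return fisher_two_sided(meth_a, unmeth_a, meth_b, unmeth_b)
    if method == "score":
        return float(score_two_sided(meth_a, unmeth_a, meth_b, unmeth_b))
    raise ValueError(f"unknown test method {method!r}")


def _fisher_vec(meth_a, unmeth_a, meth_b, unmeth_b) -> np.ndarray:
    return np.array(
        [
            fisher_two_sided(a, b, c, d)
            for a, b, c, d in zip(meth_a, unmeth_a, meth_b, unmeth_b)
        ]
    )


def _aggregate(track: MethylomeTrack, context: str, bin_bp: int) -> pd.DataFrame:
    sub = track.subset(context)
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "bin_idx", "n", "meth", "unmeth"])
    bin_idx = (sub["pos"].to_numpy() - 1) // bin_bp
    g = (
        sub.assign(bin_idx=bin_idx)
        .groupby(["chrom", "bin_idx"], sort=True, observed=True)
        .agg(n=("pos", "size"), meth=("meth", "sum"), unmeth=("unmeth", "sum"))
        .reset_index()
    )
    g["chrom"] = g["chrom"].astype(str)
    return g


def bin_table(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str,
    params: DmrParams | None = None,
    compute_p: str = "candidates",
) -> pd.DataFrame:
    """Pooled per-bin counts for two tracks, with filter flags and p-values.

    ``compute_p``:
      * "candidates" — p only on bins passing the count and
        proportion-difference filters (what `call_dmrs` needs);
      * "counts_pass" — p on every bin passing the count filters
        (filters i–ii), e.g. for null-calibration studies;
      * "none" — no p-values.
    """
    params = params or DmrParams()
    ga = _aggregate(track_a, context, params.bin_bp)
    gb = _aggregate(track_b, context, params.bin_bp)
    m = ga.merge(gb, on=["chrom", "bin_idx"], how="outer", suffixes=("_a", "_b"))
    m = m.fillna(0).astype(
        {"n_a": int, "meth_a": int, "unmeth_a": int, "n_b": int, "meth_b": int, "unmeth_b": int}
    )
    m = m.sort_values(["chrom", "bin_idx"], kind="mergesort").reset_index(drop=True)
    tot_a = m["meth_a"] + m["unmeth_a"]
    tot_b = m["meth_b"] + m["unmeth_b"]
    with np.errstate(invalid="ignore", divide="ignore"):
        m["prop_a"] = np.where(tot_a > 0, m["meth_a"] / tot_a.replace(0, 1), np.nan)
        m["prop_b"] = np.where(tot_b > 0, m["meth_b"] / tot_b.replace(0, 1), np.nan)
    m["prop_diff"] = m["prop_b"] - m["prop_a"]
    cov_ok = (
        (m["n_a"] >= params.min_cytosines)
        & (m["n_b"] >= params.min_cytosines)
        & (tot_a >= params.min_reads_per_cytosine * m["n_a"])
        & (tot_b >= params.min_reads_per_cytosine * m["n_b"])
        & (tot_a > 0)
        & (tot_b > 0)
    )
    m["counts_pass"] = cov_ok
    m["diff_pass"] = np.abs(m["prop_diff"]) >= params.min_prop_diff[context]
    m["p_value"] = np.nan
    if compute_p != "none":
        sel = cov_ok if compute_p == "counts_pass" else (cov_ok & m["diff_pass"])
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx):
            sub = m.iloc[idx]
            if params.method == "fisher":
                pv = _fisher_vec(
                    sub["meth_a"].to_numpy(), sub["unmeth_a"].to_numpy(),
                    sub["meth_b"].to_numpy(), sub["unmeth_b"].to_numpy(),
                )
            else:
                pv = score_two_sided(
                    sub["meth_a"].to_numpy(), sub["unmeth_a"].to_numpy(),
                    sub["meth_b"].to_numpy(), sub["unmeth_b"].to_numpy(),
                )
            m.loc[m.index[idx], "p_value"] = pv
    return m


def call_dmrs(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Call DMRs of one context between two tracks (see module docstring).

    Returns a DataFrame with :data:`DMR_COLUMNS`; coordinates are 0-based
    half-open and each DMR spans a whole number of bins.
    """
    params = params or DmrParams()
    if track_a.subset(context).empty and track_b.subset(context).empty:
        warnings.warn(f"context {context} absent from both tracks")
        return pd.DataFrame(columns=DMR_COLUMNS)
    tab = bin_table(track_a, track_b, context, params, compute_p="candidates")
    p = tab["p_value"].copy()
    if params.adjust_p:
        tested = p.notna()
        if tested.any():
            p.loc[tested] = _bh(p[tested].to_numpy())
    keep = tab["counts_pass"] & tab["diff_pass"] & (p <= params.p_threshold)
    surv = tab[keep.fillna(False)].copy()
    if surv.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    surv["direction"] = np.where(surv["prop_diff"] > 0, "gain", "loss")

    # merge maximal runs of adjacent same-direction bins
    new_run = (
        (surv["chrom"] != surv["chrom"].shift())
        | (surv["bin_idx"] != surv["bin_idx"].shift() + 1)
        | (surv["direction"] != surv["direction"].shift())
    )
    surv["run"] = new_run.cumsum()
    g = surv.groupby("run", sort=True)
    merged = g.agg(
        chrom=("chrom", "first"),
        start_bin=("bin_idx", "min"),
        end_bin=("bin_idx", "max"),
        n_cytosines=("n_a", "sum"),  # cytosines counted in track A's report
        meth_a=("meth_a", "sum"),
        unmeth_a=("unmeth_a", "sum"),
        meth_b=("meth_b", "sum"),
        unmeth_b=("unmeth_b", "sum"),
        direction=("direction", "first"),
    ).reset_index(drop=True)
    merged["start"] = merged["start_bin"] * params.bin_bp
    merged["end"] = (merged["end_bin"] + 1) * params.bin_bp
    merged["context"] = context
    merged["prop_a"] = merged["meth_a"] / (merged["meth_a"] + merged["unmeth_a"])
    merged["prop_b"] = merged["meth_b"] / (merged["meth_b"] + merged["unmeth_b"])
    merged["prop_diff"] = merged["prop_b"] - merged["prop_a"]
    merged["p_value"] = _fisher_vec(
        merged["meth_a"], merged["unmeth_a"], merged["meth_b"], merged["unmeth_b"]
    ) if params.method == "fisher" else score_two_sided(
        merged["meth_a"], merged["unmeth_a"], merged["meth_b"], merged["unmeth_b"]
    )
    # the merged region must itself satisfy the reported-DMR contract
    ok = (
        (np.abs(merged["prop_diff"]) >= params.min_prop_diff[context])
        & (merged["p_value"] <= params.p_threshold)
    )
    merged = merged[ok]
    return merged[DMR_COLUMNS].reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_dmrs(dmrs: pd.DataFrame, tsv_path, bed_path=None) -> None:
    """Write a DMR table as TSV and optionally BED (name = context|direction)."""
    dmrs.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in dmrs.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.context}|{r.direction}\t"
                    f"{r.prop_diff:.4f}\t.\n"
                )
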