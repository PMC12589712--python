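"""Negative-binomial differential expression between two conditions.

A deliberately transparent NB pipeline over a genes x samples count
matrix with replicate groups:

1. median-of-ratios size factors (geometric-mean reference over genes
   positive in every sample; upper-quartile fallback otherwise);
2. per-gene method-of-moments dispersion on normalised counts,
   alpha = max(0, (s^2 - m) / m^2), shrunk halfway toward the mean
   dispersion over genes;
3. a Wald test of log2 fold change against 0 using the NB variance
   m + alpha m^2, two-sided normal p-values;
4. Benjamini-Hochberg adjustment and the DEG rule
   padj <= 0.05 and |log2FC| >= 0.5.

The fold-change convention is condition B relative to condition A
throughout the package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

LN2 = np.log(2.0)

#: upper bound on per-gene raw moment dispersion; biological dispersions sit
#: well below this, and uncapped low-count estimates distort the trend mean
_DISPERSION_CAP = 5.0

DE_COLUMNS = ["gene", "base_mean", "log2_fc", "dispersion", "p_value", "p_adj", "is_deg"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors per sample.

    factor_s = median over all-positive genes of count_gs / geometric
    mean of gene g. Falls back to upper-quartile ratios (scaled to
    geometric mean 1) when no gene is positive in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logmat = np.log(mat[allpos])
        loggeo = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - loggeo, axis=0))
    else:
        warnings.warn("no gene positive in all samples; upper-quartile fallback")
        uq = np.percentile(mat, 75, axis=0)
        if (uq <= 0).any():
            raise ValueError("cannot normalise: zero upper quartile in some sample")
        factors = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fit_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Differential-expression table for cond_b relative to cond_a.

    ``samples`` maps sample -> condition (columns "sample", "condition").
    All-zero genes get NaN p-values and are excluded from BH adjustment.
    """
    cond = samples.set_index("sample")["condition"]
    sel = [s for s in counts.columns if cond.get(s) in (cond_a, cond_b)]
    if len(sel) < 4:
        raise ValueError("need >=2 replicates per condition")
    sub = counts[sel]
    groups = np.array([cond[s] for s in sel])
    for g in (cond_a, cond_b):
        if (groups == g).sum() < 2:
            raise ValueError(f"condition {g} has <2 replicates")
    sf = size_factors(sub)
    norm_counts = sub.to_numpy(dtype=float) / sf.to_numpy()

    in_a, in_b = groups == cond_a, groups == cond_b
    mean_a = norm_counts[:, in_a].mean(axis=1)
    mean_b = norm_counts[:, in_b].mean(axis=1)
    base_mean = norm_counts.mean(axis=1)

    var_num = (
        norm_counts[:, in_a].var(axis=1, ddof=1) * (in_a.sum() - 1)
        + norm_counts[:, in_b].var(axis=1, ddof=1) * (in_b.sum() - 1)
    )
    s2 = var_num / (in_a.sum() + in_b.sum() - 2)
    # moment equation alpha = (s^2 - m)/m^2 on normalized counts, with s^2
    # the pooled within-group variance; capped so low-count genes cannot
    # distort the trend mean
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_raw = np.where(base_mean > 0, (s2 - base_mean) / base_mean**2, 0.0)
    alpha_raw = np.clip(alpha_raw, 0.0, _DISPERSION_CAP)
    tested = base_mean > 0
    trend = alpha_raw[tested].mean() if tested.any() else 0.0
    alpha = shrink_weight * alpha_raw + (1 - shrink_weight) * trend

    # pseudocount only when a group mean is zero, so identical groups stay lfc 0
    zero_mask = (mean_a == 0) | (mean_b == 0)
    ma = np.where(zero_mask, mean_a + 0.5, mean_a)
    mb = np.where(zero_mask, mean_b + 0.5, mean_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2_fc = np.where(tested, np.log2(mb / ma), 0.0)
        var_log2_a = (ma + alpha * ma**2) / (in_a.sum() * ma**2 * LN2**2)
        var_log2_b = (mb + alpha * mb**2) / (in_b.sum() * mb**2 * LN2**2)
        se = np.sqrt(var_log2_a + var_log2_b)
        z = np.where((se > 0) & tested, log2_fc / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(tested, 2 * norm.sf(np.abs(z)), np.nan)
    # identical replicate sets give se = 0 and lfc = 0: p = 1, not significant
    p = np.where(tested & (se == 0), 1.0, p)

    res = pd.DataFrame(
        {
            "gene": counts.index,
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "dispersion": alpha,
            "p_value": p,
        }
    )
    return call_degs(res)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs propagate, excluded from m)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    adj = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


def call_degs(
    results: pd.DataFrame,
    p_adj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply BH adjustment and the DEG rule padj <= t and |lfc| >= t_lfc."""
    res = results.copy()
    if res.empty:
        res["p_adj"] = pd.Series(dtype=float)
        res["is_deg"] = pd.Series(dtype=bool)
        return res
    res["p_adj"] = benjamini_hochberg(res["p_value"].to_numpy())
    res["is_deg"] = (res["p_adj"] <= p_adj_threshold) & (
        res["log2_fc"].abs() >= lfc_threshold
    )
    res["is_deg"] = res["is_deg"].fillna(False)
    return res


def nb_test(
    gene_counts,
    groups,
    factors,
    cond_a: str,
    cond_b: str,
    dispersion_prior: float | None = None,
    shrink_weight: float = 0.5,
) -> dict:
    """Single-gene NB Wald test (the scalar core of :func:`fit_de`).

    ``dispersion_prior`` is the trend dispersion to shrink toward; when
    None the raw moment estimate is used unshrunk.
    """
    y = np.asarray(gene_counts, dtype=float) / np.asarray(factors, dtype=float)
    groups = np.asarray(groups)
    in_a, in_b = groups == cond_a, groups == cond_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need >=2 replicates per group")
    if y.sum() == 0:
        return dict(base_mean=0.0, log2_fc=0.0, dispersion=0.0, p_value=np.nan)
    base_mean = y[in_a | in_b].mean()
    s2 = (
        y[in_a].var(ddof=1) * (in_a.sum() - 1) + y[in_b].var(ddof=1) * (in_b.sum() - 1)
    ) / (in_a.sum() + in_b.sum() - 2)
    alpha_raw = min(max(0.0, (s2 - base_mean) / base_mean**2), _DISPERSION_CAP)
    if dispersion_prior is None:
        alpha = alpha_raw
    else:
        alpha = shrink_weight * alpha_raw + (1 - shrink_weight) * dispersion_prior
    ma, mb = y[in_a].mean(), y[in_b].mean()
    if ma == 0 or mb == 0:
        ma, mb = ma + 0.5, mb + 0.5
    log2_fc = np.log2(mb / ma)
    se = np.sqrt(
        (ma + alpha * ma**2) / (in_a.sum() * ma**2 * LN2**2)
        + (mb + alpha * mb**2) / (in_b.sum() * mb**2 * LN2**2)
    )
    z = log2_fc / se if se > 0 else 0.0
    return dict(
        base_mean=float(base_mean),
        log2_fc=float(log2_fc),
        dispersion=float(alpha),
        p_value=float(2 * norm.sf(abs(z))),
    )
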