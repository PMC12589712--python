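"""Synthetic four-condition light-acclimation study with planted ground truth.

Generates, under one seed:

* a toy genome annotation — non-overlapping genes (with UTR/exon/intron
  substructure and 1 kb strand-aware promoters), transposable elements
  labelled with superfamily and class, and a chromatin-state track that
  partitions every base among euchromatin / facultative heterochromatin /
  constitutive heterochromatin / an intergenic state;
* one pooled cytosine-count methylome per condition (SQH, SQL, FLH, FLL):
  coverage ~ Poisson, methylated reads ~ Binomial around per-context
  baselines, elevated inside TEs;
* a genes x (4 conditions x 3 replicates) RNA count matrix with
  negative-binomial noise and lognormal library-size factors;
* a truth table of planted DMRs, DEGs and concordant TE-gene links.

Each pairwise comparison (SQHvFLH, SQLvFLL, SQHvSQL, FLHvFLL) perturbs
its second condition; because four conditions form four comparisons, a
perturbed condition is necessarily shared by two comparisons, just as
every real condition participates in two comparisons. Recovery studies
that need clean separation restrict ``comparisons`` to one pair.

Outputs are a pure function of the config (including the seed):
identical configs give byte-identical files.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .intervals import interval_gap, precedence_projection, total_length
from .methylation import CONTEXT_TO_FILE, CONTEXTS, MethylomeTrack

CONDITIONS = ("SQH", "SQL", "FLH", "FLL")

#: comparison name -> (condition A, condition B); effects are planted in B
COMPARISONS: dict[str, tuple[str, str]] = {
    "SQHvFLH": ("SQH", "FLH"),
    "SQLvFLL": ("SQL", "FLL"),
    "SQHvSQL": ("SQH", "SQL"),
    "FLHvFLL": ("FLH", "FLL"),
}

TE_SUPERFAMILIES = {
    # superfamily: (sampling weight, class)
    "Gypsy": (0.20, "retrotransposon"),
    "Copia": (0.15, "retrotransposon"),
    "LINE": (0.10, "retrotransposon"),
    "SINE": (0.05, "retrotransposon"),
    "RathE": (0.05, "retrotransposon"),
    "Helitron": (0.20, "DNA_transposon"),
    "DNA": (0.15, "DNA_transposon"),
    "Unassigned": (0.10, "DNA_transposon"),
}

_TRI = {"CpG": "CGA", "CpHpG": "CAG", "CpHpH": "CTA"}  # representative trinucleotides


class SizingError(ValueError):
    """Genome too small to place the requested features."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults are the desk-scale study conditions: one 2 Mb chromosome,
    Arabidopsis-like cytosine density and context mix, pooled coverage
    20x, 150 bp-scale DMRs of effect 0.4 planted mostly in TEs, and
    three RNA replicates per condition.
    """

    seed: int
    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    n_genes: int = 450
    n_tes: int = 300
    cytosine_density: float = 0.35
    context_probs: dict = field(
        default_factory=lambda: {"CpG": 0.2, "CpHpG": 0.2, "CpHpH": 0.6}
    )
    coverage_mean: float = 20.0
    baseline_meth: dict = field(
        default_factory=lambda: {"CpG": 0.25, "CpHpG": 0.10, "CpHpH": 0.05}
    )
    te_baseline_meth: dict = field(
        default_factory=lambda: {"CpG": 0.80, "CpHpG": 0.50, "CpHpH": 0.25}
    )
    n_dmrs_planted: int = 50
    dmr_effect: float = 0.4
    dmr_length: int = 600
    dmr_context_probs: dict = field(
        default_factory=lambda: {"CpG": 0.5, "CpHpG": 0.25, "CpHpH": 0.25}
    )
    dmr_target_fracs: dict = field(
        default_factory=lambda: {"TE": 0.7, "gene": 0.2, "intergenic": 0.1}
    )
    n_degs_planted: int = 60
    deg_lfc: float = 1.0
    nb_dispersion: float = 0.05
    mean_expression: float = 300.0
    expression_log_sd: float = 1.0
    libsize_log_sd: float = 0.1
    n_replicates: int = 3
    frac_concordant_links: float = 0.5
    link_distance: int = 5000
    promoter_bp: int = 1000
    comparisons: tuple = tuple(COMPARISONS)

    def __post_init__(self) -> None:
        for name, probs in (("context_probs", self.context_probs),
                            ("dmr_context_probs", self.dmr_context_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for d in (self.baseline_meth, self.te_baseline_meth):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("methylation baselines must lie in [0, 1]")
        if not 0 < self.dmr_effect <= 1:
            raise ValueError("dmr_effect must lie in (0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 <= self.cytosine_density <= 1:
            raise ValueError("cytosine_density must lie in [0, 1]")
        if not 0 <= self.frac_concordant_links <= 1:
            raise ValueError("frac_concordant_links must lie in [0, 1]")
        unknown = set(self.comparisons) - set(COMPARISONS)
        if unknown:
            raise ValueError(f"unknown comparisons: {unknown}")
        self.comparisons = tuple(self.comparisons)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        if "seed" not in d:
            raise ValueError("config must set a seed")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def chrom_lengths(self) -> dict[str, int]:
        return {f"Chr{i + 1}": self.genome_length for i in range(self.n_chromosomes)}


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the feature set and chromatin-state track.

    Returns ``(features, states)``:

    * ``features`` — one row per feature with columns chrom, start, end
      (0-based half-open), kind ∈ {gene, promoter, five_prime_UTR, exon,
      intron, three_prime_UTR, TE}, id, strand, parent, te_superfamily,
      te_family, te_class;
    * ``states`` — disjoint intervals (chrom, start, end, state) tiling
      each chromosome with euchromatin / facultative_het /
      constitutive_het / intergenic_state.
    """
    rng = _rng(config, 1)
    chroms = sorted(config.chrom_lengths())
    n_chrom = len(chroms)
    rows: list[dict] = []
    gene_counter = te_counter = 0
    fac_genes: set[str] = set()

    for ci, chrom in enumerate(chroms):
        n_genes = config.n_genes // n_chrom + (1 if ci < config.n_genes % n_chrom else 0)
        n_tes = config.n_tes // n_chrom + (1 if ci < config.n_tes % n_chrom else 0)
        gene_lens = rng.integers(800, 4001, size=n_genes)
        te_lens = np.clip(
            np.exp(rng.normal(math.log(700), 0.6, size=n_tes)).astype(int), 150, 5000
        )
        lens = np.concatenate([gene_lens, te_lens])
        is_gene = np.concatenate([np.ones(n_genes, bool), np.zeros(n_tes, bool)])
        order = rng.permutation(len(lens))
        lens, is_gene = lens[order], is_gene[order]
        free = config.genome_length - int(lens.sum())
        if free < len(lens) + 1:
            raise SizingError(
                f"genome of {config.genome_length} bp cannot hold "
                f"{n_genes} genes + {n_tes} TEs on {chrom}"
            )
        if len(lens) == 0:
            continue
        gaps = rng.multinomial(free, np.ones(len(lens) + 1) / (len(lens) + 1))
        starts = np.cumsum(gaps[:-1]) + np.cumsum(np.concatenate([[0], lens[:-1]]))
        for start, length, g in zip(starts, lens, is_gene):
            start, end = int(start), int(start + length)
            strand = "+" if rng.random() < 0.5 else "-"
            if g:
                gene_counter += 1
                gid = f"g{gene_counter:05d}"
                rows.append(dict(chrom=chrom, start=start, end=end, kind="gene",
                                 id=gid, strand=strand, parent=""))
                rows.extend(_gene_parts(rng, chrom, start, end, strand, gid))
                p_start, p_end = _promoter(start, end, strand, config.promoter_bp,
                                           config.genome_length)
                rows.append(dict(chrom=chrom, start=p_start, end=p_end,
                                 kind="promoter", id=f"{gid}_prom", strand=strand,
                                 parent=gid))
                if rng.random() < 0.15:
                    fac_genes.add(gid)
            else:
                te_counter += 1
                sf = rng.choice(
                    list(TE_SUPERFAMILIES),
                    p=[w for w, _ in TE_SUPERFAMILIES.values()],
                )
                rows.append(dict(
                    chrom=chrom, start=start, end=end, kind="TE",
                    id=f"te{te_counter:05d}", strand=strand, parent="",
                    te_superfamily=sf, te_family=f"{sf}_{te_counter:04d}",
                    te_class=TE_SUPERFAMILIES[sf][1],
                ))

    features = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "kind", "id", "strand", "parent",
                 "te_superfamily", "te_family", "te_class"],
    )
    for col in ("te_superfamily", "te_family", "te_class"):
        features[col] = features[col] if col in features else ""
    features = features.fillna({"te_superfamily": "", "te_family": "", "te_class": ""})
    states = _chromatin_states(config, features, fac_genes)
    return features, states


def _gene_parts(rng, chrom, start, end, strand, gid) -> list[dict]:
    """UTR / exon / intron substructure inside a gene interval."""
    length = end - start
    utr5 = max(50, min(200, length // 10))
    utr3 = max(50, min(250, length // 10))
    if strand == "+":
        u5 = (start, start + utr5)
        u3 = (end - utr3, end)
        cds = (start + utr5, end - utr3)
    else:
        u5 = (end - utr5, end)
        u3 = (start, start + utr3)
        cds = (start + utr3, end - utr5)
    rows = [
        dict(chrom=chrom, start=u5[0], end=u5[1], kind="five_prime_UTR",
             id=f"{gid}.5utr", strand=strand, parent=gid),
        dict(chrom=chrom, start=u3[0], end=u3[1], kind="three_prime_UTR",
             id=f"{gid}.3utr", strand=strand, parent=gid),
    ]
    cds_len = cds[1] - cds[0]
    n_exons = int(rng.integers(1, 6))
    n_exons = max(1, min(n_exons, cds_len // 200))
    # alternate exon/intron blocks of random positive lengths
    n_blocks = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_blocks - 1, replace=False)) \
        if n_blocks > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [cds_len]]) + cds[0]
    for b in range(n_blocks):
        kind = "exon" if b % 2 == 0 else "intron"
        rows.append(dict(chrom=chrom, start=int(bounds[b]), end=int(bounds[b + 1]),
                         kind=kind, id=f"{gid}.{kind}{b // 2 + 1}", strand=strand,
                         parent=gid))
    return rows


def _promoter(start, end, strand, width, chrom_len) -> tuple[int, int]:
    if strand == "+":
        return max(0, start - width), start
    return end, min(chrom_len, end + width)


def _chromatin_states(config, features, fac_genes) -> pd.DataFrame:
    """Partition each chromosome: TEs -> constitutive het, a random subset
    of genes -> facultative het, other genes -> euchromatin, remainder ->
    the intergenic state."""
    rows = []
    for chrom, length in sorted(config.chrom_lengths().items()):
        sub = features[features["chrom"] == chrom]
        kind_ivs = {
            "constitutive_het": [
                (r.start, r.end) for r in sub[sub["kind"] == "TE"].itertuples()
            ],
            "facultative_het": [
                (r.start, r.end)
                for r in sub[(sub["kind"] == "gene") & sub["id"].isin(fac_genes)].itertuples()
            ],
            "euchromatin": [
                (r.start, r.end)
                for r in sub[(sub["kind"] == "gene") & ~sub["id"].isin(fac_genes)].itertuples()
            ],
        }
        proj = precedence_projection(
            kind_ivs,
            ["constitutive_het", "facultative_het", "euchromatin"],
            length,
            remainder_kind="intergenic_state",
        )
        for state, ivs in proj.items():
            rows.extend(dict(chrom=chrom, start=s, end=e, state=state) for s, e in ivs)
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# truth planting


@dataclass
class TruthTable:
    """Planted ground truth: DMRs, DEGs and concordant TE-gene links."""

    dmrs: pd.DataFrame    # chrom,start,end,context,comparison,effect,target_kind,target_id
    degs: pd.DataFrame    # gene_id, comparison, log2_fc
    links: pd.DataFrame   # te_id, gene_id, comparison, distance, concordant

    def check_consistent(self, features: pd.DataFrame, genome_length: int) -> None:
        if len(self.dmrs):
            if (self.dmrs["start"] < 0).any() or (self.dmrs["end"] > genome_length).any():
                raise ValueError("planted DMR outside genome bounds")
        te_dmr_ids = set(self.dmrs.loc[self.dmrs["target_kind"] == "TE", "target_id"])
        deg_ids = set(zip(self.degs["gene_id"], self.degs["comparison"]))
        for r in self.links.itertuples():
            if r.te_id not in te_dmr_ids:
                raise ValueError(f"link references non-planted TE {r.te_id}")
            if (r.gene_id, r.comparison) not in deg_ids:
                raise ValueError(f"link references non-planted DEG {r.gene_id}")

    def to_json(self, path) -> None:
        payload = {
            "dmrs": self.dmrs.to_dict(orient="records"),
            "degs": self.degs.to_dict(orient="records"),
            "links": self.links.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            dmrs=pd.DataFrame(d["dmrs"], columns=_TRUTH_DMR_COLS),
            degs=pd.DataFrame(d["degs"], columns=_TRUTH_DEG_COLS),
            links=pd.DataFrame(d["links"], columns=_TRUTH_LINK_COLS),
        )


_TRUTH_DMR_COLS = ["chrom", "start", "end", "context", "comparison", "effect",
                   "target_kind", "target_id"]
_TRUTH_DEG_COLS = ["gene_id", "comparison", "log2_fc"]
_TRUTH_LINK_COLS = ["te_id", "gene_id", "comparison", "distance", "concordant"]


def plan_truth(config: SimConfig, features: pd.DataFrame) -> TruthTable:
    """Place planted DMRs (mostly in TEs), DEGs, and concordant TE-gene links.

    Targets are sampled without replacement across comparisons so planted
    effects never stack on one feature. For a fraction
    ``frac_concordant_links`` of each comparison's TE DMRs, a TE with a
    gene within ``link_distance`` is chosen and that gene is planted as a
    DEG whose fold-change sign opposes the methylation change.
    """
    rng = _rng(config, 2)
    genes = features[features["kind"] == "gene"].reset_index(drop=True)
    tes = features[features["kind"] == "TE"].reset_index(drop=True)

    # nearest gene (gap) per TE, for concordant-link placement
    te_near: dict[str, tuple[str, int]] = {}
    for chrom, gsub in genes.groupby("chrom"):
        tsub = tes[tes["chrom"] == chrom]
        gs, ge = gsub["start"].to_numpy(), gsub["end"].to_numpy()
        for r in tsub.itertuples():
            gaps = np.maximum(np.maximum(gs - r.end, r.start - ge), 0)
            j = int(np.argmin(gaps)) if len(gaps) else -1
            if j >= 0 and gaps[j] <= config.link_distance:
                te_near[r.id] = (gsub["id"].iloc[j], int(gaps[j]))

    used_tes: set[str] = set()
    used_genes: set[str] = set()
    dmr_rows, deg_rows, link_rows = [], [], []
    contexts = list(config.dmr_context_probs)
    ctx_p = [config.dmr_context_probs[c] for c in contexts]

    for comp in config.comparisons:
        n = config.n_dmrs_planted
        n_te = round(n * config.dmr_target_fracs.get("TE", 0.7))
        n_gene = round(n * config.dmr_target_fracs.get("gene", 0.2))
        n_inter = n - n_te - n_gene
        n_linked = round(n_te * config.frac_concordant_links)

        linkable = [t for t in te_near if t not in used_tes]
        rng.shuffle(linkable)
        chosen_linked = linkable[:n_linked]
        other_pool = [t for t in tes["id"] if t not in used_tes and t not in chosen_linked]
        rng.shuffle(other_pool)
        chosen_tes = chosen_linked + other_pool[: n_te - len(chosen_linked)]
        used_tes.update(chosen_tes)

        gene_pool = [g for g in genes["id"] if g not in used_genes]
        rng.shuffle(gene_pool)
        chosen_genes = gene_pool[:n_gene]
        used_genes.update(chosen_genes)

        te_by_id = tes.set_index("id")
        gene_by_id = genes.set_index("id")

        comp_degs: dict[str, float] = {}
        for tid in chosen_tes:
            row = te_by_id.loc[tid]
            ctx = rng.choice(contexts, p=ctx_p)
            start, end = _dmr_interval(rng, row.start, row.end, config.dmr_length)
            eff = _feasible_effect(rng, config.te_baseline_meth[ctx], config.dmr_effect)
            dmr_rows.append(dict(chrom=row.chrom, start=start, end=end, context=ctx,
                                 comparison=comp, effect=eff, target_kind="TE",
                                 target_id=tid))
            if tid in chosen_linked:
                gid, dist = te_near[tid]
                lfc = -math.copysign(config.deg_lfc, eff)
                comp_degs[gid] = lfc
                used_genes.add(gid)
                link_rows.append(dict(te_id=tid, gene_id=gid, comparison=comp,
                                      distance=dist, concordant=True))
        for gid in chosen_genes:
            row = gene_by_id.loc[gid]
            ctx = rng.choice(contexts, p=ctx_p)
            start, end = _dmr_interval(rng, row.start, row.end, config.dmr_length)
            eff = _feasible_effect(rng, config.baseline_meth[ctx], config.dmr_effect)
            dmr_rows.append(dict(chrom=row.chrom, start=start, end=end, context=ctx,
                                 comparison=comp, effect=eff, target_kind="gene",
                                 target_id=gid))
        # intergenic placements: gaps between features
        inter = _intergenic_gaps(config, features)
        rng.shuffle(inter)
        placed = 0
        for chrom, s, e in inter:
            if placed >= n_inter:
                break
            if e - s < config.dmr_length:
                continue
            off = int(rng.integers(0, e - s - config.dmr_length + 1))
            ctx = rng.choice(contexts, p=ctx_p)
            eff = _feasible_effect(rng, config.baseline_meth[ctx], config.dmr_effect)
            dmr_rows.append(dict(chrom=chrom, start=s + off, end=s + off + config.dmr_length,
                                 context=ctx, comparison=comp, effect=eff,
                                 target_kind="intergenic",
                                 target_id=f"inter_{comp}_{placed}"))
            placed += 1

        # remaining DEGs beyond the link-driven ones
        extra_pool = [g for g in genes["id"] if g not in used_genes]
        rng.shuffle(extra_pool)
        for gid in extra_pool[: max(0, config.n_degs_planted - len(comp_degs))]:
            comp_degs[gid] = float(rng.choice([-1.0, 1.0])) * config.deg_lfc
            used_genes.add(gid)
        deg_rows.extend(
            dict(gene_id=g, comparison=comp, log2_fc=l) for g, l in comp_degs.items()
        )

    truth = TruthTable(
        dmrs=pd.DataFrame(dmr_rows, columns=_TRUTH_DMR_COLS),
        degs=pd.DataFrame(deg_rows, columns=_TRUTH_DEG_COLS),
        links=pd.DataFrame(link_rows, columns=_TRUTH_LINK_COLS),
    )
    truth.check_consistent(features, config.genome_length)
    return truth


def plan_expression_truth(
    config: SimConfig, gene_ids: list[str] | None = None
) -> TruthTable:
    """Expression-only truth: plant ``n_degs_planted`` DEGs per active
    comparison (sign random, magnitude ``deg_lfc``), no genome needed.

    For power/calibration studies of the differential-expression stage in
    isolation; genes are sampled without replacement across comparisons.
    """
    rng = _rng(config, 2)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    pool = list(gene_ids)
    rng.shuffle(pool)
    rows = []
    for comp in config.comparisons:
        take, pool = pool[: config.n_degs_planted], pool[config.n_degs_planted:]
        if len(take) < config.n_degs_planted:
            raise ValueError("not enough genes to plant the requested DEGs")
        signs = rng.choice([-1.0, 1.0], size=len(take))
        rows.extend(
            dict(gene_id=g, comparison=comp, log2_fc=float(s) * config.deg_lfc)
            for g, s in zip(take, signs)
        )
    return TruthTable(
        dmrs=pd.DataFrame(columns=_TRUTH_DMR_COLS),
        degs=pd.DataFrame(rows, columns=_TRUTH_DEG_COLS),
        links=pd.DataFrame(columns=_TRUTH_LINK_COLS),
    )


def _dmr_interval(rng, f_start, f_end, dmr_length) -> tuple[int, int]:
    length = min(dmr_length, f_end - f_start)
    off = int(rng.integers(0, f_end - f_start - length + 1))
    return int(f_start + off), int(f_start + off + length)


def _feasible_effect(rng, baseline: float, effect: float) -> float:
    """Random-sign effect, flipped if it would push the proportion past [0.02, 0.98]."""
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if not 0.02 <= baseline + sign * effect <= 0.98:
        sign = -sign
    return sign * effect


def _intergenic_gaps(config, features) -> list[tuple[str, int, int]]:
    out = []
    for chrom, length in sorted(config.chrom_lengths().items()):
        sub = features[(features["chrom"] == chrom) & features["kind"].isin(["gene", "TE", "promoter"])]
        ivs = sorted((int(r.start), int(r.end)) for r in sub.itertuples())
        cur = 0
        for s, e in ivs:
            if s > cur:
                out.append((chrom, cur, s))
            cur = max(cur, e)
        if cur < length:
            out.append((chrom, cur, length))
    return out


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    config: SimConfig, features: pd.DataFrame, truth: TruthTable
) -> dict[str, MethylomeTrack]:
    """One pooled cytosine-count track per condition.

    Per cytosine: coverage ~ Poisson(coverage_mean) and methylated reads
    ~ Binomial(coverage, p), where p is the context baseline (TE-elevated
    inside TEs) shifted by any planted DMR effect applying to that
    condition, clamped into [0, 1] with a warning.

    Only conditions participating in ``config.comparisons`` are generated.
    """
    rng = _rng(config, 3)
    chroms = sorted(config.chrom_lengths())
    pos_all, chrom_all, strand_all, ctx_all, p_base_all = [], [], [], [], []
    contexts = list(config.context_probs)
    cprobs = [config.context_probs[c] for c in contexts]
    tes = features[features["kind"] == "TE"]

    for chrom in chroms:
        length = config.genome_length
        n_cyt = int(round(length * config.cytosine_density))
        pos0 = np.sort(rng.choice(length, size=n_cyt, replace=False))
        strand = np.where(rng.random(n_cyt) < 0.5, "+", "-")
        ctx = rng.choice(contexts, size=n_cyt, p=cprobs)
        in_te = np.zeros(n_cyt, dtype=bool)
        tsub = tes[tes["chrom"] == chrom]
        if len(tsub):
            starts = tsub["start"].to_numpy()
            ends = tsub["end"].to_numpy()
            idx = np.searchsorted(starts, pos0, side="right") - 1
            valid = idx >= 0
            in_te[valid] = pos0[valid] < ends[idx[valid]]
        p = np.empty(n_cyt)
        for c in CONTEXTS:
            m = ctx == c
            p[m] = np.where(in_te[m], config.te_baseline_meth[c], config.baseline_meth[c])
        pos_all.append(pos0)
        chrom_all.append(np.full(n_cyt, chrom))
        strand_all.append(strand)
        ctx_all.append(ctx)
        p_base_all.append(p)

    pos0 = np.concatenate(pos_all)
    chrom = np.concatenate(chrom_all)
    strand = np.concatenate(strand_all)
    ctx = np.concatenate(ctx_all)
    p_base = np.concatenate(p_base_all)

    # per-chromosome slice bounds (cytosines are concatenated in chrom order,
    # sorted by position within each chromosome)
    offsets: dict[str, tuple[int, int]] = {}
    cursor = 0
    for ch, block in zip(chroms, pos_all):
        offsets[ch] = (cursor, cursor + len(block))
        cursor += len(block)

    active = sorted(
        {c for comp in config.comparisons for c in COMPARISONS[comp]},
        key=CONDITIONS.index,
    )
    p_cond = {c: p_base.copy() for c in active}
    for r in truth.dmrs.itertuples():
        if r.comparison not in config.comparisons:
            continue
        target = COMPARISONS[r.comparison][1]
        if target not in p_cond or r.chrom not in offsets:
            continue
        lo, hi = offsets[r.chrom]
        i = lo + np.searchsorted(pos0[lo:hi], r.start, side="left")
        j = lo + np.searchsorted(pos0[lo:hi], r.end, side="left")
        sel = np.arange(i, j)[ctx[i:j] == r.context]
        p_cond[target][sel] += r.effect

    # categorical string columns are built once and shared: constructing
    # four 700k-row frames from object arrays would dominate the runtime
    chrom_cat = pd.Categorical(chrom)
    strand_cat = pd.Categorical(strand)
    ctx_cat = pd.Categorical(ctx)
    tri_cat = ctx_cat.rename_categories({c: _TRI[c] for c in ctx_cat.categories})
    pos1 = pos0 + 1  # CX reports are 1-based

    tracks: dict[str, MethylomeTrack] = {}
    for cond in active:
        p = p_cond[cond]
        n_clamped = int(((p < 0) | (p > 1)).sum())
        if n_clamped:
            warnings.warn(
                f"{cond}: clamped {n_clamped} cytosine proportions into [0, 1]"
            )
        p = np.clip(p, 0.0, 1.0)
        cov = rng.poisson(config.coverage_mean, size=len(p))
        meth = rng.binomial(cov, p)
        df = pd.DataFrame(
            {
                "chrom": chrom_cat,
                "pos": pos1,
                "strand": strand_cat,
                "meth": meth,
                "unmeth": cov - meth,
                "context": ctx_cat,
                "tri": tri_cat,
            }
        )
        tracks[cond] = MethylomeTrack(df, condition=cond)
    return tracks


# ---------------------------------------------------------------------------
# RNA counts


def simulate_counts(
    config: SimConfig, truth: TruthTable, gene_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample count matrix (n_replicates per condition) plus sample sheet.

    counts ~ NegativeBinomial(mean = baseline * 2^lfc * library factor,
    dispersion = nb_dispersion); dispersion 0 degenerates to Poisson.
    Baselines are lognormal around ``mean_expression``; library factors
    lognormal with sd ``libsize_log_sd``. A gene planted for comparison
    (X, Y) has its mean multiplied by 2^lfc in condition Y.
    """
    rng = _rng(config, 4)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    n_genes = len(gene_ids)
    base = rng.lognormal(math.log(config.mean_expression), config.expression_log_sd,
                         size=n_genes)
    samples = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(config.n_replicates)]
    sample_cond = [cond for cond in CONDITIONS for _ in range(config.n_replicates)]
    lib = rng.lognormal(0.0, config.libsize_log_sd, size=len(samples))

    lfc = {cond: np.zeros(n_genes) for cond in CONDITIONS}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for r in truth.degs.itertuples():
        target = COMPARISONS[r.comparison][1]
        i = gene_index.get(r.gene_id)
        if i is not None:
            lfc[target][i] += r.log2_fc

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for s, (name, cond) in enumerate(zip(samples, sample_cond)):
        mu = base * np.exp2(lfc[cond]) * lib[s]
        if config.nb_dispersion > 0:
            size = 1.0 / config.nb_dispersion
            counts[:, s] = rng.negative_binomial(size, size / (size + mu))
        else:
            counts[:, s] = rng.poisson(mu)
    matrix = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=samples)
    sheet = pd.DataFrame({"sample": samples, "condition": sample_cond})
    return matrix, sheet


# ---------------------------------------------------------------------------
# writers / bundle


@dataclass
class StudyBundle:
    config: SimConfig
    features: pd.DataFrame
    states: pd.DataFrame
    truth: TruthTable
    tracks: dict[str, MethylomeTrack]
    counts: pd.DataFrame
    samples: pd.DataFrame


def simulate_study(config: SimConfig) -> StudyBundle:
    """Run every generation stage under one seed."""
    features, states = simulate_annotation(config)
    truth = plan_truth(config, features)
    tracks = simulate_methylomes(config, features, truth)
    genes = features.loc[features["kind"] == "gene", "id"].tolist()
    counts, samples = simulate_counts(config, truth, gene_ids=genes)
    return StudyBundle(config, features, states, truth, tracks, counts, samples)


def write_gff3(features: pd.DataFrame, path) -> None:
    """Genes and their parts as GFF3 (1-based inclusive on disk)."""
    kinds = ["gene", "five_prime_UTR", "exon", "intron", "three_prime_UTR"]
    sub = features[features["kind"].isin(kinds)]
    sub = sub.sort_values(["chrom", "start", "kind"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sub.itertuples():
            attr = f"ID={r.id}" + (f";Parent={r.parent}" if r.parent else "")
            fh.write(
                f"{r.chrom}\tlightmeth\t{r.kind}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attr}\n"
            )


def write_te_bed(features: pd.DataFrame, path) -> None:
    """TEs as BED6; name = family|superfamily|class."""
    sub = features[features["kind"] == "TE"].sort_values(
        ["chrom", "start"], kind="mergesort"
    )
    with open(path, "w") as fh:
        for r in sub.itertuples():
            name = f"{r.te_family}|{r.te_superfamily}|{r.te_class}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def write_state_bed(states: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in states.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")


def write_study(bundle: StudyBundle, outdir) -> dict[str, str]:
    """Write every artefact of a simulated study; returns name -> path."""
    from pathlib import Path

    from .methylation import write_cx_report

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_gff3(bundle.features, out / "genes.gff3")
    paths["gff3"] = str(out / "genes.gff3")
    write_te_bed(bundle.features, out / "tes.bed")
    paths["te_bed"] = str(out / "tes.bed")
    write_state_bed(bundle.states, out / "chromatin_states.bed")
    paths["state_bed"] = str(out / "chromatin_states.bed")
    for cond, track in bundle.tracks.items():
        p = out / f"{cond}.cx.tsv"
        write_cx_report(track, p)
        paths[f"cx_{cond}"] = str(p)
    bundle.counts.to_csv(out / "counts.tsv", sep="\t")
    paths["counts"] = str(out / "counts.tsv")
    bundle.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    paths["samples"] = str(out / "samples.tsv")
    bundle.truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    cfg_dict = asdict(bundle.config)
    cfg_dict["comparisons"] = list(cfg_dict["comparisons"])
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    paths["config"] = str(out / "sim_config.yaml")
    return paths
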