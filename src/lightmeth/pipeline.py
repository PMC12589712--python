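"""End-to-end orchestration: profiles -> DMRs -> enrichment -> DE ->
classification -> overlaps -> TE links -> correlations.

Outputs are a pure function of (inputs, config); the run log records
every parameter and the SHA-256 of every input so fixture regressions
are detectable, and contains no wall-clock state (reruns are
byte-identical).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import dmr as dmr_mod
from . import enrichment as enr
from . import integration as integ
from .methylation import CONTEXTS, lowres_profile, read_cx_report, write_bedgraph
from .simulate import COMPARISONS

LINK_WINDOWS = (1000, 2000, 5000)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    cx: dict                      # condition -> CX report path (all four)
    counts: str
    samples: str
    gff3: str
    te_bed: str
    state_bed: str
    outdir: str
    dmr: dict = field(default_factory=dict)       # DmrParams overrides
    p_adj_threshold: float = 0.05
    lfc_threshold: float = 0.5
    link_windows: tuple = LINK_WINDOWS
    profile_window: int = 100_000
    promoter_bp: int = 1000
    seed: int = 0
    chrom_lengths: dict | None = None

    def __post_init__(self) -> None:
        missing = set(COMPARISONS_CONDS) - set(self.cx)
        if missing:
            raise ValueError(f"cx paths missing conditions: {sorted(missing)}")
        self.link_windows = tuple(int(w) for w in self.link_windows)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        paths = [*self.cx.values(), self.counts, self.samples, self.gff3,
                 self.te_bed, self.state_bed]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError(f"validation: missing inputs: {missing}")

    def input_paths(self) -> dict[str, str]:
        d = {f"cx_{c}": p for c, p in sorted(self.cx.items())}
        d.update(counts=self.counts, samples=self.samples, gff3=self.gff3,
                 te_bed=self.te_bed, state_bed=self.state_bed)
        return d


COMPARISONS_CONDS = ("SQH", "SQL", "FLH", "FLL")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dict."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["lightmeth pipeline run"]
    log.append("parameters: " + json.dumps(
        {k: v for k, v in asdict(config).items() if k != "cx"}, sort_keys=True,
        default=str))
    for name, path in config.input_paths().items():
        log.append(f"input {name} {path} sha256={_sha256(path)}")

    stage = "read inputs"
    try:
        tracks = {c: read_cx_report(p, condition=c) for c, p in config.cx.items()}
        features = enr.load_annotation(config.gff3, config.te_bed)
        states = enr.read_state_bed(config.state_bed)
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        samples = pd.read_csv(config.samples, sep="\t")

        chrom_lengths = config.chrom_lengths or _derive_chrom_lengths(tracks, features, states)
        params = dmr_mod.DmrParams(**config.dmr)

        stage = "profiles"
        for cond, track in sorted(tracks.items()):
            for ctx in CONTEXTS:
                prof = lowres_profile(track, ctx, config.profile_window, chrom_lengths)
                write_bedgraph(prof, out / f"profile_{cond}_{ctx}.bedgraph")

        stage = "dmr calling"
        dmrs: dict[str, dict[str, pd.DataFrame]] = {}
        for comp, (a, b) in COMPARISONS.items():
            dmrs[comp] = {}
            for ctx in CONTEXTS:
                d = dmr_mod.call_dmrs(tracks[a], tracks[b], ctx, params)
                dmrs[comp][ctx] = d
                dmr_mod.write_dmrs(
                    d, out / f"dmrs_{comp}_{ctx}.tsv", out / f"dmrs_{comp}_{ctx}.bed"
                )

        stage = "annotation and enrichment"
        enrich_tables = {}
        for comp in COMPARISONS:
            alld = pd.concat(
                [dmrs[comp][c] for c in CONTEXTS if len(dmrs[comp][c])],
                ignore_index=True,
            ) if any(len(dmrs[comp][c]) for c in CONTEXTS) else pd.DataFrame(
                columns=dmr_mod.DMR_COLUMNS
            )
            if len(alld):
                ann = enr.annotate_dmrs(alld, features)
                ann.to_csv(out / f"dmrs_annotated_{comp}.tsv", sep="\t", index=False)
                ftab = enr.feature_enrichment(ann, features, chrom_lengths)
                ftab.to_csv(out / f"enrichment_features_{comp}.tsv", sep="\t", index=False)
                stab = enr.te_superfamily_enrichment(ann, features)
                stab.to_csv(out / f"enrichment_te_{comp}.tsv", sep="\t", index=False)
                enrich_tables[comp] = ftab
            else:
                enrich_tables[comp] = pd.DataFrame()

        stage = "differential expression"
        de_results = {}
        for comp, (a, b) in COMPARISONS.items():
            res = de_mod.fit_de(counts, samples, a, b)
            res = de_mod.call_degs(res, config.p_adj_threshold, config.lfc_threshold)
            res.to_csv(out / f"de_{comp}.tsv", sep="\t", index=False)
            de_results[comp] = res

        stage = "classification"
        dm_sets = {comp: integ.dm_feature_ids(dmrs[comp], features) for comp in COMPARISONS}
        deg_sets = {
            comp: set(r.loc[r["is_deg"], "gene"]) for comp, r in de_results.items()
        }
        meth_classes = integ.classify_light_features(dm_sets)
        expr_classes = integ.classify_light_features(deg_sets)
        _write_classes(meth_classes, out / "light_classes_methylation.tsv")
        _write_classes(expr_classes, out / "light_classes_expression.tsv")

        stage = "dmr-deg overlap"
        overlaps = {}
        for comp in COMPARISONS:
            alld = pd.concat(
                [dmrs[comp][c] for c in CONTEXTS if len(dmrs[comp][c])],
                ignore_index=True,
            ) if any(len(dmrs[comp][c]) for c in CONTEXTS) else pd.DataFrame(
                columns=dmr_mod.DMR_COLUMNS
            )
            ov = {}
            for region in ("gene_body", "promoter"):
                o = integ.overlap_dmr_deg(
                    alld, de_results[comp], features, region, config.promoter_bp
                )
                ov[region] = dict(
                    n_both=len(o["genes"]), chi2=o["chi2"], p_value=o["p_value"],
                    reliable=o["reliable"], table=o["table"].tolist(),
                )
            overlaps[comp] = ov

        stage = "te links"
        link_counts = {}
        correlations = {}
        for comp in COMPARISONS:
            alld = pd.concat(
                [dmrs[comp][c] for c in CONTEXTS if len(dmrs[comp][c])],
                ignore_index=True,
            ) if any(len(dmrs[comp][c]) for c in CONTEXTS) else pd.DataFrame(
                columns=dmr_mod.DMR_COLUMNS
            )
            changes = integ.te_methylation_change(alld, features)
            degs = de_results[comp]
            lfc = degs.loc[degs["is_deg"]].set_index("gene")["log2_fc"]
            link_counts[comp] = {}
            for w in config.link_windows:
                links = integ.link_te_to_genes(
                    changes, features, lfc, w, te_features=features, states=states
                )
                link_counts[comp][str(w)] = dict(
                    n_links=len(links),
                    n_tes=int(links["te_id"].nunique()) if len(links) else 0,
                    n_genes=int(links["gene_id"].nunique()) if len(links) else 0,
                    n_concordant=int(links["concordant"].sum()) if len(links) else 0,
                )
                if w == max(config.link_windows):
                    links.to_csv(out / f"links_{comp}.tsv", sep="\t", index=False)
                    cors = []
                    for strat in ("none", "chromatin_state", "te_class"):
                        c = integ.meth_expr_correlation(links, strat)
                        c.insert(0, "stratify_by", strat)
                        cors.append(c)
                    cor = pd.concat(cors, ignore_index=True)
                    cor.to_csv(out / f"correlations_{comp}.tsv", sep="\t", index=False)
                    correlations[comp] = cor.to_dict(orient="records")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    summary = {
        "dmr_counts": {
            comp: {ctx: int(len(dmrs[comp][ctx])) for ctx in CONTEXTS}
            for comp in COMPARISONS
        },
        "deg_counts": {comp: int(r["is_deg"].sum()) for comp, r in de_results.items()},
        "light_classes_methylation": {k: len(v) for k, v in meth_classes.items()},
        "light_classes_expression": {k: len(v) for k, v in expr_classes.items()},
        "dmr_deg_overlap": overlaps,
        "te_links": link_counts,
        "correlations": correlations,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.append("summary written")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _derive_chrom_lengths(tracks, features, states) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for df, end_col in [(features, "end"), (states, "end")]:
        for chrom, g in df.groupby("chrom"):
            lengths[chrom] = max(lengths.get(chrom, 0), int(g[end_col].max()))
    for track in tracks.values():
        for chrom, g in track.records.groupby("chrom", observed=True):
            lengths[str(chrom)] = max(lengths.get(str(chrom), 0), int(g["pos"].max()))
    return lengths


def _write_classes(classes: dict[str, set], path) -> None:
    rows = [
        {"feature_id": fid, "light_class": name}
        for name, ids in sorted(classes.items())
        for fid in sorted(ids)
    ]
    pd.DataFrame(rows, columns=["feature_id", "light_class"]).to_csv(
        path, sep="\t", index=False
    )
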