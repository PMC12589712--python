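"""Cytosine-level methylation I/O and low-resolution chromosome profiles.

The on-disk dialect is the Bismark-style per-cytosine ("CX") report: a
7-column TSV with chromosome, 1-based position, strand, methylated read
count, unmethylated read count, sequence context (CG/CHG/CHH) and the
trinucleotide. In memory, contexts are spelled CpG/CpHpG/CpHpH (H = A, C
or T) and records are kept sorted by (chrom, pos).

Zero-coverage cytosines are retained: a position with no reads is
information about missingness, and the binned DMR caller and the profile
code both distinguish "no data" from "0% methylated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: file spelling -> in-memory spelling
CONTEXT_FROM_FILE = {"CG": "CpG", "CHG": "CpHpG", "CHH": "CpHpH"}
CONTEXT_TO_FILE = {v: k for k, v in CONTEXT_FROM_FILE.items()}
CONTEXTS = ("CpG", "CpHpG", "CpHpH")

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


class CxFormatError(ValueError):
    """Raised when a CX report line cannot be parsed."""


@dataclass
class CytosineRecord:
    """One cytosine's observation in one sample."""

    chrom: str
    pos: int  # 1-based
    strand: str
    meth: int
    unmeth: int
    context: str

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


@dataclass
class MethylomeTrack:
    """All cytosine observations of one (pooled) sample.

    ``records`` is a DataFrame with columns chrom, pos (1-based), strand,
    meth, unmeth, context, tri — sorted by (chrom, pos) with unique
    (chrom, pos, strand) keys.
    """

    records: pd.DataFrame
    condition: str | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in CX_COLUMNS if c not in df.columns and c != "tri"]
        if missing:
            raise ValueError(f"track missing columns: {missing}")
        if "tri" not in df.columns:
            df = df.assign(tri="NNN")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
            drop=True
        )
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys in track")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.records[self.records["context"] == context]


def read_cx_report(path, condition: str | None = None) -> MethylomeTrack:
    """Parse a 7-column CX report into a :class:`MethylomeTrack`.

    Contexts CG/CHG/CHH are mapped to CpG/CpHpG/CpHpH; records are
    sorted; zero-coverage rows are kept. Malformed lines raise
    :class:`CxFormatError` with the offending 1-based line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "meth": np.int64,
                "unmeth": np.int64,
                "context": str,
                "tri": str,
            },
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty CX report: {path}")
        df = pd.DataFrame(columns=CX_COLUMNS).astype({"pos": int, "meth": int, "unmeth": int})
        return MethylomeTrack(df, condition)
    except (ValueError, pd.errors.ParserError):
        _raise_with_line_number(path)
    if df.empty:
        warnings.warn(f"empty CX report: {path}")
        return MethylomeTrack(df, condition)
    bad = ~df["context"].isin(CONTEXT_FROM_FILE)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise CxFormatError(
            f"{path}: unknown context {df.loc[bad, 'context'].iloc[0]!r} at line {line}"
        )
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise CxFormatError(f"{path}: negative read counts")
    df["context"] = df["context"].map(CONTEXT_FROM_FILE)
    for col in ("chrom", "strand", "context", "tri"):
        df[col] = df[col].astype("category")
    return MethylomeTrack(df, condition)


def _raise_with_line_number(path) -> None:
    """Re-scan a malformed file line by line to report where it breaks."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise CxFormatError(
                    f"{path}: expected 7 tab-separated fields at line {i}, got {len(parts)}"
                )
            try:
                int(parts[1]), int(parts[3]), int(parts[4])
            except ValueError:
                raise CxFormatError(f"{path}: non-integer field at line {i}") from None
    raise CxFormatError(f"{path}: malformed CX report")


def write_cx_report(track: MethylomeTrack, path) -> None:
    """Write a track back to the 7-column CX dialect (file context spelling)."""
    df = track.records.copy()
    df["context"] = df["context"].map(CONTEXT_TO_FILE)
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def collapse_symmetric_strands(track: MethylomeTrack) -> MethylomeTrack:
    """Merge read counts of symmetric CpG (pos, pos+1) and CpHpG (pos, pos+2)
    strand pairs onto the + strand record.

    Off by default throughout the pipeline: the binned caller pools all
    counts in a bin regardless, and collapsing halves the cytosine count
    that the min-cytosine filter sees.
    """
    df = track.records.copy()
    offset = {"CpG": 1, "CpHpG": 2}
    drop = np.zeros(len(df), dtype=bool)
    key = {
        (c, p, s): i
        for i, (c, p, s) in enumerate(zip(df["chrom"], df["pos"], df["strand"]))
    }
    meth = df["meth"].to_numpy().copy()
    unmeth = df["unmeth"].to_numpy().copy()
    ctx = df["context"].to_numpy()
    for i, (c, p, s, cx) in enumerate(
        zip(df["chrom"], df["pos"], df["strand"], df["context"])
    ):
        if s != "+" or cx not in offset:
            continue
        j = key.get((c, p + offset[cx], "-"))
        if j is not None and ctx[j] == cx:
            meth[i] += meth[j]
            unmeth[i] += unmeth[j]
            drop[j] = True
    df["meth"], df["unmeth"] = meth, unmeth
    return MethylomeTrack(df[~drop].reset_index(drop=True), track.condition)


def lowres_profile(
    track: MethylomeTrack,
    context: str,
    window_bp: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window weighted methylation proportion along each chromosome.

    proportion = sum(meth) / sum(meth + unmeth) over the window's
    cytosines of the requested context; windows with no covered cytosine
    are NaN (missing), never 0.

    Returns a DataFrame (chrom, start, end, n_cytosines, meth, total,
    proportion) with 0-based half-open windows.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sub = track.subset(context)
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(g["pos"].max())
            for c, g in sub.groupby("chrom", sort=True, observed=True)
        }
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = max(1, -(-length // window_bp))
        g = sub[sub["chrom"] == chrom]
        win = np.minimum((g["pos"].to_numpy() - 1) // window_bp, n_win - 1)
        meth = np.bincount(win, weights=g["meth"].to_numpy(), minlength=n_win)
        tot = np.bincount(
            win, weights=(g["meth"] + g["unmeth"]).to_numpy(), minlength=n_win
        )
        ncyt = np.bincount(win, minlength=n_win)
        starts = np.arange(n_win) * window_bp
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(tot > 0, meth / np.where(tot > 0, tot, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_bp, length),
                    "n_cytosines": ncyt,
                    "meth": meth.astype(int),
                    "total": tot.astype(int),
                    "proportion": prop,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "n_cytosines", "meth", "total", "proportion"]
    )


def write_bedgraph(profile: pd.DataFrame, path) -> None:
    """Write a profile as bedGraph (0-based half-open); missing windows skipped."""
    ok = profile.dropna(subset=["proportion"])
    with open(path, "w") as fh:
        for row in ok.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.proportion:.6g}\n")
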