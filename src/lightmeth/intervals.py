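"""Small interval-arithmetic helpers on 0-based half-open coordinates.

These cover the pieces the annotation/enrichment steps need that no
installed range library exposes directly: interval-set union/subtraction
and the precedence projection that partitions a chromosome among feature
kinds. Feature counts here are small (thousands), so plain sorted-list
sweeps are ample.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted, disjoint list. Empty intervals dropped."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def subtract_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b; both inputs need not be disjoint."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def precedence_projection(
    kind_intervals: dict[str, list[tuple[int, int]]],
    precedence: list[str],
    chrom_length: int,
    remainder_kind: str = "intergenic",
) -> dict[str, list[tuple[int, int]]]:
    """Partition [0, chrom_length) among kinds by precedence.

    Each base is assigned to the highest-precedence kind covering it;
    uncovered bases go to ``remainder_kind``. The returned interval sets
    are disjoint and tile the chromosome exactly.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    covered: list[tuple[int, int]] = []
    for kind in precedence:
        ivs = merge_intervals(
            [(max(0, s), min(chrom_length, e)) for s, e in kind_intervals.get(kind, [])]
        )
        out[kind] = subtract_intervals(ivs, covered)
        covered = merge_intervals(covered + out[kind])
    out[remainder_kind] = subtract_intervals([(0, chrom_length)], covered)
    return out


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two intervals; 0 when they overlap or abut."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end, 0)


def overlap_length(a_start, a_end, b_start, b_end):
    """Vectorised overlap length of interval pairs (clipped at 0)."""
    return np.maximum(
        0, np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
    )
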