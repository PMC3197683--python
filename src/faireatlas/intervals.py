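"""Genomic interval algebra under BED half-open arithmetic.

Overlap requires at least one shared base: abutting intervals ([0,10) and
[10,20)) do not overlap and are never merged. All operations work on plain
``(chrom, start, end)`` triples or anything exposing ``chrom``/``start``/
``end`` attributes (peaks).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "as_interval",
    "overlap_pairs",
    "overlap_fraction",
    "merge_intervals",
    "extract_centers",
]

Interval = tuple[str, int, int]


def as_interval(x) -> tuple[str, int, int, str]:
    """Normalize a peak-like object or tuple to (chrom, start, end, id)."""
    if hasattr(x, "chrom"):
        return (x.chrom, x.start, x.end, getattr(x, "peak_id", ""))
    chrom, start, end = x[0], x[1], x[2]
    ident = x[3] if len(x) > 3 else f"{chrom}:{start}-{end}"
    return (chrom, start, end, str(ident))


def _grouped(items) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    for x in items:
        chrom, start, end, ident = as_interval(x)
        out.setdefault(chrom, []).append((start, end, ident))
    for ivals in out.values():
        ivals.sort()
    return out


def overlap_pairs(a, b, min_overlap: int = 1) -> list[tuple[str, str, int]]:
    """All (a_id, b_id, shared_bp) pairs with at least ``min_overlap``
    shared bases, via a per-chromosome sorted sweep.

    Symmetric: swapping the roles of a and b swaps the pair orientation but
    reports the same pair set.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ga, gb = _grouped(a), _grouped(b)
    pairs: list[tuple[str, str, int]] = []
    for chrom in ga:
        if chrom not in gb:
            continue
        bs = gb[chrom]
        b_starts = np.array([s for s, _, _ in bs], dtype=np.int64)
        # sweep: for each a interval find candidate b intervals by start
        for a_start, a_end, a_id in ga[chrom]:
            hi = int(np.searchsorted(b_starts, a_end - min_overlap, side="right"))
            for b_start, b_end, b_id in bs[:hi]:
                shared = min(a_end, b_end) - max(a_start, b_start)
                if shared >= min_overlap:
                    pairs.append((a_id, b_id, shared))
    return pairs


def overlap_fraction(a, b) -> float:
    """Fraction of elements of ``a`` overlapping (>=1 bp) at least one
    element of ``b``. Invariant under merging or permuting ``b``."""
    ga = _grouped(a)
    n = sum(len(v) for v in ga.values())
    if n == 0:
        raise ValueError("overlap_fraction undefined for empty query set")
    merged = _grouped(merge_intervals(b))
    hit = 0
    for chrom, ivals in ga.items():
        if chrom not in merged:
            continue
        m = merged[chrom]
        m_starts = np.array([s for s, _, _ in m], dtype=np.int64)
        m_ends = np.array([e for _, e, _ in m], dtype=np.int64)
        for start, end, _ in ivals:
            i = int(np.searchsorted(m_ends, start, side="right"))
            if i < len(m_starts) and m_starts[i] < end:
                hit += 1
    return hit / n


def merge_intervals(x) -> list[Interval]:
    """Union of intervals: overlapping (>=1 shared bp) inputs are merged,
    abutting inputs are kept separate. Idempotent."""
    merged: list[Interval] = []
    for chrom, ivals in sorted(_grouped(x).items()):
        cur_s, cur_e = None, None
        for start, end, _ in ivals:
            if cur_s is None:
                cur_s, cur_e = start, end
            elif start < cur_e:  # strict: abutment (start == cur_e) not merged
                cur_e = max(cur_e, end)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = start, end
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


def extract_centers(
    peaks,
    width: int,
    chrom_lengths: dict[str, int] | None = None,
) -> list[Interval]:
    """Fixed-width windows centered on each peak's floor-midpoint.

    The window is [c - width//2, c - width//2 + width), clipped to
    [0, chrom_length) when chromosome lengths are provided (and to
    non-negative coordinates always). Clipped windows may be shorter than
    ``width``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out: list[Interval] = []
    for x in peaks:
        chrom, start, end, _ = as_interval(x)
        c = (start + end) // 2
        w_start = c - width // 2
        w_end = w_start + width
        w_start = max(w_start, 0)
        if chrom_lengths is not None and chrom in chrom_lengths:
            w_end = min(w_end, chrom_lengths[chrom])
        if w_end > w_start:
            out.append((chrom, w_start, w_end))
    return out
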