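"""Peak atlas construction: genomic context, cross-condition union peaks,
tertile-based condition specificity, and average signal profiles.

The specificity scheme ranks each union peak's signal within each condition
independently, cuts the detected peaks into tertiles (low/mid/high), and
labels each peak from its (tertile_A, tertile_B) cell in a 4x4 table whose
fourth row/column is "absent" (not detected in that condition). The default
label map calls a peak condition-specific only for a contrast of at least
two tertile steps (high vs low, or mid/high vs absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, Peak, PeakSet, SignalTrack
from .intervals import as_interval

__all__ = [
    "CATEGORIES",
    "UnionPeak",
    "SpecificityTable",
    "ProfileMatrix",
    "default_label_map",
    "classify_promoter",
    "genomic_distribution",
    "build_union_peaks",
    "tertile_specificity",
    "average_profile",
]

CATEGORIES = ("high", "mid", "low", "absent")
CONTEXTS = ("promoter", "proximal_upstream", "exon", "intron", "distal")


@dataclass(frozen=True)
class UnionPeak:
    """A maximal overlap-merged interval across both conditions' peak sets.

    Per-condition signal is the maximum over contributing peaks, 0 when the
    condition contributed nothing (then detected is False).
    """

    chrom: str
    start: int
    end: int
    union_id: str
    signal: tuple[float, float]
    detected: tuple[bool, bool]
    peak_ids: tuple[tuple[str, ...], tuple[str, ...]]

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ProfileMatrix:
    """Average per-base signal around a set of anchors, binned."""

    bin_edges: np.ndarray  # relative to anchor, length n_bins + 1
    values: np.ndarray  # mean signal per bin
    n_anchors: int


def default_label_map(cond_a: str, cond_b: str) -> dict[tuple[str, str], str]:
    """Default 4x4 cell -> label assignment.

    Specific calls require a >=2-step tertile contrast; cells with matched
    or one-step-apart occupancy are invariant; the rest are unclassified.
    """
    la, lb = f"specific_to_{cond_a}", f"specific_to_{cond_b}"
    m: dict[tuple[str, str], str] = {}
    for ca in CATEGORIES:
        for cb in CATEGORIES:
            m[(ca, cb)] = "unclassified"
    for ca, cb in (("high", "low"), ("high", "absent"), ("mid", "absent")):
        m[(ca, cb)] = la
        m[(cb, ca)] = lb
    for cell in (("high", "high"), ("high", "mid"), ("mid", "high"), ("mid", "mid"), ("low", "low")):
        m[cell] = "invariant"
    del m[("absent", "absent")]
    return m


class SpecificityTable:
    """Per-union-peak tertile categories and specificity labels.

    Backed by a DataFrame with columns chrom, start, end, union_id, cat_a,
    cat_b, label, signal_a, signal_b, peak_ids_a, peak_ids_b (ids
    comma-joined), indexed by union_id.
    """

    COLUMNS = [
        "chrom", "start", "end", "union_id", "cat_a", "cat_b",
        "label", "signal_a", "signal_b", "peak_ids_a", "peak_ids_b",
    ]

    def __init__(self, df: pd.DataFrame, conditions: tuple[str, str]) -> None:
        self.df = df.reset_index(drop=True)
        self.conditions = conditions

    def __len__(self) -> int:
        return len(self.df)

    def rows_with_label(self, label: str) -> pd.DataFrame:
        return self.df[self.df["label"] == label]

    def label_of(self, condition: str) -> str:
        if condition not in self.conditions:
            raise KeyError(condition)
        return f"specific_to_{condition}"

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, conditions: tuple[str, str]) -> "SpecificityTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        return cls(df, conditions)


def classify_promoter(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
    half_window: int = 500,
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks into (promoter, non_promoter) by whether the peak
    center lies within +/- half_window of any TSS, boundaries inclusive."""
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    if not list(genes):
        warnings.warn("empty gene collection: all peaks classified non-promoter", stacklevel=2)
        return [], list(peaks)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}
    promoter, non_promoter = [], []
    for p in peaks:
        tss = tss_by_chrom.get(p.chrom)
        is_prom = False
        if tss is not None and len(tss):
            i = int(np.searchsorted(tss, p.center))
            for j in (i - 1, i):
                if 0 <= j < len(tss) and abs(int(tss[j]) - p.center) <= half_window:
                    is_prom = True
                    break
        (promoter if is_prom else non_promoter).append(p)
    return promoter, non_promoter


def genomic_distribution(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_half_window: int = 500,
    upstream_window: int = 5000,
) -> tuple[dict[str, str], pd.Series]:
    """Classify each peak center into exactly one genomic context with
    precedence promoter > proximal_upstream > exon > intron > distal.

    proximal_upstream is strand-aware: [tss-5000, tss-500) upstream of the
    TSS in transcription orientation. Returns (per-peak category,
    fraction per category); fractions sum to 1.
    """
    genes = list(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    categories: dict[str, str] = {}
    peaks = list(peaks)
    for p in peaks:
        c = p.center
        cat = "distal"
        candidates = by_chrom.get(p.chrom, [])
        if any(abs(g.tss - c) <= promoter_half_window for g in candidates):
            cat = "promoter"
        else:
            def upstream(g: GeneModel) -> bool:
                if g.strand == "+":
                    return g.tss - upstream_window <= c < g.tss - promoter_half_window
                return g.tss + promoter_half_window < c <= g.tss + upstream_window

            if any(upstream(g) for g in candidates):
                cat = "proximal_upstream"
            elif any(s <= c < e for g in candidates for s, e in g.exons):
                cat = "exon"
            elif any(g.span_start <= c < g.span_end for g in candidates):
                cat = "intron"
        categories[p.peak_id] = cat
    counts = pd.Series(
        [sum(1 for v in categories.values() if v == ctx) for ctx in CONTEXTS],
        index=list(CONTEXTS),
        dtype=float,
    )
    fractions = counts / counts.sum() if counts.sum() else counts
    return categories, fractions


def build_union_peaks(a: PeakSet, b: PeakSet) -> list[UnionPeak]:
    """Merge the two conditions' peaks transitively wherever they share
    >=1 bp; every input peak contributes to exactly one union peak."""
    tagged = [(p.chrom, p.start, p.end, 0, p) for p in a] + [
        (p.chrom, p.start, p.end, 1, p) for p in b
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[UnionPeak] = []
    cur: list[tuple[int, Peak]] = []
    cur_chrom, cur_s, cur_e = None, 0, 0

    def flush() -> None:
        if not cur:
            return
        sig = [0.0, 0.0]
        ids: tuple[list[str], list[str]] = ([], [])
        for cond_i, p in cur:
            sig[cond_i] = max(sig[cond_i], p.signal)
            ids[cond_i].append(p.peak_id)
        out.append(
            UnionPeak(
                chrom=cur_chrom,  # type: ignore[arg-type]
                start=cur_s,
                end=cur_e,
                union_id=f"u{len(out)}",
                signal=(sig[0], sig[1]),
                detected=(bool(ids[0]), bool(ids[1])),
                peak_ids=(tuple(ids[0]), tuple(ids[1])),
            )
        )

    for chrom, start, end, cond_i, p in tagged:
        if cur and chrom == cur_chrom and start < cur_e:
            cur_e = max(cur_e, end)
            cur.append((cond_i, p))
        else:
            flush()
            cur = [(cond_i, p)]
            cur_chrom, cur_s, cur_e = chrom, start, end
    flush()
    return out


def _tertile_categories(union: Sequence[UnionPeak], cond_i: int) -> list[str]:
    """Rank detected peaks ascending by signal (ties by chrom, start) and
    cut into tertiles: index floor(3*(rank-1)/n) -> low/mid/high."""
    detected = [(u.signal[cond_i], u.chrom, u.start, j) for j, u in enumerate(union) if u.detected[cond_i]]
    n = len(detected)
    if n < 3:
        raise ValueError(f"fewer than 3 detected peaks in condition index {cond_i}")
    detected.sort()
    cats = ["absent"] * len(union)
    names = ("low", "mid", "high")
    for rank, (_, _, _, j) in enumerate(detected, start=1):
        cats[j] = names[(3 * (rank - 1)) // n]
    return cats


def tertile_specificity(
    union: Sequence[UnionPeak],
    conditions: tuple[str, str],
    label_map: Mapping[tuple[str, str], str] | None = None,
) -> SpecificityTable:
    """Apply the tertile specificity scheme to a union-peak collection."""
    union = list(union)
    if label_map is None:
        label_map = default_label_map(*conditions)
    cats_a = _tertile_categories(union, 0)
    cats_b = _tertile_categories(union, 1)
    rows = []
    for u, ca, cb in zip(union, cats_a, cats_b):
        rows.append(
            {
                "chrom": u.chrom,
                "start": u.start,
                "end": u.end,
                "union_id": u.union_id,
                "cat_a": ca,
                "cat_b": cb,
                "label": label_map[(ca, cb)],
                "signal_a": u.signal[0],
                "signal_b": u.signal[1],
                "peak_ids_a": ",".join(u.peak_ids[0]),
                "peak_ids_b": ",".join(u.peak_ids[1]),
            }
        )
    return SpecificityTable(pd.DataFrame(rows, columns=SpecificityTable.COLUMNS), conditions)


def average_profile(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int] | tuple[str, int, str]],
    half_window: int,
    bin_size: int,
) -> ProfileMatrix:
    """Mean per-base signal around anchors, averaged into bins.

    Windows span [pos - half_window, pos + half_window); minus-strand
    anchors are reversed before averaging; out-of-range bases contribute 0.
    """
    if half_window % bin_size != 0:
        raise ValueError("half_window must be a multiple of bin_size")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("average_profile requires at least one anchor")
    span = 2 * half_window
    acc = np.zeros(span, dtype=float)
    for anchor in anchors:
        chrom, pos = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "+"
        vals = track.window(chrom, pos - half_window, pos + half_window)
        if strand == "-":
            vals = vals[::-1]
        acc += vals
    mean = acc / len(anchors)
    n_bins = span // bin_size
    values = mean.reshape(n_bins, bin_size).mean(axis=1)
    edges = np.arange(-half_window, half_window + 1, bin_size)
    return ProfileMatrix(bin_edges=edges, values=values, n_anchors=len(anchors))
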