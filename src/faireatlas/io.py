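"""Readers and writers for the external formats the pipeline consumes.

Everything is converted at the boundary to a single internal coordinate
convention: 0-based, half-open intervals (BED arithmetic). Peaks are the
atoms of all downstream analyses; genes are TSS-anchored records; expression
is a gene-by-condition table on a linear scale.

Formats: BED3/BED5 (peaks, TF binding sites), TSV (gene models, expression),
FASTA (sequence), bedGraph (signal), MEME minimal (motifs). All readers skip
blank lines and ``#`` comments and raise :class:`ParseError` with a line
number on malformed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Peak",
    "PeakSet",
    "GeneModel",
    "ExpressionTable",
    "SignalTrack",
    "ParseError",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_gene_table",
    "write_gene_table",
    "read_expression_table",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_meme_motifs",
    "write_meme_motifs",
]

VALID_DNA = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class Peak:
    """A called open-chromatin peak: half-open interval plus signal height.

    ``signal`` is the peak-caller's height statistic in arbitrary units
    (FindPeaks-style); it is only ever used for ranking and maxima, never
    interpreted on an absolute scale.
    """

    chrom: str
    start: int
    end: int
    signal: float = 1.0
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for peak {self.peak_id!r}"
            )
        if self.signal < 0:
            raise ValueError(f"negative signal {self.signal} for peak {self.peak_id!r}")

    @property
    def center(self) -> int:
        """Floor of the interval midpoint (summits are not available)."""
        return (self.start + self.end) // 2


class PeakSet:
    """Sorted collection of peaks from one condition.

    Peaks are kept sorted by (chrom, start, end) and peak ids must be
    unique. ``fdr_cutoff`` is provenance metadata from the upstream peak
    caller and is never used in computation.
    """

    def __init__(
        self,
        condition: str,
        peaks: Iterable[Peak] = (),
        fdr_cutoff: float | None = None,
    ) -> None:
        self.condition = condition
        self.fdr_cutoff = fdr_cutoff
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        seen: set[str] = set()
        for p in self.peaks:
            if p.peak_id in seen:
                raise ValueError(f"duplicate peak_id {p.peak_id!r} in condition {condition!r}")
            seen.add(p.peak_id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.condition == other.condition and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakSet({self.condition!r}, n={len(self)})"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "peak_id": [p.peak_id for p in self.peaks],
                "signal": [p.signal for p in self.peaks],
            }
        )

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}


@dataclass(frozen=True)
class GeneModel:
    """TSS-anchored gene record; coordinates 0-based half-open.

    For minus-strand genes the TSS is near ``span_end`` but the annotation
    is trusted as given. Exons, when present, are non-overlapping intervals
    inside the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if not (self.span_start <= self.tss < self.span_end):
            raise ValueError(
                f"gene {self.gene_id!r}: tss {self.tss} outside span "
                f"[{self.span_start}, {self.span_end})"
            )
        prev_end = None
        for s, e in self.exons:
            if not (self.span_start <= s < e <= self.span_end):
                raise ValueError(f"gene {self.gene_id!r}: exon [{s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e


class ExpressionTable:
    """Gene-by-condition expression values, linear scale.

    Values are floored at construction time (``floor``) so that fold
    changes are always finite; the floor stands in for the detection limit
    of the upstream expression platform.
    """

    def __init__(self, values: pd.DataFrame, floor: float = 1.0) -> None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r} in expression table")
        self.floor = floor
        self.values = values.clip(lower=floor)
        self.conditions = list(values.columns)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def fold_change(self, cond_a: str, cond_b: str) -> pd.Series:
        """expr(cond_b) / expr(cond_a), after flooring. Always finite."""
        fc = self.values[cond_b] / self.values[cond_a]
        fc.name = "fold_change"
        return fc


class SignalTrack:
    """Step-function coverage per chromosome (bedGraph semantics).

    Positions not covered by any interval have value 0. Intervals are kept
    sorted and must not overlap.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            ivals = sorted(ivals)
            starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
            values = np.array([v for _, _, v in ivals], dtype=float)
            if np.any(starts >= ends):
                raise ValueError(f"inverted interval on {chrom}")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._data:
            return []
        s, e, v = self._data[chrom]
        return [(int(a), int(b), float(c)) for a, b, c in zip(s, e, v)]

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside any covered
        interval (including negative coordinates) are 0."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data or end <= start:
            return out
        starts, ends, values = self._data[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for i in range(i0, i1):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_bed_peaks(path: str | Path, condition: str, fdr_cutoff: float | None = None) -> PeakSet:
    """Read peaks from BED3+ (optional 4th name, 5th score-as-signal).

    A missing signal column yields signal 1.0; a missing name yields
    auto-generated ids ``condition:index``.
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        peak_id = fields[3] if len(fields) > 3 and fields[3] else f"{condition}:{len(peaks)}"
        signal = 1.0
        if len(fields) > 4 and fields[4] != "":
            try:
                signal = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
            if signal < 0:
                raise ParseError(f"{path}:{lineno}: negative signal {signal}")
        peaks.append(Peak(chrom, start, end, signal, peak_id))
    return PeakSet(condition, peaks, fdr_cutoff=fdr_cutoff)


def write_bed_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write BED5 (chrom, start, end, peak_id, signal)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.signal:g}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read plain intervals (e.g. TF binding sites) from BED3+."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        out.append((fields[0], start, end))
    return sorted(out)


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "span_start", "span_end", "exons"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with header
    gene_id, chrom, strand, tss, span_start, span_end, exons.

    The exon column holds semicolon-separated ``start-end`` pairs and may be
    empty.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        exon_field = getattr(row, "exons", "") if "exons" in df.columns else ""
        exons: list[tuple[int, int]] = []
        if exon_field:
            for pair in exon_field.split(";"):
                if not pair:
                    continue
                s, e = pair.split("-")
                exons.append((int(s), int(e)))
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                span_start=int(row.span_start),
                span_end=int(row.span_end),
                exons=tuple(sorted(exons)),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            exons = ";".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.span_start}\t{g.span_end}\t{exons}\n"
            )


def read_expression_table(
    path: str | Path,
    floor: float = 1.0,
    known_genes: Iterable[str] | None = None,
) -> ExpressionTable:
    """Read a gene-level expression TSV: gene_id column plus one numeric
    column per condition.

    Genes absent from ``known_genes`` (when given) are retained with a
    warning — expression platforms routinely measure genes outside the
    interval annotation in use.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(f"{path}: non-numeric expression for gene {bad!r} in {col!r}")
    if known_genes is not None:
        unknown = set(df.index) - set(known_genes)
        if unknown:
            warnings.warn(
                f"{len(unknown)} expression genes absent from annotation (retained)",
                stacklevel=2,
            )
    return ExpressionTable(df.astype(float), floor=floor)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")


def read_fasta(path: str | Path, hard_mask: bool = False) -> dict[str, str]:
    """Read FASTA into {id: sequence}.

    Lower-case letters mark soft-masked (repeat) positions; with
    ``hard_mask=True`` they become N, otherwise they are upper-cased.
    Characters outside ACGTN are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if hard_mask:
            seq = "".join("N" if c.islower() else c for c in raw)
        else:
            seq = raw.upper()
        bad = set(seq.upper()) - VALID_DNA
        if bad:
            raise ParseError(f"{path}: sequence {rec.id!r} has non-DNA characters {sorted(bad)}")
        seqs[rec.id] = seq.upper() if not hard_mask else seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a bedGraph into a :class:`SignalTrack` (sorted, non-overlapping)."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        if line.startswith("track"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        per_chrom.setdefault(fields[0], []).append((start, end, value))
    try:
        return SignalTrack(per_chrom)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_meme_motifs(path: str | Path):
    """Parse MEME minimal format into a list of :class:`faireatlas.motifs.PWM`.

    Rows are renormalized when they sum to 1 within 1e-3..1e-2 band rules:
    a deviation above 1e-2 is an error, below that the row is renormalized.
    """
    from .motifs import PWM  # local import to avoid a cycle

    motifs = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            if i < len(lines):
                toks = lines[i].split()
                freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks) - 1, 2)}
                background = np.array([freq.get(b, 0.25) for b in "ACGT"])
            i += 1
            continue
        if line.startswith("MOTIF"):
            name = line.split(maxsplit=2)[1]
            i += 1
            # find the letter-probability header
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {name!r} has no letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise ParseError(f"{path}: motif {name!r} has no letter-probability matrix")
            header = lines[i]
            i += 1
            rows = []
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) != 4:
                    break
                try:
                    rows.append([float(t) for t in toks])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ParseError(f"{path}: motif {name!r} has width 0")
            matrix = np.array(rows)
            sums = matrix.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-2):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ParseError(
                    f"{path}: motif {name!r} row {bad} sums to {sums[bad]:.4f} (tolerance 1e-2)"
                )
            matrix = matrix / sums[:, None]
            motifs.append(PWM(name=name, matrix=matrix, background=background.copy()))
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs, path: str | Path) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
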