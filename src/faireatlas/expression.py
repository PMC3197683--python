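"""Linking open-chromatin peaks to gene expression change.

Peaks are tied to genes either by nearest TSS (each peak gets exactly one
gene) or by a symmetric vicinity window around the TSS (default +/-25 kb,
inclusive). Regulation calls are simple fold-change thresholds on a
two-condition expression table: >2-fold up/down, >3-fold up, >10-fold
induced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .atlas import CATEGORIES, SpecificityTable
from .intervals import as_interval, merge_intervals
from .io import ExpressionTable, GeneModel, Peak, PeakSet

__all__ = [
    "regulation_calls",
    "assign_nearest_gene",
    "peaks_near_tss",
    "fraction_regulated_by_peakcount",
    "peakcount_by_expression_strata",
    "vicinity_enrichment",
    "overlap_by_stratum",
    "gene_motif_fraction",
    "rank_genes_for_ontology",
]


def regulation_calls(
    expr: ExpressionTable,
    cond_a: str,
    cond_b: str,
    up_fold: float = 2.0,
    down_fold: float = 2.0,
    strong_fold: float = 3.0,
    induced_fold: float = 10.0,
) -> pd.DataFrame:
    """Per-gene fold change cond_b/cond_a and threshold flags.

    Columns: fold_change, up2, down2, up3, induced10. The flags nest:
    induced10 implies up3 implies up2, and up2/down2 are exclusive.
    """
    fc = expr.fold_change(cond_a, cond_b)
    return pd.DataFrame(
        {
            "fold_change": fc,
            "up2": fc > up_fold,
            "down2": fc < 1.0 / down_fold,
            "up3": fc > strong_fold,
            "induced10": fc > induced_fold,
        }
    )


def assign_nearest_gene(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Assign each peak to the gene with nearest TSS (absolute center-TSS
    distance); ties broken by smaller TSS coordinate, then gene_id.

    Returns a DataFrame indexed by peak_id with columns gene_id and
    distance. The distance is signed in transcription orientation:
    negative means the peak center lies upstream of the TSS. Peaks on
    chromosomes without genes are left unassigned (gene_id NaN) with a
    warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gl], dtype=np.int64), gl)
    rows = []
    n_unassigned = 0
    for p in peaks:
        c = p.center
        if p.chrom not in index:
            rows.append({"peak_id": p.peak_id, "gene_id": None, "distance": np.nan})
            n_unassigned += 1
            continue
        tss_arr, gl = index[p.chrom]
        i = int(np.searchsorted(tss_arr, c))
        best: GeneModel | None = None
        best_key: tuple[int, int, str] | None = None
        for j in range(max(0, i - 2), min(len(gl), i + 2)):
            g = gl[j]
            key = (abs(g.tss - c), g.tss, g.gene_id)
            if best_key is None or key < best_key:
                best, best_key = g, key
        assert best is not None
        signed = (c - best.tss) if best.strand == "+" else (best.tss - c)
        rows.append({"peak_id": p.peak_id, "gene_id": best.gene_id, "distance": signed})
    if n_unassigned:
        warnings.warn(f"{n_unassigned} peaks on chromosomes without genes left unassigned",
                      stacklevel=2)
    return pd.DataFrame(rows).set_index("peak_id")


def peaks_near_tss(
    genes: Sequence[GeneModel],
    peaks: PeakSet | Sequence[Peak],
    half_window: int = 25_000,
) -> pd.DataFrame:
    """Per gene: number of peaks whose center lies within
    [tss - half_window, tss + half_window] (inclusive) and the maximum
    signal among them (0 if none)."""
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.center, p.signal))
    arrays = {}
    for chrom, cs in by_chrom.items():
        cs.sort()
        arrays[chrom] = (
            np.array([c for c, _ in cs], dtype=np.int64),
            np.array([s for _, s in cs], dtype=float),
        )
    rows = []
    for g in genes:
        n, mx = 0, 0.0
        if g.chrom in arrays:
            centers, signals = arrays[g.chrom]
            lo = int(np.searchsorted(centers, g.tss - half_window, side="left"))
            hi = int(np.searchsorted(centers, g.tss + half_window, side="right"))
            n = hi - lo
            if n:
                mx = float(signals[lo:hi].max())
        rows.append({"gene_id": g.gene_id, "n_peaks": n, "max_signal": mx})
    return pd.DataFrame(rows).set_index("gene_id")


def fraction_regulated_by_peakcount(
    peak_counts: Mapping[str, int] | pd.Series,
    regulation: pd.DataFrame,
    max_bucket: int = 4,
) -> pd.DataFrame:
    """Fraction of genes up-/down-regulated >2-fold among genes with
    exactly k assigned peaks of one specificity label (top bucket pools
    >= max_bucket).

    ``peak_counts`` maps gene_id -> count for the label of interest; genes
    in ``regulation`` but absent from the mapping count as 0. Empty buckets
    report NaN fractions, not 0.
    """
    counts = pd.Series(peak_counts, dtype=float).reindex(regulation.index).fillna(0).astype(int)
    bucket = counts.clip(upper=max_bucket)
    rows = []
    for k in range(max_bucket + 1):
        sel = regulation[bucket == k]
        n = len(sel)
        rows.append(
            {
                "bucket": k,
                "fraction_up": sel["up2"].mean() if n else np.nan,
                "fraction_down": sel["down2"].mean() if n else np.nan,
                "n_genes": n,
            }
        )
    return pd.DataFrame(rows).set_index("bucket")


def peakcount_by_expression_strata(
    peak_counts_by_label: Mapping[str, Mapping[str, int] | pd.Series],
    regulation: pd.DataFrame,
    strata_edges: Sequence[float],
) -> pd.DataFrame:
    """Mean per-gene peak count per specificity label, with genes stratified
    by log2 fold change into left-closed bins [e_i, e_{i+1}).

    Genes outside the outermost edges are excluded. Empty strata report
    NaN means.
    """
    edges = np.asarray(strata_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("strata_edges must be strictly increasing with >= 2 values")
    log2fc = np.log2(regulation["fold_change"].to_numpy())
    # digitize: bin i covers [edges[i], edges[i+1]); a value on an edge
    # falls in the bin that starts there.
    which = np.digitize(log2fc, edges, right=False) - 1
    rows = []
    for i in range(len(edges) - 1):
        genes_in = regulation.index[which == i]
        row: dict[str, object] = {
            "stratum_lo": edges[i],
            "stratum_hi": edges[i + 1],
            "n_genes": len(genes_in),
        }
        for label, counts in peak_counts_by_label.items():
            s = pd.Series(counts, dtype=float).reindex(genes_in).fillna(0)
            row[f"mean_{label}"] = s.mean() if len(genes_in) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def vicinity_enrichment(
    has_peak: pd.Series,
    selected_genes: Iterable[str],
) -> dict[str, float]:
    """Hypergeometric upper-tail enrichment of peak-bearing genes within a
    selected gene set (e.g. the top-n most up-regulated genes).

    ``has_peak`` is a boolean Series over the gene universe. Returns the
    2x2 counts and p = P(X >= observed overlap). Degenerate margins give
    p = 1.
    """
    selected = set(selected_genes)
    missing = selected - set(has_peak.index)
    if missing:
        raise ValueError(f"selected genes absent from universe: {sorted(missing)[:3]}...")
    n_genes = len(has_peak)
    n_marked = int(has_peak.sum())
    n_sel = len(selected)
    k = int(has_peak.loc[sorted(selected)].sum())
    if n_marked == 0 or n_sel == 0 or n_sel >= n_genes:
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, n_genes, n_marked, n_sel))
    return {
        "n_genes": n_genes,
        "n_marked": n_marked,
        "n_selected": n_sel,
        "n_selected_marked": k,
        "p_value": min(p, 1.0),
    }


def overlap_by_stratum(
    spec: SpecificityTable,
    tf_sites: Sequence,
    summary_cells: Iterable[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, float]:
    """Percent of union peaks overlapping >=1 TF binding site, per
    (tertile_A, tertile_B) cell of the specificity table.

    Returns the 4x4 percent matrix (rows cat_a, columns cat_b; empty cells
    NaN) and the unweighted mean over ``summary_cells`` (undefined cells
    excluded) — the "average of bars" statistic.
    """
    merged = merge_intervals(tf_sites)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, ([], []))  # type: ignore[arg-type]
    for chrom in by_chrom:
        ivals = [(s, e) for c, s, e in merged if c == chrom]
        by_chrom[chrom] = (
            np.array([s for s, _ in ivals], dtype=np.int64),
            np.array([e for _, e in ivals], dtype=np.int64),
        )

    def overlaps(chrom: str, start: int, end: int) -> bool:
        if chrom not in by_chrom:
            return False
        starts, ends = by_chrom[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    df = spec.df
    hit = df.apply(lambda r: overlaps(r["chrom"], r["start"], r["end"]), axis=1) if len(df) else pd.Series(dtype=bool)
    matrix = pd.DataFrame(np.nan, index=list(CATEGORIES), columns=list(CATEGORIES))
    for ca in CATEGORIES:
        for cb in CATEGORIES:
            sel = (df["cat_a"] == ca) & (df["cat_b"] == cb)
            n = int(sel.sum())
            if n:
                matrix.loc[ca, cb] = 100.0 * hit[sel].mean()
    cells = [matrix.loc[ca, cb] for ca, cb in summary_cells]
    defined = [c for c in cells if not (isinstance(c, float) and math.isnan(c))]
    summary = float(np.mean(defined)) if defined else float("nan")
    return matrix, summary


def gene_motif_fraction(
    genes: Sequence[GeneModel],
    motif_peaks: PeakSet | Sequence[Peak],
    all_nonpromoter_peaks: PeakSet | Sequence[Peak],
    tf_sites: Sequence,
    regulation: pd.DataFrame,
    half_window: int = 25_000,
) -> pd.DataFrame:
    """Fraction of genes with a motif-bearing non-promoter peak within
    +/-25 kb of the TSS, stratified by whether the gene is TF-bound
    (>=1 site center within the window) and induced (>2-fold up).

    ``motif_peaks`` are the non-promoter peaks that carry >=1 motif hit.
    Returns a 2x2 table indexed by (bound, induced) with the fraction and
    group size; empty groups report NaN.
    """
    motif_near = peaks_near_tss(genes, motif_peaks, half_window)["n_peaks"] > 0
    site_peaks = [
        Peak(chrom, start, end, 1.0, f"tf{i}")
        for i, (chrom, start, end) in enumerate(as_interval(s)[:3] for s in tf_sites)
    ]
    bound = peaks_near_tss(genes, site_peaks, half_window)["n_peaks"] > 0
    gene_ids = [g.gene_id for g in genes]
    induced = regulation["up2"].reindex(gene_ids).fillna(False)
    rows = []
    for b in (True, False):
        for ind in (True, False):
            sel = [gid for gid in gene_ids if bound[gid] == b and bool(induced[gid]) == ind]
            rows.append(
                {
                    "bound": b,
                    "induced": ind,
                    "fraction_with_motif": motif_near.loc[sel].mean() if sel else np.nan,
                    "n_genes": len(sel),
                }
            )
    return pd.DataFrame(rows).set_index(["bound", "induced"])


def rank_genes_for_ontology(
    genes: Sequence[GeneModel],
    label_peaks: PeakSet | Sequence[Peak],
    half_window: int = 25_000,
    top_n: int = 2000,
) -> list[str]:
    """Rank genes by (number, then maximum height) of label peaks within
    +/- half_window of the TSS, descending; ties by gene_id. The truncated
    list is the input to external ontology-term tools."""
    stats = peaks_near_tss(genes, label_peaks, half_window)
    order = sorted(
        stats.itertuples(),
        key=lambda r: (-r.n_peaks, -r.max_signal, r.Index),
    )
    return [r.Index for r in order[:top_n]]
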