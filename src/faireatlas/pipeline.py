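"""End-to-end orchestration: read inputs, run every analysis stage in
dependency order, write per-figure TSV reports and a machine-readable run
manifest. Fully deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import (
    SpecificityTable,
    build_union_peaks,
    classify_promoter,
    genomic_distribution,
    tertile_specificity,
)
from .clustering import cluster_null_test, nearest_distance_histogram
from .coregulation import coregulation_test, random_gene_control
from .expression import (
    assign_nearest_gene,
    fraction_regulated_by_peakcount,
    gene_motif_fraction,
    peakcount_by_expression_strata,
    peaks_near_tss,
    rank_genes_for_ontology,
    regulation_calls,
    vicinity_enrichment,
)
from .io import (
    Peak,
    PeakSet,
    read_bed_intervals,
    read_bed_peaks,
    read_expression_table,
    read_fasta,
    read_gene_table,
    read_meme_motifs,
)
from .motifs import motif_screen, scan_sequences, score_pvalue_table

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Input paths, condition labels and every stage parameter.

    All parameters are echoed into the run manifest so a report directory
    is self-describing.
    """

    genes: str
    expression: str
    peaks_a: str
    peaks_b: str
    conditions: tuple[str, str] = ("day0", "day8")
    tf_sites: str | None = None
    peak_sequences: str | None = None
    motifs: str | None = None
    # stage parameters
    promoter_half_window: int = 500
    association_half_window: int = 25_000
    up_fold: float = 2.0
    strong_fold: float = 3.0
    induced_fold: float = 10.0
    max_bucket: int = 4
    strata_edges: tuple[float, ...] = (-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0)
    top_regulated: int = 100
    cluster_windows: tuple[int, ...] = (800, 2_000, 10_000, 30_000, 100_000)
    n_trials: int = 1000
    chrom_length: int | None = None
    motif_top_n: int = 2000
    center_width: int = 150
    scan_p_threshold: float = 1e-4
    ratio_threshold_fg: float = 1.20
    ratio_threshold_bg: float = 0.833
    coreg_background: str = "all_genes"
    ontology_top_n: int = 2000
    seed: int = 0
    expression_floor: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("conditions", "strata_edges", "cluster_windows"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def for_bundle_dir(
        cls, bundle_dir: str | Path, conditions: tuple[str, str] = ("day0", "day8"), **kw
    ) -> "PipelineConfig":
        """Config pointing at the file layout ``StudyBundle.write`` emits."""
        d = Path(bundle_dir)
        return cls(
            genes=str(d / "genes.tsv"),
            expression=str(d / "expression.tsv"),
            peaks_a=str(d / f"peaks_{conditions[0]}.bed"),
            peaks_b=str(d / f"peaks_{conditions[1]}.bed"),
            tf_sites=str(d / "tf_sites.bed"),
            peak_sequences=str(d / "peak_centers.fa"),
            motifs=str(d / "motifs.meme"),
            conditions=conditions,
            **kw,
        )


def _union_rows_as_peaks(rows: pd.DataFrame, signal_col: str) -> list[Peak]:
    return [
        Peak(r.chrom, int(r.start), int(r.end), float(getattr(r, signal_col)), str(r.union_id))
        for r in rows.itertuples()
    ]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages, writing per-figure reports into ``outdir``.

    Missing required inputs raise before any computation; a failure inside
    a stage is recorded in the manifest and later dependent stages are
    skipped, with earlier outputs retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = {"genes": config.genes, "expression": config.expression,
                "peaks_a": config.peaks_a, "peaks_b": config.peaks_b}
    for name, path in required.items():
        if not Path(path).is_file():
            raise FileNotFoundError(f"required input {name!r} not found: {path}")
    cond_a, cond_b = config.conditions
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "version": __version__,
        "stages": {},
    }

    def done(stage: str) -> None:
        manifest["stages"][stage] = "ok"

    def failed(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = f"failed: {exc}"

    def write_manifest() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    # ---- inputs --------------------------------------------------------
    genes = read_gene_table(config.genes)
    expression = read_expression_table(config.expression, floor=config.expression_floor,
                                       known_genes=[g.gene_id for g in genes])
    peaks_a = read_bed_peaks(config.peaks_a, cond_a)
    peaks_b = read_bed_peaks(config.peaks_b, cond_b)
    for name, path in (("tf_sites", config.tf_sites),
                       ("peak_sequences (motif stage)", config.peak_sequences),
                       ("motifs (motif stage)", config.motifs)):
        if path is not None and not Path(path).is_file():
            raise FileNotFoundError(f"configured input {name} not found: {path}")
    tf_sites = read_bed_intervals(config.tf_sites) if config.tf_sites else None
    sequences = read_fasta(config.peak_sequences) if config.peak_sequences else None
    motifs = read_meme_motifs(config.motifs) if config.motifs else None
    manifest["inputs"] = {
        "n_genes": len(genes),
        f"n_peaks_{cond_a}": len(peaks_a),
        f"n_peaks_{cond_b}": len(peaks_b),
        "n_tf_sites": len(tf_sites) if tf_sites is not None else None,
    }

    # ---- atlas ---------------------------------------------------------
    spec: SpecificityTable | None = None
    try:
        _, fractions = genomic_distribution(peaks_a, genes, config.promoter_half_window)
        fractions.rename("fraction").to_csv(outdir / "figS1A.tsv", sep="\t",
                                            index_label="category")
        _, nonprom_a = classify_promoter(peaks_a, genes, config.promoter_half_window)
        _, nonprom_b = classify_promoter(peaks_b, genes, config.promoter_half_window)
        manifest["inputs"]["n_nonpromoter_a"] = len(nonprom_a)
        manifest["inputs"]["n_nonpromoter_b"] = len(nonprom_b)
        union = build_union_peaks(PeakSet(cond_a, nonprom_a), PeakSet(cond_b, nonprom_b))
        spec = tertile_specificity(union, config.conditions)
        spec.to_tsv(outdir / "fig2B.tsv")
        done("atlas")
    except Exception as exc:  # noqa: BLE001 - stage isolation
        failed("atlas", exc)
        write_manifest()
        raise

    label_a, label_b = f"specific_to_{cond_a}", f"specific_to_{cond_b}"
    regulation = regulation_calls(expression, cond_a, cond_b, config.up_fold,
                                  config.up_fold, config.strong_fold, config.induced_fold)

    # ---- expression linkage -------------------------------------------
    label_peaks: dict[str, list[Peak]] = {}
    try:
        counts_by_label: dict[str, pd.Series] = {}
        fig2d_frames = []
        for label, signal_col in ((label_a, "signal_a"), (label_b, "signal_b"),
                                  ("invariant", "signal_b")):
            rows = spec.rows_with_label(label)
            lp = _union_rows_as_peaks(rows, signal_col)
            label_peaks[label] = lp
            assignment = assign_nearest_gene(lp, genes) if lp else pd.DataFrame(columns=["gene_id"])
            counts = assignment.groupby("gene_id").size() if len(assignment) else pd.Series(dtype=int)
            counts_by_label[label] = counts
            tbl = fraction_regulated_by_peakcount(counts, regulation, config.max_bucket)
            tbl.insert(0, "label", label)
            fig2d_frames.append(tbl.reset_index())
        pd.concat(fig2d_frames).to_csv(outdir / "fig2D.tsv", sep="\t", index=False)
        fig2e = peakcount_by_expression_strata(counts_by_label, regulation,
                                               config.strata_edges)
        fig2e.to_csv(outdir / "fig2E.tsv", sep="\t", index=False)
        # Fig 2C: enrichment of specific peaks near most-regulated genes
        fc = regulation["fold_change"]
        fig2c_rows = []
        for label in (label_a, label_b):
            near = peaks_near_tss(genes, label_peaks[label], config.association_half_window)
            has_peak = near["n_peaks"] > 0
            for direction, ordered in (("up", fc.sort_values(ascending=False)),
                                       ("down", fc.sort_values(ascending=True))):
                top = list(ordered.index[: config.top_regulated])
                res = vicinity_enrichment(has_peak, top)
                fig2c_rows.append({"label": label, "direction": direction, **res})
        pd.DataFrame(fig2c_rows).to_csv(outdir / "fig2C.tsv", sep="\t", index=False)
        ranked = rank_genes_for_ontology(genes, label_peaks[label_b],
                                         config.association_half_window, config.ontology_top_n)
        (outdir / "ontology_genes.txt").write_text("\n".join(ranked) + "\n")
        done("expression_link")
    except Exception as exc:  # noqa: BLE001
        failed("expression_link", exc)

    # ---- TF-site overlap by stratum (Fig 2H) ---------------------------
    if tf_sites is not None:
        try:
            from .expression import overlap_by_stratum

            summary_cells = [("low", "high"), ("absent", "high"), ("absent", "mid")]
            matrix, summary = overlap_by_stratum(spec, tf_sites, summary_cells)
            matrix.to_csv(outdir / "fig2H.tsv", sep="\t", index_label="cat_a")
            manifest["fig2H_summary_percent"] = summary
            done("tf_overlap")
        except Exception as exc:  # noqa: BLE001
            failed("tf_overlap", exc)

    # ---- clustering ----------------------------------------------------
    try:
        rows_b = spec.rows_with_label(label_b)
        sites = {
            chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
            for chrom, grp in rows_b.groupby("chrom")
        }
        counts, edges, _ = nearest_distance_histogram(sites)
        pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}).to_csv(
            outdir / "fig4A.tsv", sep="\t", index=False
        )
        max_coord = max(p.end for ps in (peaks_a, peaks_b) for p in ps)
        chrom_len = config.chrom_length or int(max_coord * 1.05)
        genome = {chrom: chrom_len for chrom in sites}
        reports = []
        for w in config.cluster_windows:
            rep = cluster_null_test(sites, w, genome, config.n_trials, seed=config.seed)
            reports.append(dataclasses.asdict(rep))
        pd.DataFrame(reports).to_csv(outdir / "fig4B.tsv", sep="\t", index=False)
        done("cluster_stats")
    except Exception as exc:  # noqa: BLE001
        failed("cluster_stats", exc)

    # ---- neighbor co-regulation ---------------------------------------
    try:
        results = {}
        for mode in ("all_genes", "disjoint"):
            r = coregulation_test(genes, regulation, config.induced_fold,
                                  config.strong_fold, background=mode)
            results[mode] = r
        main = results[config.coreg_background]
        observed = main.n_neighbors_up3 / main.n_neighbors
        control = random_gene_control(genes, regulation, main.n_seed, config.n_trials,
                                      seed=config.seed, up_fold=config.strong_fold,
                                      observed_fraction=observed)
        row = dataclasses.asdict(main)
        row.update({f"control_{k}": v for k, v in control.items()})
        pd.DataFrame([row]).to_csv(outdir / "fig4D.tsv", sep="\t", index=False)
        manifest["coregulation_p_by_background"] = {
            mode: results[mode].fisher_p_one_sided for mode in results
        }
        done("neighbor_coreg")
    except Exception as exc:  # noqa: BLE001
        failed("neighbor_coreg", exc)

    # ---- motif screen --------------------------------------------------
    if motifs and sequences:
        try:
            screen = motif_screen(
                spec, motifs, peak_sequences=sequences,
                top_n=config.motif_top_n, center_width=config.center_width,
                p_threshold=config.scan_p_threshold, seed=config.seed,
            )
            screen.to_csv(outdir / "fig5.tsv", sep="\t", index=False)
            done("motif_screen")
        except Exception as exc:  # noqa: BLE001
            failed("motif_screen", exc)
        # Fig 8D: genes with motif-bearing non-promoter peaks, by TF binding
        # and induction
        if tf_sites is not None:
            try:
                nonprom_rows = spec.df
                all_np_peaks = _union_rows_as_peaks(nonprom_rows, "signal_b")
                seqs = {}
                for r in nonprom_rows.itertuples():
                    for pid in (str(r.peak_ids_b) or str(r.peak_ids_a)).split(","):
                        if pid in sequences:
                            seqs[str(r.union_id)] = sequences[pid]
                            break
                pwm = motifs[0]
                dist = score_pvalue_table(pwm)
                hits = scan_sequences(seqs, pwm, config.scan_p_threshold, dist=dist)
                with_hit = {h.sequence_id for h in hits}
                motif_peaks = [p for p in all_np_peaks if p.peak_id in with_hit]
                table = gene_motif_fraction(genes, motif_peaks, all_np_peaks, tf_sites,
                                            regulation, config.association_half_window)
                table.reset_index().to_csv(outdir / "fig8D.tsv", sep="\t", index=False)
                done("gene_motif_fraction")
            except Exception as exc:  # noqa: BLE001
                failed("gene_motif_fraction", exc)
    write_manifest()
    return manifest
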