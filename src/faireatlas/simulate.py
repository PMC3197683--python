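"""Synthetic two-condition open-chromatin study with planted ground truth.

The generator emulates the statistical structure a differentiation
time-course FAIRE experiment asserts downstream of peak calling, at desk
scale: two peak sets (condition A = precursor, condition B =
differentiated) sharing promoter and invariant peaks; condition-specific
peaks planted near up-/down-regulated genes; tight clusters of B-specific
peaks near a few anchor genes; TF binding sites overlapping a controlled
fraction of B-specific peaks; a consensus motif planted into a controlled
fraction of each specific class's center sequences; and expression fold
changes in which neighbors of highly induced genes are co-up-regulated
with probability rho.

Every planted element is recorded in a :class:`SyntheticTruth` so each
pipeline stage has a parameter-recovery check, and a matching ``null``
variant removes all planted associations while keeping the class/signal
structure, for type-I-error checks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionTable,
    GeneModel,
    Peak,
    PeakSet,
    SignalTrack,
    write_bed_intervals,
    write_bed_peaks,
    write_bedgraph,
    write_expression_table,
    write_fasta,
    write_gene_table,
    write_meme_motifs,
)
from .motifs import PWM

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StudyBundle",
    "default_planted_motif",
    "generate_study",
    "null_study",
]

REVCOMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions used by
    the recovery and type-I acceptance checks."""

    seed: int = 0
    conditions: tuple[str, str] = ("day0", "day8")
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    genes_per_chrom: int = 100
    # expression
    fraction_up: float = 0.15
    fraction_down: float = 0.15
    base_expr_log_mean: float = float(np.log(100.0))
    base_expr_log_sd: float = 1.0
    up_log2fold_range: tuple[float, float] = (1.2, 5.5)
    noise_log2fold_sd: float = 0.25
    coreg_rho: float = 0.5
    coreg_log2fold_range: tuple[float, float] = (1.7, 3.1)
    # peaks
    promoter_peak_rate: float = 0.7
    peaks_per_up_gene: float = 2.0  # Poisson lambda, B-specific
    peaks_per_down_gene: float = 3.0  # Poisson lambda, A-specific
    n_invariant: int = 300
    placement_halfwidth: int = 15_000  # specific peaks land within +/- this of the TSS
    min_tss_distance: int = 1_000  # distal elements: keep clear of promoter windows
    min_center_separation: int = 600
    peak_width_log_mean: float = float(np.log(300.0))
    peak_width_log_sd: float = 0.25
    # signals (log-normal, class-dependent location)
    signal_specific_log_mean: float = float(np.log(50.0))
    signal_specific_log_sd: float = 0.5
    signal_invariant_log_mean: float = float(np.log(15.0))
    signal_invariant_log_sd: float = 0.5
    signal_low_log_mean: float = float(np.log(4.0))
    signal_low_log_sd: float = 0.4
    signal_promoter_log_mean: float = float(np.log(20.0))
    signal_promoter_log_sd: float = 0.4
    q_absent: float = 0.85  # P(specific peak entirely absent in the other condition)
    # clusters of B-specific peaks
    cluster_anchors: int = 12
    cluster_size: int = 5
    cluster_span: int = 2500
    cluster_peak_width: int = 250
    # TF sites and motifs
    tf_overlap_fraction: float = 0.45
    tf_site_halfwidth: int = 100
    n_background_tf_sites: int = 50
    motif_rate_b: float = 0.30
    motif_rate_a: float = 0.05
    # sequences
    seq_length: int = 150
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # structure switch (False = null bundle: uniform placement, no linkage)
    planted_structure: bool = True

    @property
    def n_genes(self) -> int:
        return self.n_chroms * self.genes_per_chrom

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def validate(self) -> None:
        for p in (
            self.fraction_up, self.fraction_down, self.coreg_rho, self.q_absent,
            self.promoter_peak_rate, self.tf_overlap_fraction,
            self.motif_rate_a, self.motif_rate_b,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.peaks_per_up_gene < 0 or self.peaks_per_down_gene < 0:
            raise ValueError("Poisson rates must be >= 0")
        if self.chrom_length <= 2 * 25_000:
            raise ValueError("chromosomes must exceed twice the 25 kb vicinity window")
        if self.placement_halfwidth * 2 >= self.chrom_length:
            raise ValueError("placement window exceeds chromosome")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("conditions", "up_log2fold_range", "coreg_log2fold_range", "base_composition"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted labels: one row per planted peak element and per gene."""

    peaks: pd.DataFrame  # element_id, kind, chrom, center, width, gene_id, motif, tf, cluster
    genes: pd.DataFrame  # gene_id, regulated, fold, induced10, cluster_anchor, coreg_neighbor

    def sites(self, kind: str) -> dict[str, np.ndarray]:
        """Per-chromosome sorted center positions of one planted class."""
        sel = self.peaks[self.peaks["kind"] == kind]
        return {
            chrom: np.sort(grp["center"].to_numpy())
            for chrom, grp in sel.groupby("chrom")
        }


@dataclass
class StudyBundle:
    config: SyntheticConfig
    genes: list[GeneModel]
    expression: ExpressionTable
    peaks_a: PeakSet
    peaks_b: PeakSet
    tf_sites: list[tuple[str, int, int]]
    sequences: dict[str, str]  # element_id -> center sequence
    track: SignalTrack
    motif: PWM
    truth: SyntheticTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cond_a, cond_b = self.config.conditions
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_expression_table(self.expression, outdir / "expression.tsv")
        write_bed_peaks(self.peaks_a, outdir / f"peaks_{cond_a}.bed")
        write_bed_peaks(self.peaks_b, outdir / f"peaks_{cond_b}.bed")
        write_bed_intervals(self.tf_sites, outdir / "tf_sites.bed")
        write_fasta(self.sequences, outdir / "peak_centers.fa")
        write_bedgraph(self.track, outdir / f"signal_{cond_b}.bedgraph")
        write_meme_motifs([self.motif], outdir / "motifs.meme")
        self.truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
        self.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.config.to_json(outdir / "config.json")


def default_planted_motif(name: str = "NFI_SYN") -> PWM:
    """Sharp 11-bp synthetic motif (NFI-half-site-like consensus
    TTGGCAGCCAA) used as the planted binding element; 0.985 probability on
    the consensus letter per column."""
    consensus = "TTGGCAGCCAA"
    idx = {c: i for i, c in enumerate("ACGT")}
    matrix = np.full((len(consensus), 4), 0.005)
    for j, letter in enumerate(consensus):
        matrix[j, idx[letter]] = 0.985
    return PWM(name=name, matrix=matrix)


def _random_seq(rng: np.random.Generator, length: int, comp: np.ndarray) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=comp)])


def _separated_offsets(
    rng: np.random.Generator, k: int, halfwidth: int, min_abs: int, min_sep: int
) -> np.ndarray:
    """k offsets with min_abs <= |offset| <= halfwidth and pairwise
    separation >= min_sep (rejection; falls back after 200 draws)."""
    for _ in range(200):
        mag = rng.integers(min_abs, halfwidth + 1, size=k)
        sign = np.where(rng.random(k) < 0.5, -1, 1)
        off = mag * sign
        if k == 1 or np.min(np.diff(np.sort(off))) >= min_sep:
            return off
    return off  # pragma: no cover - practically unreachable at defaults


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate the full study bundle; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cond_a, cond_b = config.conditions
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    motif = default_planted_motif()
    consensus = motif.consensus()

    # --- genes on a jittered grid -------------------------------------
    genes: list[GeneModel] = []
    spacing = config.chrom_length // (config.genes_per_chrom + 1)
    jitter = max(spacing // 5, 1)
    serial = 0
    for chrom in config.chrom_names:
        for i in range(config.genes_per_chrom):
            tss = (i + 1) * spacing + int(rng.integers(-jitter, jitter + 1))
            tss = int(np.clip(tss, 30_000, config.chrom_length - 30_000))
            strand = "+" if rng.random() < 0.5 else "-"
            span_len = int(rng.integers(5_000, 20_000))
            if strand == "+":
                span = (tss, tss + span_len)
                exons = ((tss, tss + 200), (span[1] - 200, span[1]))
            else:
                span = (tss - span_len + 1, tss + 1)
                exons = ((span[0], span[0] + 200), (tss - 199, tss + 1))
            genes.append(
                GeneModel(
                    gene_id=f"g{serial:04d}", chrom=chrom, strand=strand,
                    tss=tss, span_start=span[0], span_end=span[1], exons=exons,
                )
            )
            serial += 1

    # --- expression with planted regulation ---------------------------
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_up = int(round(config.fraction_up * n))
    n_down = int(round(config.fraction_down * n))
    perm = rng.permutation(n)
    up_idx = set(perm[:n_up].tolist())
    down_idx = set(perm[n_up : n_up + n_down].tolist())
    lo, hi = config.up_log2fold_range
    log2fc = rng.normal(0.0, config.noise_log2fold_sd, size=n)
    for i in range(n):
        if i in up_idx:
            log2fc[i] = rng.uniform(lo, hi)
        elif i in down_idx:
            log2fc[i] = -rng.uniform(lo, hi)
    # neighbor co-regulation: neighbors of >10-fold genes pushed >3-fold
    induced = {i for i in up_idx if 2.0 ** log2fc[i] > 10.0}
    coreg_flag = np.zeros(n, dtype=bool)
    if config.planted_structure and config.coreg_rho > 0 and induced:
        order: dict[str, list[int]] = {}
        for i, g in enumerate(genes):
            order.setdefault(g.chrom, []).append(i)
        for idxs in order.values():
            idxs.sort(key=lambda i: (genes[i].tss, genes[i].gene_id))
            pos = {i: j for j, i in enumerate(idxs)}
            for i in sorted(induced):
                if i not in pos:
                    continue
                j = pos[i]
                for k in (j - 1, j + 1):
                    if 0 <= k < len(idxs):
                        nb = idxs[k]
                        # only unregulated neighbors are recruited; planted
                        # up/down genes keep their own fold change
                        if nb in up_idx or nb in down_idx or coreg_flag[nb]:
                            continue
                        if rng.random() < config.coreg_rho:
                            log2fc[nb] = rng.uniform(*config.coreg_log2fold_range)
                            coreg_flag[nb] = True
    base = np.exp(rng.normal(config.base_expr_log_mean, config.base_expr_log_sd, size=n))
    expr = pd.DataFrame(
        {cond_a: base, cond_b: base * (2.0 ** log2fc)}, index=pd.Index(gene_ids, name="gene_id")
    )
    expression = ExpressionTable(expr, floor=1.0)

    # --- planted peak elements ----------------------------------------
    elements: list[dict] = []

    def lognorm(mean_log: float, sd_log: float) -> float:
        return float(np.exp(rng.normal(mean_log, sd_log)))

    def draw_width() -> int:
        return max(int(np.exp(rng.normal(config.peak_width_log_mean, config.peak_width_log_sd))), 50)

    def add_element(kind: str, chrom: str, center: int, width: int, gene_id: str | None,
                    sig_a: float, sig_b: float, cluster: bool = False) -> None:
        center = int(np.clip(center, width, config.chrom_length - width))
        elements.append(
            dict(
                element_id=f"{kind}{len(elements):05d}", kind=kind, chrom=chrom,
                center=center, width=width, gene_id=gene_id or "",
                sig_a=sig_a, sig_b=sig_b, cluster=cluster, motif=False, tf=False,
            )
        )

    def uniform_position() -> tuple[str, int]:
        # margin only wide enough for the peak body, so that uniformly
        # placed elements match a uniform-over-chromosome null closely
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        return chrom, int(rng.integers(1_000, config.chrom_length - 1_000))

    # promoter peaks: both conditions, equal signal
    for g in genes:
        if rng.random() < config.promoter_peak_rate:
            s = lognorm(config.signal_promoter_log_mean, config.signal_promoter_log_sd)
            add_element("prom", g.chrom, g.tss + int(rng.integers(-100, 101)),
                        draw_width(), g.gene_id, s, s * float(np.exp(rng.normal(0, 0.05))))

    # condition-specific peaks near regulated genes (or uniform in the null)
    def specific_signals(own_is_b: bool) -> tuple[float, float]:
        own = lognorm(config.signal_specific_log_mean, config.signal_specific_log_sd)
        other = 0.0 if rng.random() < config.q_absent else lognorm(
            config.signal_low_log_mean, config.signal_low_log_sd
        )
        return (other, own) if own_is_b else (own, other)

    def plant_specific(kind: str, gene_indices: set[int], lam: float) -> None:
        own_is_b = kind == "spec_b"
        if config.planted_structure:
            for i in sorted(gene_indices):
                g = genes[i]
                k = int(rng.poisson(lam))
                if k == 0:
                    continue
                offsets = _separated_offsets(
                    rng, k, config.placement_halfwidth,
                    config.min_tss_distance, config.min_center_separation,
                )
                for off in offsets:
                    sa, sb = specific_signals(own_is_b)
                    add_element(kind, g.chrom, g.tss + int(off), draw_width(), g.gene_id, sa, sb)
        else:
            total = int(rng.poisson(lam * len(gene_indices)))
            for _ in range(total):
                chrom, center = uniform_position()
                sa, sb = specific_signals(own_is_b)
                add_element(kind, chrom, center, draw_width(), None, sa, sb)

    plant_specific("spec_b", up_idx, config.peaks_per_up_gene)
    plant_specific("spec_a", down_idx, config.peaks_per_down_gene)

    # clusters of B-specific peaks near anchor genes
    anchor_flag = np.zeros(n, dtype=bool)
    if config.cluster_anchors > 0:
        pool = sorted(up_idx) if config.planted_structure else list(range(n))
        anchors = rng.choice(pool, size=min(config.cluster_anchors, len(pool)), replace=False)
        step = config.cluster_span / max(config.cluster_size - 1, 1)
        for i in anchors:
            anchor_flag[i] = True
            g = genes[i]
            offset = int(rng.integers(2_000, 8_001))
            if rng.random() < 0.5:
                start = g.tss + offset
            else:  # keep the whole span clear of the promoter window
                start = g.tss - offset - config.cluster_span
            for j in range(config.cluster_size):
                center = start + int(j * step) + int(rng.integers(-150, 151))
                sa, sb = specific_signals(True)
                add_element("spec_b", g.chrom, center, config.cluster_peak_width,
                            g.gene_id, sa, sb, cluster=True)

    # invariant peaks, uniform placement, near-equal signals
    for _ in range(config.n_invariant):
        chrom, center = uniform_position()
        s = lognorm(config.signal_invariant_log_mean, config.signal_invariant_log_sd)
        add_element("inv", chrom, center, draw_width(),
                    None, s, s * float(np.exp(rng.normal(0, 0.05))))

    # --- TF sites -------------------------------------------------------
    tf_sites: list[tuple[str, int, int]] = []
    for el in elements:
        if el["kind"] == "spec_b" and rng.random() < config.tf_overlap_fraction:
            el["tf"] = True
            tf_sites.append(
                (el["chrom"], el["center"] - config.tf_site_halfwidth,
                 el["center"] + config.tf_site_halfwidth)
            )
    for _ in range(config.n_background_tf_sites):
        chrom, center = uniform_position()
        tf_sites.append((chrom, center - config.tf_site_halfwidth,
                         center + config.tf_site_halfwidth))
    tf_sites.sort()

    # --- center sequences with planted motif instances ------------------
    sequences: dict[str, str] = {}
    plant_at = (config.seq_length - len(consensus)) // 2
    for el in elements:
        seq = _random_seq(rng, config.seq_length, comp)
        rate = {"spec_b": config.motif_rate_b, "spec_a": config.motif_rate_a}.get(el["kind"], 0.0)
        if rate > 0 and rng.random() < rate:
            el["motif"] = True
            inst = consensus if rng.random() < 0.5 else consensus.translate(REVCOMP)[::-1]
            seq = seq[:plant_at] + inst + seq[plant_at + len(consensus):]
        sequences[el["element_id"]] = seq

    # --- peak sets ------------------------------------------------------
    def make_peak(el: dict, signal: float) -> Peak:
        start = el["center"] - el["width"] // 2
        return Peak(el["chrom"], start, start + el["width"], signal, el["element_id"])

    peaks_a = PeakSet(cond_a, [make_peak(el, el["sig_a"]) for el in elements if el["sig_a"] > 0],
                      fdr_cutoff=1e-4)
    peaks_b = PeakSet(cond_b, [make_peak(el, el["sig_b"]) for el in elements if el["sig_b"] > 0],
                      fdr_cutoff=1e-4)

    # --- a demo signal track for condition B ---------------------------
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for p in peaks_b:
        per_chrom.setdefault(p.chrom, []).append((p.start, p.end, p.signal))
    clipped: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        out = []
        prev_end = -1
        for s, e, v in ivals:
            s = max(s, prev_end)
            if s < e:
                out.append((s, e, v))
                prev_end = e
        clipped[chrom] = out
    track = SignalTrack(clipped)

    # --- truth ----------------------------------------------------------
    truth_peaks = pd.DataFrame(
        [
            {
                "element_id": el["element_id"], "kind": el["kind"], "chrom": el["chrom"],
                "center": el["center"], "width": el["width"], "gene_id": el["gene_id"],
                "motif_planted": el["motif"], "tf_overlap": el["tf"],
                "cluster_member": el["cluster"],
            }
            for el in elements
        ]
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "regulated": [
                "up" if i in up_idx else ("down" if i in down_idx else "none") for i in range(n)
            ],
            "fold": 2.0 ** log2fc,
            "induced10": [i in induced for i in range(n)],
            "cluster_anchor": anchor_flag,
            "coreg_neighbor": coreg_flag,
        }
    )
    return StudyBundle(
        config=config, genes=genes, expression=expression,
        peaks_a=peaks_a, peaks_b=peaks_b, tf_sites=tf_sites,
        sequences=sequences, track=track, motif=motif,
        truth=SyntheticTruth(peaks=truth_peaks, genes=truth_genes),
    )


def null_study(config: SyntheticConfig | None = None, seed: int | None = None) -> StudyBundle:
    """Bundle with no planted associations: specific-class peaks placed
    uniformly (no gene linkage, no clusters), rho = 0, no TF overlap, and
    equal motif plant rates in both classes.

    The class/signal structure itself is retained so that specificity
    labels — which the motif screen needs as foreground/background — still
    exist; only the regulatory structure is removed. Downstream tests on a
    null bundle must be non-significant at nominal rates.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    null_rate = 0.7  # equal in both classes; high enough for a stable ratio
    config = replace(
        config,
        planted_structure=False,
        coreg_rho=0.0,
        tf_overlap_fraction=0.0,
        cluster_anchors=0,
        motif_rate_a=null_rate,
        motif_rate_b=null_rate,
    )
    return generate_study(config)
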