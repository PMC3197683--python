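"""Neighbor-gene co-regulation test.

Neighbors of a seed gene are the genes immediately adjacent to it in TSS
order on the same chromosome (one on each side), with the seed genes
themselves excluded and shared neighbors de-duplicated. The test asks
whether neighbors of highly induced genes (>10-fold by default) are
up-regulated (>3-fold) more often than the gene universe, with a one-sided
Fisher exact test, plus a random-seed-set control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneModel

__all__ = [
    "CoregulationResult",
    "neighbor_set",
    "fisher_one_sided",
    "coregulation_test",
    "random_gene_control",
]


@dataclass
class CoregulationResult:
    n_neighbors: int
    n_neighbors_up3: int
    n_total: int
    n_total_up3: int
    fisher_p_one_sided: float
    background: str
    induced_fold: float
    up_fold: float
    n_seed: int


def _tss_order(genes: Sequence[GeneModel]) -> dict[str, list[str]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return {
        chrom: [g.gene_id for g in sorted(gl, key=lambda g: (g.tss, g.gene_id))]
        for chrom, gl in by_chrom.items()
    }


def neighbor_set(genes: Sequence[GeneModel], seed_genes: Iterable[str]) -> set[str]:
    """Genes immediately adjacent (previous/next by TSS order, same
    chromosome) to any seed gene; de-duplicated, seeds excluded."""
    seeds = set(seed_genes)
    known = {g.gene_id for g in genes}
    missing = seeds - known
    if missing:
        raise ValueError(f"seed genes absent from annotation: {sorted(missing)[:3]}")
    neighbors: set[str] = set()
    for ordered in _tss_order(genes).values():
        index = {gid: i for i, gid in enumerate(ordered)}
        for gid in ordered:
            if gid in seeds:
                i = index[gid]
                if i > 0:
                    neighbors.add(ordered[i - 1])
                if i + 1 < len(ordered):
                    neighbors.add(ordered[i + 1])
    return neighbors - seeds


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for the 2x2 table [[a, b], [c, d]], testing
    enrichment of column 1 in row 1: P(X >= a) for X hypergeometric with
    the table's margins fixed. Zero margins give p = 1."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == N or col1 == N:
        return 1.0
    return float(min(1.0, hypergeom.sf(a - 1, N, col1, row1)))


def coregulation_test(
    genes: Sequence[GeneModel],
    regulation: pd.DataFrame,
    induced_fold: float = 10.0,
    up_fold: float = 3.0,
    background: str = "all_genes",
) -> CoregulationResult:
    """Test whether neighbors of genes induced > induced_fold are enriched
    for genes up-regulated > up_fold.

    ``background="all_genes"`` contrasts neighbors against the whole gene
    universe (the construction matching a printed neighbors-vs-total
    sentence); ``"disjoint"`` removes the neighbors from the background so
    the two rows are disjoint.
    """
    if background not in ("all_genes", "disjoint"):
        raise ValueError("background must be 'all_genes' or 'disjoint'")
    fc = regulation["fold_change"]
    gene_ids = [g.gene_id for g in genes]
    fc = fc.reindex(gene_ids).dropna()
    seeds = set(fc.index[fc > induced_fold])
    neighbors = neighbor_set(genes, seeds)
    neighbors &= set(fc.index)
    if not neighbors:
        raise ValueError("empty neighbor set")
    up = fc > up_fold
    n_nb = len(neighbors)
    a = int(up.loc[sorted(neighbors)].sum())
    n_total = len(fc)
    n_total_up = int(up.sum())
    if background == "all_genes":
        c, d = n_total_up, n_total - n_total_up
    else:
        c = n_total_up - a
        d = (n_total - n_nb) - c
    p = fisher_one_sided(a, n_nb - a, c, d)
    return CoregulationResult(
        n_neighbors=n_nb,
        n_neighbors_up3=a,
        n_total=n_total,
        n_total_up3=n_total_up,
        fisher_p_one_sided=p,
        background=background,
        induced_fold=induced_fold,
        up_fold=up_fold,
        n_seed=len(seeds),
    )


def random_gene_control(
    genes: Sequence[GeneModel],
    regulation: pd.DataFrame,
    n_seed: int,
    n_trials: int = 1000,
    seed: int = 0,
    up_fold: float = 3.0,
    observed_fraction: float | None = None,
) -> dict[str, float]:
    """Neighbor up-regulation fraction for uniformly random seed sets.

    Returns the mean and sd of the neighbor up-fraction over trials, and —
    when ``observed_fraction`` is given — an empirical p: the fraction of
    trials whose neighbor up-fraction is at least the observed one (with
    the +1 correction). Deterministic given the seed.
    """
    gene_ids = [g.gene_id for g in genes]
    if n_seed >= len(gene_ids):
        raise ValueError("n_seed must be smaller than the number of genes")
    up = (regulation["fold_change"] > up_fold).reindex(gene_ids).fillna(False)
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_trials, dtype=float)
    ids = np.array(gene_ids)
    for t in range(n_trials):
        chosen = rng.choice(ids, size=n_seed, replace=False)
        nb = neighbor_set(genes, chosen)
        fractions[t] = up.loc[sorted(nb)].mean() if nb else 0.0
    out = {
        "mean_fraction": float(fractions.mean()),
        "sd_fraction": float(fractions.std(ddof=1)) if n_trials > 1 else 0.0,
        "n_trials": float(n_trials),
    }
    if observed_fraction is not None:
        ge = int(np.count_nonzero(fractions >= observed_fraction))
        out["empirical_p"] = (1 + ge) / (n_trials + 1)
    return out
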