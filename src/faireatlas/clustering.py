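"""Spatial clustering statistics for genomic site positions.

A cluster at window width w is a maximal chain of sites on one chromosome
in which consecutive sites are at most w apart; a chain of at least
``min_size`` sites counts once. Observed cluster counts are compared with
an empirical null that redraws the same number of sites per chromosome
uniformly over the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClusterReport",
    "nearest_distance_histogram",
    "count_clusters",
    "cluster_null_test",
]

Sites = Mapping[str, Sequence[int]]


@dataclass
class ClusterReport:
    """Observed cluster count against the uniform-random null."""

    window_w: int
    n_clusters_observed: int
    null_mean: float
    null_sd: float
    empirical_p: float  # (1 + #{null >= observed}) / (n_trials + 1)
    n_trials: int
    seed: int


def nearest_neighbor_distances(sites: Sites) -> np.ndarray:
    """Per site, distance to the nearest other site on the same chromosome.

    Sites alone on their chromosome are excluded.
    """
    dists = []
    for positions in sites.values():
        pos = np.sort(np.asarray(positions, dtype=np.int64))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        left = np.concatenate(([np.iinfo(np.int64).max], gaps))
        right = np.concatenate((gaps, [np.iinfo(np.int64).max]))
        dists.append(np.minimum(left, right))
    if not dists:
        raise ValueError("nearest-neighbor distances need >=2 sites on some chromosome")
    return np.concatenate(dists)


def nearest_distance_histogram(
    sites: Sites,
    bin_edges: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of nearest-neighbor distances.

    Default bins are log-spaced from 100 bp to 10 Mb. Returns (counts,
    edges, distances).
    """
    d = nearest_neighbor_distances(sites)
    if bin_edges is None:
        bin_edges = np.logspace(2, 7, 26)
    counts, edges = np.histogram(d, bins=np.asarray(bin_edges, dtype=float))
    return counts, edges, d


def _count_from_sorted(pos: np.ndarray, window_w: int, min_size: int) -> int:
    """Cluster count for one chromosome's sorted positions: split into
    maximal chains at gaps > window_w and count chains of >= min_size."""
    n = len(pos)
    if n == 0:
        return 0
    if n == 1:
        return 1 if min_size <= 1 else 0
    close = np.diff(pos) <= window_w
    if min_size == 2:
        # one cluster per run of consecutive close gaps
        return int(np.count_nonzero(close & ~np.concatenate(([False], close[:-1]))))
    # general: chain sizes = run lengths of close gaps + 1, plus singletons
    padded = np.concatenate(([False], close, [False])).astype(np.int8)
    change = np.diff(padded)
    starts = np.flatnonzero(change == 1)
    ends = np.flatnonzero(change == -1)
    sizes = ends - starts + 1
    count = int(np.count_nonzero(sizes >= min_size))
    if min_size <= 1:
        count += n - int(sizes.sum())  # isolated sites are size-1 chains
    return count


def count_clusters(sites: Sites, window_w: int, min_size: int = 2) -> int:
    """Number of maximal chains of >= min_size sites with consecutive gaps
    <= window_w, summed over chromosomes."""
    if window_w < 1:
        raise ValueError("window_w must be >= 1")
    return sum(
        _count_from_sorted(np.sort(np.asarray(p, dtype=np.int64)), window_w, min_size)
        for p in sites.values()
    )


def _draw_unique(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct uniform positions in [0, length); cheap rejection redraw."""
    pos = np.unique(rng.integers(0, length, size=n))
    while len(pos) < n:
        extra = rng.integers(0, length, size=n - len(pos))
        pos = np.unique(np.concatenate((pos, extra)))
    return pos


def cluster_null_test(
    sites: Sites,
    window_w: int,
    genome: Mapping[str, int],
    n_trials: int = 1000,
    seed: int = 0,
    min_size: int = 2,
) -> ClusterReport:
    """Compare the observed cluster count with counts from uniformly
    redrawn sites (same number per chromosome, without replacement).

    empirical_p = (1 + #{null >= observed}) / (n_trials + 1); deterministic
    given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    per_chrom = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sites.items() if len(p)}
    for chrom, pos in per_chrom.items():
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} missing from genome lengths")
        if len(pos) > genome[chrom]:
            raise ValueError(f"more sites than bases on {chrom!r}")
    observed = count_clusters(per_chrom, window_w, min_size)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        total = 0
        for chrom, pos in per_chrom.items():
            draw = _draw_unique(rng, genome[chrom], len(pos))
            total += _count_from_sorted(draw, window_w, min_size)
        null_counts[t] = total
    ge = int(np.count_nonzero(null_counts >= observed))
    return ClusterReport(
        window_w=window_w,
        n_clusters_observed=observed,
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)) if n_trials > 1 else 0.0,
        empirical_p=(1 + ge) / (n_trials + 1),
        n_trials=n_trials,
        seed=seed,
    )
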