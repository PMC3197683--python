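"""Peak-gene linkage and expression-association statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from faireatlas.atlas import SpecificityTable
from faireatlas.expression import (
    assign_nearest_gene,
    fraction_regulated_by_peakcount,
    gene_motif_fraction,
    overlap_by_stratum,
    peakcount_by_expression_strata,
    peaks_near_tss,
    rank_genes_for_ontology,
    regulation_calls,
    vicinity_enrichment,
)
from faireatlas.io import ExpressionTable, GeneModel, Peak, PeakSet


def gene(gid, tss, chrom="chr1", strand="+"):
    return GeneModel(gid, chrom, strand, tss, tss, tss + 1000)


def peak(center, signal=1.0, pid=None, chrom="chr1"):
    return Peak(chrom, center - 50, center + 50, signal, pid or f"p{center}")


class TestRegulationCalls:
    def test_flags_nest(self):
        expr = ExpressionTable(
            pd.DataFrame({"a": [10, 10, 10, 10], "b": [15, 25, 45, 150]},
                         index=["g1", "g2", "g3", "g4"])
        )
        reg = regulation_calls(expr, "a", "b")
        assert reg.loc["g1"].tolist()[1:] == [False, False, False, False]
        assert reg.loc["g2", "up2"] and not reg.loc["g2", "up3"]
        assert reg.loc["g3", "up3"] and not reg.loc["g3", "induced10"]
        assert reg.loc["g4", "induced10"]
        assert not (reg["up2"] & reg["down2"]).any()
        assert (reg["induced10"] <= reg["up3"]).all() and (reg["up3"] <= reg["up2"]).all()


class TestAssignNearestGene:
    def test_single_gene_takes_all(self):
        genes = [gene("g1", 1000)]
        out = assign_nearest_gene([peak(50_000)], genes)
        assert out.loc["p50000", "gene_id"] == "g1"

    def test_distance_sign_and_value(self):
        out = assign_nearest_gene([peak(400)], [gene("g1", 0), gene("g2", 1000)])
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["distance"] == 400

    def test_equidistant_tie_break_smaller_tss(self):
        out = assign_nearest_gene([peak(500)], [gene("g1", 0), gene("g2", 1000)])
        assert out.iloc[0]["gene_id"] == "g1"

    def test_minus_strand_sign(self):
        out = assign_nearest_gene([peak(900)], [gene("g1", 1000, strand="-")])
        assert out.iloc[0]["distance"] == 100  # downstream of a minus-strand TSS

    def test_unassigned_chromosome_warns(self):
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_nearest_gene([peak(100, chrom="chrZ")], [gene("g1", 0)])
        assert out.iloc[0]["gene_id"] is None

    def test_matches_naive_scan(self, rng):
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(sorted(rng.integers(0, 10**6, 40)))]
        peaks = [peak(int(c), pid=f"q{i}") for i, c in enumerate(rng.integers(0, 10**6, 100))]
        out = assign_nearest_gene(peaks, genes)
        for p in peaks:
            best = min(genes, key=lambda g: (abs(g.tss - p.center), g.tss, g.gene_id))
            assert out.loc[p.peak_id, "gene_id"] == best.gene_id


class TestPeaksNearTss:
    @pytest.mark.parametrize("offset,counted", [(24_999, True), (25_000, True), (25_001, False)])
    def test_window_boundaries(self, offset, counted):
        genes = [gene("g1", 100_000)]
        out = peaks_near_tss(genes, [peak(100_000 + offset)])
        assert bool(out.loc["g1", "n_peaks"] == 1) is counted

    def test_matches_brute_force(self, rng):
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(0, 10**6, 100))]
        peaks = [peak(int(c), signal=float(s), pid=f"q{i}")
                 for i, (c, s) in enumerate(zip(rng.integers(0, 10**6, 100), rng.random(100)))]
        out = peaks_near_tss(genes, peaks, 25_000)
        for g in genes:
            near = [p for p in peaks if abs(p.center - g.tss) <= 25_000]
            assert out.loc[g.gene_id, "n_peaks"] == len(near)
            expect_max = max((p.signal for p in near), default=0.0)
            assert out.loc[g.gene_id, "max_signal"] == pytest.approx(expect_max)


class TestFractionRegulatedByPeakcount:
    def test_hand_example(self):
        reg = regulation_calls(
            ExpressionTable(pd.DataFrame(
                {"a": [10] * 6, "b": [30, 5, 5, 5, 30, 30]},
                index=[f"g{i}" for i in range(6)])),
            "a", "b",
        )
        counts = {"g4": 1, "g5": 1}  # two genes with one peak, both up
        out = fraction_regulated_by_peakcount(counts, reg, max_bucket=2)
        assert out.loc[0, "fraction_up"] == pytest.approx(0.25)  # 1 of 4
        assert out.loc[1, "fraction_up"] == pytest.approx(1.0)
        assert math.isnan(out.loc[2, "fraction_up"])  # empty bucket undefined
        assert out.loc[0, "n_genes"] == 4

    def test_all_unregulated(self):
        reg = regulation_calls(
            ExpressionTable(pd.DataFrame({"a": [10, 10], "b": [10, 11]}, index=["g1", "g2"])),
            "a", "b",
        )
        out = fraction_regulated_by_peakcount({"g1": 1}, reg, max_bucket=1)
        assert (out["fraction_up"].dropna() == 0).all()

    def test_top_bucket_pools(self):
        reg = regulation_calls(
            ExpressionTable(pd.DataFrame({"a": [10] * 3, "b": [30] * 3},
                                         index=["g0", "g1", "g2"])),
            "a", "b",
        )
        out = fraction_regulated_by_peakcount({"g0": 5, "g1": 9, "g2": 2}, reg, max_bucket=2)
        assert out.loc[2, "n_genes"] == 3


class TestStrata:
    def make_reg(self, folds):
        expr = ExpressionTable(pd.DataFrame(
            {"a": [10.0] * len(folds), "b": [10.0 * f for f in folds]},
            index=[f"g{i}" for i in range(len(folds))]))
        return regulation_calls(expr, "a", "b")

    def test_single_stratum_mean(self):
        reg = self.make_reg([1.0, 1.1])
        out = peakcount_by_expression_strata(
            {"lab": {"g0": 1, "g1": 3}}, reg, strata_edges=[-1, 1]
        )
        assert out.loc[0, "mean_lab"] == pytest.approx(2.0)

    def test_edge_value_goes_right(self):
        reg = self.make_reg([1.0, 2.0])  # log2fc 0 and 1
        out = peakcount_by_expression_strata(
            {"lab": {"g0": 4, "g1": 8}}, reg, strata_edges=[-1, 0, 1, 2]
        )
        # log2fc == 0 sits in the bin starting at 0; log2fc == 1 in [1, 2)
        assert out.loc[1, "mean_lab"] == pytest.approx(4.0)
        assert out.loc[2, "mean_lab"] == pytest.approx(8.0)
        assert math.isnan(out.loc[0, "mean_lab"])

    def test_matches_naive(self, rng):
        folds = 2.0 ** rng.normal(0, 1.5, 60)
        reg = self.make_reg(folds)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 5, 60))}
        edges = [-3, -1, 0, 1, 3]
        out = peakcount_by_expression_strata({"lab": counts}, reg, edges)
        log2fc = np.log2(reg["fold_change"].to_numpy())
        for i in range(4):
            sel = [f"g{j}" for j in range(60) if edges[i] <= log2fc[j] < edges[i + 1]]
            if sel:
                assert out.loc[i, "mean_lab"] == pytest.approx(np.mean([counts[g] for g in sel]))


class TestVicinityEnrichment:
    def test_closed_form(self):
        has_peak = pd.Series([True] * 5 + [False] * 5, index=[f"g{i}" for i in range(10)])
        res = vicinity_enrichment(has_peak, [f"g{i}" for i in range(5)])
        assert res["p_value"] == pytest.approx(1 / 252)

    def test_degenerate_margins(self):
        has_peak = pd.Series([False] * 6, index=[f"g{i}" for i in range(6)])
        assert vicinity_enrichment(has_peak, ["g0", "g1"])["p_value"] == 1.0

    def test_full_selection(self):
        has_peak = pd.Series([True, False, True], index=["g0", "g1", "g2"])
        assert vicinity_enrichment(has_peak, ["g0", "g1", "g2"])["p_value"] == 1.0

    def test_matches_enumeration_small(self, rng):
        from math import comb

        for _ in range(20):
            n, K, s = 12, int(rng.integers(1, 11)), int(rng.integers(1, 11))
            marked = rng.choice(n, size=K, replace=False)
            has_peak = pd.Series([i in set(marked) for i in range(n)],
                                 index=[f"g{i}" for i in range(n)])
            sel = [f"g{i}" for i in rng.choice(n, size=s, replace=False)]
            obs = int(has_peak.loc[sel].sum())
            # exact enumeration of the hypergeometric upper tail
            p = sum(comb(K, k) * comb(n - K, s - k) for k in range(obs, min(K, s) + 1)) / comb(n, s)
            assert vicinity_enrichment(has_peak, sel)["p_value"] == pytest.approx(p)


def spec_from_cells(cells):
    """cells: list of (cat_a, cat_b, chrom, start, end)."""
    rows = [
        {"chrom": c, "start": s, "end": e, "union_id": f"u{i}", "cat_a": ca,
         "cat_b": cb, "label": "x", "signal_a": 1.0, "signal_b": 1.0,
         "peak_ids_a": "", "peak_ids_b": ""}
        for i, (ca, cb, c, s, e) in enumerate(cells)
    ]
    return SpecificityTable(pd.DataFrame(rows), ("A", "B"))


class TestOverlapByStratum:
    def test_full_overlap(self):
        spec = spec_from_cells([("high", "low", "chr1", 0, 100), ("mid", "mid", "chr1", 200, 300)])
        matrix, summary = overlap_by_stratum(spec, [("chr1", 0, 1000)],
                                             [("high", "low"), ("mid", "mid")])
        assert matrix.loc["high", "low"] == 100.0
        assert summary == 100.0

    def test_no_overlap(self):
        spec = spec_from_cells([("high", "low", "chr1", 0, 100)])
        matrix, _ = overlap_by_stratum(spec, [("chr2", 0, 1000)], [])
        assert matrix.loc["high", "low"] == 0.0

    def test_unweighted_summary(self):
        spec = spec_from_cells(
            [("high", "low", "chr1", 0, 100), ("high", "low", "chr1", 200, 300),
             ("mid", "absent", "chr1", 400, 500)]
        )
        # high/low cell: 1 of 2 overlap = 50%; mid/absent: 1 of 1 = 100%
        sites = [("chr1", 50, 60), ("chr1", 450, 460)]
        matrix, summary = overlap_by_stratum(spec, sites, [("high", "low"), ("mid", "absent")])
        assert matrix.loc["high", "low"] == 50.0
        assert summary == pytest.approx(75.0)

    def test_empty_cell_excluded_from_summary(self):
        spec = spec_from_cells([("high", "low", "chr1", 0, 100)])
        matrix, summary = overlap_by_stratum(spec, [("chr1", 0, 1000)],
                                             [("high", "low"), ("low", "high")])
        assert math.isnan(matrix.loc["low", "high"])
        assert summary == 100.0

    def test_invariant_under_tf_site_merge(self, rng):
        from faireatlas.intervals import merge_intervals

        cells = [(ca, cb, "chr1", int(s), int(s) + 80)
                 for ca, cb, s in zip(
                     rng.choice(["high", "mid", "low"], 30),
                     rng.choice(["high", "mid", "low"], 30),
                     rng.integers(0, 20_000, 30))]
        spec = spec_from_cells(cells)
        sites = [("chr1", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 20_000, 40), rng.integers(10, 500, 40))]
        m1, _ = overlap_by_stratum(spec, sites, [])
        m2, _ = overlap_by_stratum(spec, merge_intervals(sites), [])
        pd.testing.assert_frame_equal(m1, m2)


class TestGeneMotifFraction:
    def test_extremes(self):
        genes = [gene(f"g{i}", 100_000 * (i + 1)) for i in range(4)]
        expr = ExpressionTable(pd.DataFrame(
            {"a": [10] * 4, "b": [30, 30, 5, 5]}, index=[g.gene_id for g in genes]))
        reg = regulation_calls(expr, "a", "b")
        all_peaks = [peak(g.tss + 5000, pid=f"np{i}") for i, g in enumerate(genes)]
        out = gene_motif_fraction(genes, [], all_peaks, [], reg)
        assert (out["fraction_with_motif"].dropna() == 0).all()
        out = gene_motif_fraction(genes, all_peaks, all_peaks, [], reg)
        assert (out["fraction_with_motif"].dropna() == 1).all()

    def test_planted_cell_largest(self):
        genes = [gene(f"g{i}", 100_000 * (i + 1)) for i in range(8)]
        folds = [30, 30, 30, 30, 5, 5, 5, 5]
        expr = ExpressionTable(pd.DataFrame(
            {"a": [10] * 8, "b": [10 * f for f in folds]}, index=[g.gene_id for g in genes]))
        reg = regulation_calls(expr, "a", "b")
        tf_sites = [("chr1", g.tss + 4000, g.tss + 4200) for g in genes[:2] + genes[4:6]]
        all_peaks = [peak(g.tss + 5000, pid=f"np{i}") for i, g in enumerate(genes)]
        motif_peaks = [all_peaks[0], all_peaks[1]]  # only bound+induced genes
        out = gene_motif_fraction(genes, motif_peaks, all_peaks, tf_sites, reg)
        target = out.loc[(True, True), "fraction_with_motif"]
        others = out.drop(index=(True, True))["fraction_with_motif"].dropna()
        assert (target > others).all()


class TestRankGenes:
    def test_ordering(self):
        genes = [gene("a", 100_000), gene("b", 300_000), gene("c", 500_000)]
        peaks = [peak(100_000 + 5000, 2.0, "p1"), peak(100_000 - 3000, 1.0, "p2"),
                 peak(300_000 + 1000, 9.0, "p3")]
        ranked = rank_genes_for_ontology(genes, peaks, top_n=10)
        assert ranked == ["a", "b", "c"]  # 2 peaks > 1 peak > 0

    def test_count_tie_broken_by_max_signal(self):
        genes = [gene("a", 100_000), gene("b", 300_000)]
        peaks = [peak(100_000 + 5000, 2.0, "p1"), peak(300_000 + 1000, 9.0, "p3")]
        assert rank_genes_for_ontology(genes, peaks, top_n=2) == ["b", "a"]

    def test_full_tie_lexicographic_and_truncation(self):
        genes = [gene("b", 100_000), gene("a", 300_000)]
        assert rank_genes_for_ontology(genes, [], top_n=1) == ["a"]
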