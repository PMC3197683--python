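"""Peak atlas: promoter calls, genomic context, union peaks, tertile
specificity, average profiles."""

import numpy as np
import pytest

from faireatlas.atlas import (
    average_profile,
    build_union_peaks,
    classify_promoter,
    default_label_map,
    genomic_distribution,
    tertile_specificity,
)
from faireatlas.io import GeneModel, Peak, PeakSet, SignalTrack


def peak_at(center, signal=1.0, pid="p", chrom="chr1", width=100):
    start = center - width // 2
    return Peak(chrom, start, start + width, signal, pid)


class TestClassifyPromoter:
    @pytest.mark.parametrize(
        "center,expected", [(10_000, True), (10_500, True), (10_501, False), (9_500, True)]
    )
    def test_inclusive_boundary(self, toy_genes, center, expected):
        ps = PeakSet("x", [peak_at(center, pid="q", width=2)])
        prom, nonprom = classify_promoter(ps, toy_genes, half_window=500)
        assert (len(prom) == 1) is expected
        assert len(prom) + len(nonprom) == 1

    def test_empty_genes_warns(self, toy_peaks):
        with pytest.warns(UserWarning, match="non-promoter"):
            prom, nonprom = classify_promoter(toy_peaks, [])
        assert not prom and len(nonprom) == len(toy_peaks)

    def test_partition_exhaustive(self, toy_peaks, toy_genes):
        prom, nonprom = classify_promoter(toy_peaks, toy_genes)
        assert {p.peak_id for p in prom} | {p.peak_id for p in nonprom} == {
            p.peak_id for p in toy_peaks
        }
        assert not ({p.peak_id for p in prom} & {p.peak_id for p in nonprom})


class TestGenomicDistribution:
    def test_categories_and_precedence(self, toy_genes):
        peaks = PeakSet(
            "x",
            [
                peak_at(10_050, pid="prom"),          # within 500 of g1 TSS
                peak_at(86_900, pid="upstream"),      # 3.1 kb upstream of + strand g3
                peak_at(19_900, pid="exon"),          # inside g1 terminal exon
                peak_at(15_000, pid="intron"),        # inside g1 span, not exon
                peak_at(500_000, pid="distal", chrom="chr2"),
            ],
        )
        cats, fractions = genomic_distribution(peaks, toy_genes)
        assert cats == {
            "prom": "promoter",
            "upstream": "proximal_upstream",
            "exon": "exon",
            "intron": "intron",
            "distal": "distal",
        }
        assert fractions.sum() == pytest.approx(1.0)

    def test_minus_strand_upstream(self, toy_genes):
        # g2 is minus strand at 60_000: upstream means larger coordinates
        cats, _ = genomic_distribution(PeakSet("x", [peak_at(63_000, pid="u")]), toy_genes)
        assert cats["u"] == "proximal_upstream"

    def test_fractions_sum_to_one(self, toy_peaks, toy_genes):
        _, fractions = genomic_distribution(toy_peaks, toy_genes)
        assert fractions.sum() == pytest.approx(1.0)


class TestBuildUnionPeaks:
    def test_single_condition_peak(self):
        a = PeakSet("A", [Peak("chr1", 0, 100, 5.0, "a1")])
        b = PeakSet("B", [])
        (u,) = build_union_peaks(a, b)
        assert u.detected == (True, False)
        assert u.signal == (5.0, 0.0)

    def test_merge_with_max_signal(self):
        a = PeakSet("A", [Peak("chr1", 0, 100, 5.0, "a1")])
        b = PeakSet("B", [Peak("chr1", 50, 150, 8.0, "b1")])
        (u,) = build_union_peaks(a, b)
        assert (u.start, u.end) == (0, 150)
        assert u.signal == (5.0, 8.0)
        assert u.peak_ids == (("a1",), ("b1",))

    def test_transitive_chain(self):
        a = PeakSet("A", [Peak("chr1", 0, 100, 1, "a1"), Peak("chr1", 180, 280, 3, "a2")])
        b = PeakSet("B", [Peak("chr1", 90, 190, 2, "b1")])
        (u,) = build_union_peaks(a, b)
        assert (u.start, u.end) == (0, 280)
        assert u.signal == (3.0, 2.0)

    def test_every_peak_contributes_once(self, rng):
        mk = lambda cond, n: PeakSet(
            cond,
            [Peak("chr1", int(s), int(s) + int(w), 1.0, f"{cond}{i}")
             for i, (s, w) in enumerate(zip(rng.integers(0, 50_000, n), rng.integers(50, 800, n)))],
        )
        a, b = mk("A", 80), mk("B", 80)
        union = build_union_peaks(a, b)
        seen = [pid for u in union for ids in u.peak_ids for pid in ids]
        assert sorted(seen) == sorted([p.peak_id for p in a] + [p.peak_id for p in b])


def make_union(signals_a, signals_b):
    """Union peaks from parallel signal lists (0 = absent), disjoint coords."""
    out = []
    for i, (sa, sb) in enumerate(zip(signals_a, signals_b)):
        peaks_a = (f"a{i}",) if sa > 0 else ()
        peaks_b = (f"b{i}",) if sb > 0 else ()
        from faireatlas.atlas import UnionPeak

        out.append(
            UnionPeak("chr1", 1000 * i, 1000 * i + 100, f"u{i}", (sa, sb),
                      (sa > 0, sb > 0), (peaks_a, peaks_b))
        )
    return out


class TestTertileSpecificity:
    def test_tertile_arithmetic_nine_peaks(self):
        union = make_union(list(range(1, 10)), [5] * 9)
        spec = tertile_specificity(union, ("A", "B"))
        cats = spec.df["cat_a"].tolist()
        assert cats == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_absent_high_is_specific(self):
        union = make_union([0, 1, 2, 3, 4], [9, 1, 2, 3, 4])
        spec = tertile_specificity(union, ("A", "B"))
        row = spec.df.set_index("union_id").loc["u0"]
        assert row["cat_a"] == "absent"
        assert row["cat_b"] == "high"
        assert row["label"] == "specific_to_B"

    def test_high_high_invariant(self):
        union = make_union([1, 2, 9], [1, 2, 9])
        spec = tertile_specificity(union, ("A", "B"))
        assert spec.df.set_index("union_id").loc["u2", "label"] == "invariant"

    def test_too_few_detected_rejected(self):
        union = make_union([1, 2, 0], [1, 2, 3])
        with pytest.raises(ValueError, match="fewer than 3"):
            tertile_specificity(union, ("A", "B"))

    def test_tertiles_partition_in_thirds(self, rng):
        signals_a = rng.lognormal(2, 1, 100)
        signals_b = np.where(rng.random(100) < 0.3, 0.0, rng.lognormal(2, 1, 100))
        union = make_union(signals_a, signals_b)
        spec = tertile_specificity(union, ("A", "B"))
        for col in ("cat_a", "cat_b"):
            counts = spec.df[col].value_counts()
            sizes = [counts.get(c, 0) for c in ("low", "mid", "high")]
            assert max(sizes) - min(sizes) <= 1
            assert sum(sizes) + counts.get("absent", 0) == 100

    def test_condition_swap_symmetry(self, rng):
        signals_a = rng.lognormal(2, 1, 60)
        signals_b = np.where(rng.random(60) < 0.4, 0.0, rng.lognormal(3, 1, 60))
        fwd = tertile_specificity(make_union(signals_a, signals_b), ("A", "B"))
        rev = tertile_specificity(make_union(signals_b, signals_a), ("A", "B"))
        swap = {"specific_to_A": "specific_to_B", "specific_to_B": "specific_to_A"}
        assert [swap.get(l, l) for l in fwd.df["label"]] == rev.df["label"].tolist()
        assert fwd.df["cat_a"].tolist() == rev.df["cat_b"].tolist()

    def test_labels_partition(self, rng):
        union = make_union(rng.lognormal(2, 1, 30), rng.lognormal(2, 1, 30))
        spec = tertile_specificity(union, ("A", "B"))
        assert set(spec.df["label"]) <= {
            "specific_to_A", "specific_to_B", "invariant", "unclassified",
        }
        assert len(spec.df) == 30

    def test_default_label_map_cells(self):
        m = default_label_map("A", "B")
        assert m[("high", "low")] == "specific_to_A"
        assert m[("mid", "absent")] == "specific_to_A"
        assert m[("absent", "mid")] == "specific_to_B"
        assert m[("mid", "mid")] == "invariant"
        assert m[("high", "low")] != m[("low", "high")]
        assert m[("low", "mid")] == "unclassified"
        assert ("absent", "absent") not in m


def naive_profile(track, anchors, half_window, bin_size):
    """Per-base oracle for average_profile."""
    span = 2 * half_window
    rows = []
    for anchor in anchors:
        chrom, pos = anchor[0], anchor[1]
        strand = anchor[2] if len(anchor) > 2 else "+"
        vals = [track.value_at(chrom, p) for p in range(pos - half_window, pos + half_window)]
        if strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    mean = np.mean(rows, axis=0)
    return np.array([mean[i : i + bin_size].mean() for i in range(0, span, bin_size)])


class TestAverageProfile:
    def test_constant_track(self):
        track = SignalTrack({"chr1": [(0, 10_000, 3.0)]})
        prof = average_profile(track, [("chr1", 5000)], half_window=500, bin_size=50)
        assert np.allclose(prof.values, 3.0)

    def test_delta_response(self):
        track = SignalTrack({"chr1": [(5000, 5001, 1.0)]})
        prof = average_profile(track, [("chr1", 5000)], half_window=100, bin_size=20)
        # anchor base is the first base of the right-of-center bin
        assert prof.values[5] == pytest.approx(1 / 20)
        assert prof.values.sum() == pytest.approx(1 / 20)

    def test_matches_naive_oracle(self, rng):
        ivals = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(1, 50))
            end = pos + int(rng.integers(1, 40))
            ivals.append((pos, end, float(rng.random())))
            pos = end
        track = SignalTrack({"chr1": ivals})
        anchors = [("chr1", 300, "+"), ("chr1", 700, "-"), ("chr1", 50, "+")]
        prof = average_profile(track, anchors, half_window=120, bin_size=10)
        assert np.allclose(prof.values, naive_profile(track, anchors, 120, 10))

    def test_strand_reversal(self):
        track = SignalTrack({"chr1": [(900, 1000, 2.0)]})
        plus = average_profile(track, [("chr1", 1000, "+")], 200, 10)
        minus = average_profile(track, [("chr1", 1000, "-")], 200, 10)
        assert np.allclose(plus.values, minus.values[::-1])

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            average_profile(SignalTrack({}), [], 100, 10)
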