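"""PWM motif scanning and differential enrichment between peak classes.

Scans the center sequences of day8- vs day0-specific peaks with the
planted NFI-like motif at an exact p-value threshold of 1e-4, and reports
the hit-density enrichment ratio (with the 1.20 / 0.833 reporting
thresholds) plus sequence-level presence Fisher tests against the opposite
class and against dinucleotide shuffles.
"""

import faireatlas as fa

bundle = fa.generate_study(fa.SyntheticConfig(seed=0))
_, na = fa.classify_promoter(bundle.peaks_a, bundle.genes)
_, nb = fa.classify_promoter(bundle.peaks_b, bundle.genes)
union = fa.build_union_peaks(fa.PeakSet("day0", na), fa.PeakSet("day8", nb))
spec = fa.tertile_specificity(union, ("day0", "day8"))

print(f"motif: {bundle.motif.name}, consensus {bundle.motif.consensus()}")
screen = fa.motif_screen(spec, [bundle.motif], peak_sequences=bundle.sequences,
                         top_n=2000, center_width=150, p_threshold=1e-4,
                         background="uniform", seed=0)
for r in screen.itertuples():
    flag = " (reported as enriched)" if r.enriched else ""
    print(f"  {r.direction}: {r.fg_hits} hits / {r.fg_bp} bp vs "
          f"{r.bg_hits} / {r.bg_bp} bp -> ratio {r.ratio:.2f}{flag}; "
          f"presence p {r.presence_p:.2e}, vs shuffles {r.shuffle_p:.2e}")
print("\nThe planted rate ratio is 0.30/0.05 = 6; with only ~10 background "
      "hits the per-seed estimate scatters around that value but clears the "
      "1.20 reporting threshold decisively. The reverse direction is its "
      "reciprocal and is not enriched.")

# a single hit in detail
hits = fa.scan_sequences({k: bundle.sequences[k] for k in list(bundle.sequences)[:50]},
                         bundle.motif, p_threshold=1e-4)
if hits:
    h = hits[0]
    print(f"\nexample hit: {h.sequence_id} offset {h.offset} strand {h.strand} "
          f"score {h.score:.1f} bits, p = {h.p_value:.2e}")
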