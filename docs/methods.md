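# Methods

## Coordinate conventions and inputs

All internal coordinates are 0-based, half-open (BED arithmetic); any
1-based source must be converted at the reader boundary. Overlap means ≥1
shared base: abutting intervals do not overlap and are never merged. Peak
"centers" are the floor of the interval midpoint — summit positions are
not part of the input model. Window tests against a TSS (±500 bp promoter,
±25 kb vicinity) use the peak center and inclusive bounds.

Peaks arrive pre-called with a signal column (height statistic in
arbitrary units). Signals are only ever ranked or maximized, never
interpreted on an absolute scale, so any monotone transformation of the
peak caller's height column gives identical specificity calls. Expression
values are floored (default 1.0, standing in for the platform's detection
limit) before fold changes, so fold changes are always finite.

## Tertile condition specificity

Union peaks are built by transitively merging the two conditions' peaks
wherever they share ≥1 bp; each condition's signal on a union peak is the
maximum over its contributing peaks, and a condition with no contribution
is *absent*. Within each condition, detected union peaks are ranked
ascending by signal (ties broken by (chrom, start) for stability) and
assigned tertile index ⌊3(rank−1)/n⌋ → low/mid/high, so tertile sizes
differ by at most one. The (category_A, category_B) cell determines the
label through a configurable map. The default map requires a contrast of
at least two tertile steps for a specific call:

- specific to X: (high_X, low_Y), (high_X, absent_Y), (mid_X, absent_Y)
- invariant: (high, high), (high, mid), (mid, high), (mid, mid), (low, low)
- everything else: unclassified.

This is deliberately conservative — a (high, mid) peak is treated as
shared, not gained — and the map is an explicit argument for users whose
figure-style definition differs. Specificity is computed on non-promoter
peaks; promoter peaks are largely condition-invariant and would dilute the
tertile boundaries.

## Clustering statistic

A cluster at window width w is a maximal chain of sites (peak centers) on
one chromosome in which consecutive sites are ≤ w apart, counted once when
it has ≥ `min_size` sites. `min_size` defaults to 2 (a pair is the
smallest cluster; the nearest-neighbor interval histogram is a pairwise
analysis, which supports this reading) and can be set to 3 for the
stricter reading of "more than two". The null redraws, per chromosome, the
same number of sites uniformly without replacement over the chromosome
length, and the empirical p uses the +1 correction,
p = (1 + #{null ≥ observed})/(n_trials + 1), so p is never 0 and the test
is valid at finite trial counts. No mappability or accessibility
correction is applied — the null is uniform by construction, which is also
exactly how the synthetic generator places unstructured sites.

## Neighbor co-regulation

Gene adjacency is TSS order per chromosome; the neighbor set of the seed
genes is the union of each seed's immediate predecessor and successor,
minus the seeds, de-duplicated. The one-sided Fisher test is the
upper-tail hypergeometric probability with the table's margins fixed
(scipy's hypergeometric survival function; an independent exhaustive
enumeration oracle checks it in the tests). Two background constructions
are implemented: `all_genes` contrasts the neighbor set against the whole
gene universe (the construction that matches a printed
neighbors-vs-total-genes sentence, though its rows are not disjoint) and
`disjoint` removes the neighbors from the background. Both are reported;
`all_genes` is the default. The random control redraws seed sets of the
observed size uniformly and reports the mean ± sd neighbor up-fraction and
an empirical p.

## Motif scanning

Scores are log-odds in bits: log2(((p + κ·b)/(1 + κ))/b) with pseudocount
κ = 0.001 mixed proportionally to the background b, keeping consensus-like
matrices finite; κ = 0 is allowed and then −∞ entries simply make the
affected windows unreportable. Window p-values are exact: each column's
scores are integerized onto a grid (the widest column spans `granularity`
= 10,000 steps) and the full null distribution of the integer total under
the 0-order background is built by convolution; P(score ≥ s) is then a
finite sum of word probabilities, and a window is a hit when its tail
probability is ≤ the threshold (10⁻⁴ default), on either strand. Windows
containing N (hard-masked sequence) are skipped. An exhaustive 4^L
enumeration validates the distribution to 10⁻⁹ for L ≤ 6.

Enrichment between two sequence classes is reported two ways. The
hit-density ratio divides hits-per-nucleotide in the foreground by the
background, with 1.20 and 0.833 as the reporting thresholds for calling a
motif enriched on either side; swapping the classes maps the ratio to its
reciprocal. The presence test is a sequence-level one-sided Fisher test
(≥1 hit or not, foreground vs background) — used both between the two peak
classes and against dinucleotide-preserving shuffles of the foreground
(Altschul–Erickson: a random Euler path over the dinucleotide multigraph,
preserving exact dinucleotide counts and the terminal letters). Scanning
background composition defaults to the pooled composition of the analyzed
sequences and can be set to uniform.

A practical note on chance hits: with a fine-grained (non-degenerate)
score spectrum, thresholding at p ≤ 10⁻⁴ admits close to 10⁻⁴ chance hits
per window — ~0.03 per 150-bp sequence over both strands — which dilutes
hit-density ratios toward 1 whenever true densities are low. This is a
property of threshold scanning itself, not of the implementation. The
planted-truth evaluations therefore score against the generator's true
(uniform) base composition, under which the planted motif's discrete score
spectrum leaves a gap below 10⁻⁴ and the chance rate drops to ~10⁻⁵ per
window; with estimated (pooled) backgrounds the measured ratio for a
planted 6-fold rate contrast is expected to land nearer 5.

## Synthetic study generator

The generator emulates the downstream statistical structure of a
two-condition differentiation study at desk scale. Defaults (all
overridable in `SyntheticConfig`):

- **Genome/genes**: 4 chromosomes × 10 Mb; 100 genes per chromosome on a
  jittered ~100 kb grid (spacing ≥ 2 kb guaranteed), random strand, spans
  5–20 kb with terminal exons.
- **Expression**: baseline log-normal (median 100, log-sd 1); 15% of genes
  up-, 15% down-regulated with |log2 fold| ~ Uniform(1.2, 5.5) (up to
  ~45-fold, so a realistic heavy tail of strongly induced genes — roughly
  30 genes exceed 10-fold), remaining genes N(0, 0.25) on the log2 scale.
  Neighbors (TSS-adjacent) of >10-fold genes that are themselves
  unregulated are recruited to 3–8.5-fold with probability ρ = 0.5.
- **Peaks**: promoter peaks at 70% of TSSs, equal signal in both
  conditions; condition-specific peaks Poisson-planted near regulated
  genes (λ = 2 per up gene for the differentiated condition, λ = 3 per
  down gene for the precursor), placed 1–15 kb from the TSS (clear of the
  promoter window, within the ±25 kb vicinity); 300 invariant peaks placed
  uniformly. Signals are log-normal with class-dependent medians
  (specific 50, invariant 15, promoter 20, cross-condition leak 4; log-sd
  0.4–0.5), chosen so planted specific peaks land in the top tertile with
  high probability while a 15% "leak" (the specific peak weakly detected
  in the other condition) exercises the low/absent distinction
  (q_absent = 0.85).
- **Clusters**: 12 anchor genes (drawn from the up-regulated set) each
  receive 5 extra differentiated-condition-specific peaks on a jittered
  grid spanning 2.5 kb, 2–10.5 kb from the TSS — tight enough to chain at
  a 1 kb window, and an excess of chains persists to ≥30 kb windows.
- **TF sites** overlap 45% of differentiated-specific peaks (200 bp,
  centered), plus 50 background sites.
- **Sequences**: one 150 bp uniform-composition center sequence per peak;
  the planted motif (NFI-like 11-bp consensus TTGGCAGCCAA at 0.985 per
  informative column) is substituted at the center of 30% of
  differentiated-specific and 5% of precursor-specific sequences, on a
  random strand.

The `null_study` variant keeps the class/signal structure — the
specificity labels must still exist for the motif screen to have
foreground and background classes — but removes every planted association:
specific peaks are placed uniformly with no gene linkage or cluster
anchors, ρ = 0, no TF overlap, and equal motif plant rates (0.7 in both
classes, high enough that the null hit-density ratio concentrates near 1).

What the generator does **not** emulate: read-level noise and peak-calling
artifacts, mappability structure, nucleosome positioning, correlated
signal between replicates, non-uniform base composition or repeats, and
distance-decay in co-regulation. Passing recovery tests therefore show the
statistics are implemented correctly and are well-powered under clean
planted structure — not that real data meet these assumptions.

## Numerical and design choices

- Tertile ties broken by (chrom, start); nearest-gene ties by smaller TSS
  then gene id; gene-ranking ties by count, then max signal, then gene id.
- Expression strata bins are left-closed ([e_i, e_{i+1})); a value on an
  edge falls in the bin that starts there. Empty buckets/strata/cells
  report NaN, never 0, and undefined cells are excluded from summary
  means (the TF-overlap summary is the unweighted mean over its listed
  cells).
- Degenerate Fisher margins return p = 1; empirical p-values always use
  the +1 correction; every randomized routine takes an explicit seed and
  is bit-reproducible given it.
- The published neighbor-co-regulation contingency (112/618 vs
  2,012/21,343) yields 4.18×10⁻¹¹ (`all_genes`) or 8.34×10⁻¹²
  (`disjoint`) here; both are reported and recorded in the run manifest.
- Problem sizes in the bundled checks (400 genes, ~1,600 peaks, five
  recovery seeds, 200 null seeds, 1,000-trial nulls) were chosen so the
  planted effects are detected with comfortable power while the whole
  verification runs on a laptop in about a minute.

## Known limitations

- The cluster null is uniform per chromosome; on real genomes a
  mappability- or accessibility-matched null would be more appropriate.
- The presence Fisher test treats sequences as exchangeable; it ignores
  sequence-length differences within a class (lengths are constant for
  center sequences by construction).
- `overlap_by_stratum` and the screens operate on union peaks; peaks
  merged across conditions are counted once, which can differ from
  per-condition counting when peaks chain heavily.
- The MEME parser covers the minimal format only (letter-probability
  blocks); count matrices and extended attributes are out of scope.
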