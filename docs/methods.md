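# Methods

This note records the modelling choices behind `fragloop`: what each stage
assumes, which knobs matter, what the synthetic generator does and does
not emulate, and where the method's own statistics have known rough edges.

## Segment universe

Chromosomes are digested at every occurrence of the restriction motif
(default `GATC`, a blunt 4-cutter); the cut is placed at the motif start.
The exact cut offset within the site is irrelevant downstream: it moves
segment boundaries by at most the motif length and never the statistics.
Fragments are merged greedily left-to-right until the accumulated length
reaches `min_len` (default 500 bp); a trailing remainder shorter than
`min_len` is absorbed into the previous segment, and a single long
fragment is never split. The rule produces segments mostly in the
500 bp–1 kb range while letting rare long fragments stand alone. Each
segment records its fragment-end count E = (number of constituent
fragments) + 1, the covariate of the end-density bias model. Coordinates
are 0-based half-open everywhere inside the package; GFF3 input is
converted at the I/O boundary.

Segments overlapping a configured centromere interval by ≥ 1 bp are
tagged, and any contact touching a tagged segment is dropped — the
conservative reading of "located in" a masked region.

## Contact filters

Mate positions are the 5′ mapped coordinates; each mate is assigned to
the segment containing it, unordered pair counts are aggregated, and
intra-segment pairs are excluded (at < 1.5 kb self-ligation artefacts
dominate, hence the 2 kb floor). The analysis window is inclusive:
2000 ≤ D ≤ 25000 bp, with D the center-to-center distance.

## Distance decay

Filtered contacts are sorted by distance and split into 50 bins of equal
read occupancy; a distance value is never split across bins, so
occupancies are equal only up to that granularity. Per bin, the per-bp
intensity is C = N/(b − a + 1) and the representative distance is the
count-weighted mean of the member distances (a plain mean weighted by
contact counts; a denominator of summed distances would not be a mean and
is not used). The 50 (ln D, ln C) points are fitted with a cubic
least-squares spline whose smoothing knob is the interior-knot count
(default 4, i.e. ≈ 8 effective degrees of freedom on 50 bins — smoothing
parameters do not port across spline implementations, so exact curve
equality with any particular statistical environment is a non-goal).
Fitted values are projected onto the nearest non-increasing sequence
(antitonic regression — minimal, deterministic, order-preserving) and the
model interpolates linearly in log-log space between knots, clamping to
the boundary values outside the fitted domain. Natural logarithms are
used throughout.

## Bias model

β (sequencing visibility) is the segment's length-normalized genomic
resequencing coverage divided by the genome-wide mean, so mean(β) = 1 by
construction; multiple resequencing libraries are pooled by summing depth
first. Segments with β outside [0.05, 20] (inclusive bounds) are removed
globally — as anchors *and* from every partner set and denominator, the
consistent extension of removing "contacts" between such segments.

The fragment-end-density effect f(E) is a log-linear fit of segment Hi-C
depth on E, returned as a multiplier normalized to mean 1 (the scale
cancels in the probability normalization; the normalization is kept so
the multiplier is interpretable). Depth is length-normalized before the
regression: segment length enters the adjusted-probability product as its
own explicit factor, and longer segments mechanically contain more
fragment ends, so leaving length in the response would count it twice and
distort the adjusted probabilities.

Adjusted probabilities for an anchor are proportional to
f(D)·f(E)·l·β over all usable window partners on both sides and sum to
one; removing a partner and renormalizing equals recomputing on the
reduced set (property-tested), which is the "visibility" rationale for
the β filter in the first place.

## Significance test

A pair's count is AB = X + Y, X ~ NB(Â, p_AB), Y ~ NB(B̂, p_BA), with the
NB mass C(k+r−1, k)·p^k·(1−p)^r generalized to real r through the gamma
function and evaluated in log space. The convolution is exact (an O(k²)
double sum, organized as Σ_i P(X=i)·F_Y(k−1−i) with compensated
summation); no saddlepoint or normal approximation is used, and k = 0
returns p = 1 (empty sum). Â sums the anchor's other contacts weighted by
the attribution ratio r_i = (A′ − C_Ai)/((A′ − C_Ai) + (i_tot − C_Ai)),
0.5 on a vanishing denominator, where A′ is the anchor's windowed depth
minus the tested pair's own reads; the tested partner is excluded from
the sum, so a pair never informs its own background. Depths are windowed
(reads within 2–25 kb), matching the read set everything else is
computed from. BH correction runs over the family of all observed
(k ≥ 1), filter-passing pairs; zero-count pairs are untestable and not
counted in the family size. r = 0 degenerates to a point mass at zero;
a p_AB at the simplex boundary is clamped into (0, 1) and such pairs are
reported with p-value 1 or 0 as the degenerate limit dictates.

### Calibration behaviour (known rough edge)

Two structural effects keep the tested family's p-values from being
exactly uniform on null data, and both are properties of the method, not
of its implementation:

1. **Family truncation.** Only pairs with k ≥ 1 are testable. At finite
   sequencing density, conditioning on k ≥ 1 removes high-p mass, so the
   empirical p-value CDF sits above the diagonal at mid-range p. The
   effect concentrates at long distances (smallest expected counts).
2. **Attribution deficit.** Â weights each partner's counts by r_i, and
   heavier partners contribute more counts while receiving smaller r_i,
   so the count-weighted attribution averages slightly below one half
   under multiplicative depth heterogeneity (l, β, f(E) together give
   segment-depth CVs near 50% under the generator's defaults). The null
   mean is underestimated by ~10–15% on average, more for low-visibility
   pairs, which makes the extreme tail mildly anti-conservative at high
   per-pair coverage.

At the package's default contact density (≈ 2.5 reads per window pair)
the two effects combine to a Kolmogorov–Smirnov distance of ≈ 0.05 from
uniform (truncation-dominated; the far-left tail is clean, and BH at
q < 0.01 yields zero false calls in ≈ 19/20 seeds). Deeper coverage
removes the truncation but amplifies the deficit (KS ≈ 0.066 at ≈ 12.5
reads/pair, with occasional false calls); shallower coverage does the
reverse. Users should treat q-values near the threshold with care on very
deep libraries.

## Gene self-loops

Candidates are genes with |TTS − TSS| ≥ 2 kb (shorter genes cannot have a
callable partner given the 2 kb minimum loop span; the weakest rule
consistent with the span floor). Focal points at TSS and +400/+800 bp
downstream are used individually only when inside the gene body. A
partner counts when its segment center lies within R = |TTS − focal| of
the focal point (inclusive); laterality is the sign of (center − focal)
in transcription direction, with an exact tie counting as neither side.
Minus-strand genes are handled by mirroring, so "downstream" always means
in transcription direction. The directionality-bias scan applies the same
laterality rule to focal points 5/2/1/0.5/0 kb upstream of TSSs, grouped
by expression level, reporting 3′/5′ partner fractions per offset.

## Association machinery

Promoter = TSS ± 500 bp, clipped at chromosome ends and flagged when
clipped. A promoter carries a mark when ≥ 30% of it is covered by the
merged peak track (inclusive threshold). A promoter-pair interaction is a
significant loop of span ≥ 6 kb whose segments overlap distinct promoters
(≥ 1 bp; maximal overlap wins, ties resolved by nearest TSS); within- vs
between-gene classification uses loops of span < 6 kb whose segments both
overlap gene bodies, assigned by maximal overlap. Track shifts are
circular so feature count and covered length are conserved exactly (a
wrapped feature is stored as two pieces sharing one feature id);
clamping-and-dropping would change the null's feature budget. The
empirical p uses the add-one estimator (1 + #{null ≥ obs})/(1 + #null).
Expression reassignment rotates levels along the chromosome's gene order
by ±20/±50 positions with wrap-around, preserving the per-chromosome
level multiset exactly. ChIP-style tracks are compared as
ln(signal/control) after scaling both to a common total, with a
1-read-equivalent pseudocount by default.

## Synthetic data

The generator emulates the study conditions end to end: a genome whose
only motif occurrences sit at geometric spacings (mean 256 bp, the
expectation for a uniform 4-mer); non-overlapping genes with log-normal
lengths (median ≈ 2.2 kb), exponential intergenic gaps, random strands
and uniform decile expression levels; per-pair contact intensities
λ ∝ D^−α · f(E_A)f(E_B) · l_A l_B · β_A β_B restricted to the 2–25 kb
window, with α = 1 (log-linear decay), β log-normal with σ = 0.25, and
f(E) = E (depth proportional to ligatable ends); planted enrichments
multiply λ by a fold (default 10). Counts are Poisson by default: the
technical noise at the fragment-pair level is counting noise, and the
over-dispersion seen in real maps stems largely from visibility biases
that the generator already injects explicitly — an optional NB size knob
adds extra dispersion when wanted. Resequencing coverage is Poisson at
30× with 100 bp read-equivalents, which recovers β at r ≥ 0.95.

Planted loop spans are log-uniform on 2.5–15 kb, centred on the
gene-scale spans that dominate sub-kilobase maps. Planted gene self-loops
connect the TSS segment to the segment containing the point 500 bp short
of the TTS (in transcription direction): the classifier's search radius
ends at the TTS, so the center of the TTS-containing segment itself falls
outside the radius in about half of all placements by construction — the
inset keeps a planted partner detectable, which is what a recovery
benchmark needs. Promoter-pair loops connect TSS segments of gene pairs
6–20 kb apart; with coupling c each participating gene receives a
promoter peak with probability c, against a 20% background peak rate.

What the generator does **not** emulate: real base composition,
centromere structure and pericentromeric heterochromatin, long-range
(> 25 kb) contacts, inter-chromosomal contacts, replicate structure, PCR
duplication, and mapping artefacts. Passing tests therefore demonstrate
the statistical machinery under a faithful factor-model world, not
robustness to every artefact of a real library.

## Problem sizes

The test and benchmark configurations are sized for interactive runs on
one CPU: the planted-loop benchmark uses 50 pairs at 10-fold among 5×10⁵
contacts on a 2 × 5 Mb genome, pooled over five seeds (recall ≈ 0.72–0.77,
empirical FDR ≈ 0.03–0.05); null calibration uses twenty 2 Mb / 2×10⁵
contact simulations; decay recovery uses 10⁵ contacts on 1 Mb per
exponent; the full acceptance sweep completes in about half a minute.

## Limitations

- The background estimator's attribution deficit (above) makes the test
  mildly anti-conservative on deeply sequenced, strongly heterogeneous
  libraries; an explicitly calibrated alternative (e.g. estimating the
  pair-specific attribution from both depths) would change the published
  procedure and is deliberately not substituted.
- One pooled decay model genome-wide; no per-chromosome decay.
- No matrix balancing (ICE/KR); the explicit factor model replaces it.
- Inter-chromosomal and > 25 kb contacts are out of scope, as is merging
  adjacent significant pairs into loop domains.
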