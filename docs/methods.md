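# Methods

This note documents the models, numerical conventions and design choices
behind `cyclenuc`, and what the synthetic benchmark does and does not
establish about real data.

## Nucleosome occupancy tracks

Reads are single-end intervals (BED6). Each read contributes +1 to
`extension` bases (default 147 bp, the canonical mono-nucleosome footprint)
starting at its 5′ end in read orientation, clipped at contig ends. The
positioning protocols behind real datasets vary; 5′-end extension to the
footprint is the standard mono-nucleosome reconstruction and the extension
is a parameter. Reads recorded outside their contig are rejected and
counted; an unknown contig is an error, since it indicates a mismatched
genome build.

Normalization is the log-median ratio
`occ(b) = log(raw(b) + c) / log(median(raw + c))`, which fixes the genome
median of the normalized track at 1. The pseudocount `c` (default 1, the
smallest integer stabilizer) exists because integer pileups contain zeros
and `log 0` is undefined; the normalization refuses to run when
`median(raw + c) <= 1`, where the log ratio degenerates. Normalizing an
already-normalized track is rejected outright rather than silently
re-scaled. Note the median-of-1 invariant is exact because pileup counts are
heavily tied at the median, so the interpolated sample median is an attained
value.

Quality filters follow the conventions of nucleosome mapping studies:
contigs pass when strictly more than 20% of their bases are covered by
called nucleosome regions (when no external calls are supplied, covered
bases are those with normalized signal ≥ 1, i.e. at or above median
occupancy — a proxy for called nucleosome centers); genes whose mean raw
signal is strictly greater than 100× the genome-wide mean are excluded
(repeat-like artifacts). Both cutoffs use strict inequalities.

Coordinates are 0-based half-open everywhere; bedGraph is written 0-based
half-open and fixed-step wiggle input is converted from 1-based.

## Expression periodicity

Preprocessing order: (1) drop genes with more than half their timepoints
missing, (2) average duplicate gene rows elementwise ignoring missing
values, (3) KNN-impute each remaining gap (K = 10) using the nan-aware
Euclidean distance, which rescales by sqrt(T/observed) so genes with
different missingness patterns are comparable, (4) center each gene to mean
zero. Imputation precedes centering so the mean-zero invariant holds
exactly on the final values. Non-uniform timepoint spacing is rejected
rather than silently resampled, because the frequency-index analysis
assumes a uniform grid.

The one-sided amplitude spectrum of a centered series of length T is
`A(k) = 2|X_k|/T` for frequency indices 1..floor(T/2) (DC excluded), with
the Nyquist term for even T scaled 1/T. With this convention a pure cosine
of amplitude a at an integer frequency has peak amplitude a. The Parseval
identity that pins the scaling is
`(T/2) * sum_{k<T/2} A(k)^2 + T * A(T/2)^2 = sum_t x_t^2`
(the Nyquist term, when present, carries weight T, not T/2).

The cell-cycle frequency index f_cc is found in one of two modes:

* `secondary_max`: the index with the *second*-largest mean amplitude over
  all genes. In alpha-factor synchronization series the global maximum is
  typically a slow non-cell-cycle component (release/recovery drift), so the
  secondary peak is the cell cycle. The mean spectrum (not median or max) is
  used; this is a documented choice.
* `reference_set`: the index with the largest mean amplitude over a supplied
  set of known cell-cycle genes. Reference genes missing from the matrix are
  dropped with a warning; an empty intersection is an error.

Ties at the decisive rank resolve to the lower frequency index
(deterministic, and biased toward cell-cycle-scale components).

Each gene's periodicity distance is `d_g = |argmax_k A_g(k) - f_cc|` in
frequency-index units (invariant to the sampling interval). The cutoff
d_inflection is the knee of the ascending sorted-d_g curve: both axes are
normalized to [0, 1] and the knee is the point of maximum perpendicular
distance to the chord joining the endpoints — a deterministic,
parameter-free stand-in for reading an inflection off a plot. A gene is
cell-cycle regulated iff `d_g < d_inflection` (strict). If all d_g are
equal the knee is undefined and the caller must supply an explicit
threshold.

## Motif tools

Bracket consensus patterns (`[AGT][AT]CGCGT[CT][AGT]` and the like) parse to
one allowed-base set per position. Scanning reports every offset where all
positions match, on both strands (minus-strand hits match the reverse
complement of the motif; `N` never matches; overlapping hits are all
reported). The scanner compiles the pattern to a lookahead regex; the test
suite holds it to exact hit-set equality with a brute-force positionwise
membership oracle.

Upstream windows are the 600 bp 5′ of the coding start, gene-oriented
(reverse-complemented for minus-strand genes), truncated at contig ends, and
deliberately do *not* stop at a neighboring gene. A hit's position is its
center, `start + floor(len/2)`, in ATG-relative offsets; the center
minimizes orientation artifacts for near-palindromic motifs. A hit falling
in two genes' overlapping windows (divergent promoters) is reported once per
gene. Hit strand does not affect downstream grouping.

MI enrichment splits genes by d_g rank into `n_bins` (default 10)
equal-occupancy bins and computes
`MI = sum_{m,b} p(m,b) log2[ p(m,b) / (p(m) p(b)) ]` over the presence flag
and bin index, with a permutation p-value on shuffled presence flags using
the (1+hits)/(1+n_perm) correction so p is never exactly 0. Constant
presence yields MI = 0, p = 1 with a warning.

## Cross-species conservation

Orthology must be one-to-one; many-to-many rows are rejected at parse time.
Three per-motif classifications, from permissive to strict:

1. **presence** — conserved iff the ortholog's 600-bp upstream window has at
   least one consensus match anywhere ("upstream of the regulatory region"
   is read as upstream of the ortholog's coding start, matching the global
   upstream definition).
2. **positional** — absent iff no ortholog hit center lies within ±200 bp of
   the same ATG-relative offset. The shared offset coordinate (not an
   alignment) defines "that position", and centers (not any-overlap) are
   compared; with a window at least as wide as the upstream region this
   rule provably reduces to the presence rule.
3. **aligned** — on a pairwise upstream alignment: conserved iff every motif
   column is gap-free in both species and the ortholog bases still realize
   the consensus, in either orientation (a motif may "change into another
   form of the consensus", including the reverse-complement reading, since
   scanning is strand-symmetric); lost iff aligned but no longer a
   consensus; unaligned iff any motif column is gapped. A degapped-side
   mismatch with the stored upstream sequence raises an integrity error.

Gene-level TF-binding partition: a gene is *bound* iff ≥ 1 of its upstream
consensus hits overlaps a bound-site interval, *unbound* iff it has hits but
none bound; genes without hits are in neither set. The expressed-gene filter
retains the top quantile (default 90%) by mean expression level, ties at the
cutoff retained inclusively.

## Profiles and statistics

The profile matrix holds one row per (gene, hit): normalized occupancy over
offsets −flank..+flank (default 300) around the motif center, extracted in
gene orientation, missing (NaN) beyond contig ends, rows sorted ascending by
the gene's d_g (ties by gene id). Averages ignore missing cells and report
per-offset n.

The trough is the offset of the minimum of an average profile; ties break
toward the motif center, then upstream — so a flat profile yields 0.
Group comparisons locate the trough on the pooled average of both groups and
apply a two-sided Welch (unequal-variance) t test to the per-row values at
that single offset; when both groups have zero variance and equal means the
result is t = 0, p = 1. A ±window mean summary is available as an
alternative to the single-offset value.

The occupancy-periodicity association compares cyclic vs acyclic rows
(the d_inflection split) by a two-sided Mann-Whitney U test on per-row
summaries. The pairing of a continuous occupancy signal with a continuous
periodicity measure admits several designs; the group-comparison form is the
one implemented and documented, not asserted as the only reading. The U test
is exact for combined n ≤ 20 — by the exact null distribution for tie-free
data, by full enumeration over all C(n+m, n) labelings when ties are present
— and otherwise uses the normal approximation with tie and continuity
corrections.

Figure-style exports write row-aligned profile and expression TSVs in
identical gene order (floats as %.17g, so `read_figure_tables`, which
parses with round-trip precision, reproduces the matrices bit-exactly).

## The synthetic benchmark

The generator emulates the *structure* of a two-species nucleosome +
cell-cycle expression study with exact truth labels. Default study
conditions (all configurable):

* 150 genes per species in fixed slots on 2 contigs (~100 kb/species),
  alternating strands, 600-bp upstream windows, 400-bp coding regions.
* Expression: 25 timepoints at 5-minute spacing (125 min, just over two
  60-minute cell-cycle periods). Cyclic genes (30%) are
  `2·cos(2πt/60 + phase) + N(0, 1)`; half of the non-cyclic genes carry a
  slow artifact `3·cos(2πt/125 + phase)` emulating the synchronization
  drift that makes the global spectral maximum a non-cell-cycle signal —
  without it the secondary-maximum rule would have nothing to skip; the
  remaining genes are pure noise. 10% of entries are missing at random and
  5% of genes get >50% missingness to exercise the filter.
* Motifs: every cyclic gene and 30% of acyclic genes carry one planted
  MBP1-style consensus realization at a uniform offset in
  [−600, −motif_len], written over i.i.d. uniform ACGT background. 70% of
  planted motifs are conserved in species B (copied at the same offset);
  the rest are ablated by substituting the two most informative positions.
  Species-B upstream windows are additionally *scrubbed* of chance
  consensus matches (unprotected bases resampled until only planted motifs
  match on either strand), so "absent" is absent under every conservation
  definition and conservation truth labels are exact. Species-A windows are
  not scrubbed: they retain chance matches at the i.i.d. rate (~0.16 per
  gene for the default 9-mer), which realistically dilutes presence flags.
* Reads: nucleosome dyads are Poisson-sampled per base at 0.2 dyads/bp,
  modulated by multiplicative Gaussian dips of depth 0.8 and sd 50 bp on
  depleted motifs (cyclic genes' motifs) and a fixed dip (depth 0.6, sd
  60 bp) 150 bp upstream of every ATG (the promoter NDR). Each dyad emits
  one 36-bp single-end read from a random end of its 147-bp footprint,
  strand Bernoulli(1/2), so footprint-extension pileup reconstructs the
  dyad intensity.
* Orthology is one-to-one and complete; alignments are gap-free pairs of
  the two species' upstream windows (substitution rate 0.1 outside
  conserved motifs, no indels). A gene is TF-"bound" iff it is cyclic and
  carries a motif; bound sites are emitted as genomic intervals.

All randomness derives from a single seed through named substreams, so
bundles are byte-identical across runs of the same config.

The 150-gene default was calibrated so the default study realizes the
documented behavior of every stage with margin — in particular the
10-bin MI enrichment statistic, whose permutation test is underpowered on
much smaller gene sets; at 150 genes the planted enrichment is detected at
p ≤ 0.01 in 40/40 calibration seeds (and the occupancy-periodicity
association at p < 0.01 in ≥ 99/100 seeds).

What passing on synthetic data does **not** show: the generator uses
uniform base composition (no GC structure or real promoter grammar),
independent Poisson reads (no amplification duplicates, mappability or
MNase sequence bias), cosine expression with i.i.d. Gaussian noise (no
phase-dependent amplitude decay across the time course), gap-free
alignments (no indels), and nucleosome dips that are stationary across the
cell cycle. Results on real data additionally depend on alignment quality,
ortholog assignment, and synchronization quality, none of which are
modeled.

## Problem sizes and determinism

Default analyses run in seconds on one CPU: the demo study is 150
genes/species (~32k reads), the periodicity-recovery study 500 genes, the
spectral-recovery simulation 1,000 genes, and the seed-sweep of the
end-to-end association uses 100 seeds. Permutation counts default to 1,000.
All stochastic procedures take explicit seeds or Generator objects;
identical inputs give identical outputs, including file bytes.
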