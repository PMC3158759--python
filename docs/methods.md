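# Methods

## The analysis model

The pipeline treats a genome as a sequence of fixed-width windows (default
100 kb) and summarizes two channels per window: nucleosome-space occupancy
(NO; density of histone-H3 ChIP tags) and transcription (density of RNA-seq
tags). Window densities are raw counts × 10⁶ / library size — a pure
library-size correction, chosen because the downstream Fisher test
explicitly conditions on library sizes as margins, so any richer
normalization would be double-applied. Tags are assigned to windows by their
5′ start coordinate; this makes counting insensitive to read length and
keeps the conservation law Σ window counts = library size exact. Windows
tile chromosomes without overlap: the analysis units downstream (block
segmentation, differential regions) require disjoint countable windows, so
"sliding" is implemented as step = width (both configurable).

### LOG/HOG clustering

Windows are clustered with k-means, k = 2, on the z-scored NO and RNA
columns (all provided samples). Z-scoring matters: occupancy densities are
an order of magnitude larger than expression densities and would otherwise
dominate the Euclidean metric. Ten restarts keep the lowest
within-cluster sum of squares; the cluster with the higher mean *raw* NO
density is labeled HOG, the other LOG, which fixes the otherwise arbitrary
cluster identity. Maximal same-label runs per chromosome are the ACB (HOG)
and ICB (LOG) blocks. Genes inherit the label of the window containing the
TSS — deterministic for boundary-spanning genes and consistent with the
promoter-centric gene analyses. k-means initialization and feature scaling
are exposed in the API; the defaults above are what the rest of the package
assumes.

### Differential occupancy

For windows counts a, b in two libraries of sizes A, B the test is Fisher's
exact test on [[a, A−a], [b, B−b]] — the two-library count-comparison
design of IDEG6. Two-sided p-values use the minimum-likelihood rule: the
sum of probabilities of all tables (same margins) no more probable than the
observed one, with a relative tie tolerance of 10⁻⁷ absorbing float noise
on mathematically tied tables. The implementation computes the
hypergeometric pmf over the support via log-gamma and is vectorized across
windows by grouping on a+b (windows with equal totals share one pmf).
Direction is by cross-multiplied proportions (aB vs bA); exact ties get
direction "none" and are never significant. The stringent α = 10⁻⁵ is used
without further multiple-testing correction. Consecutive significant
same-direction windows merge into regions; regions never span chromosomes.

Known limitation: margin-based two-library tests inherit *composition
bias*. If differential mass is unevenly split between the tissues, library
totals differ, and at very deep coverage (thousands of tags per window)
that small proportional shift becomes detectable on truly non-differential
windows. In the synthetic power experiments the per-window depth is set
where recall has already saturated (~10³ tags per high-occupancy window);
beyond that the measured false-positive rate reflects this bias of the test
design rather than the caller.

### Gene-level features

Expression is exonic tag density: tags whose start falls in any exon,
× 10⁹ / (exonic bp × library size) — i.e. tags per kb of exon model per
million mapped tags. A tag inside the exons of two overlapping genes counts
for both; fractional assignment would need an isoform model the data do not
support. Isoform selection keeps the transcript with the most exons; ties
go to the longer span, then the lexicographically smaller transcript id, so
the choice is order-invariant.

Promoter classes follow the standard three-class CpG scheme: 500-bp windows
at 5-bp steps across TSS−500..+2000 (minus-strand promoters
reverse-complemented); HCP if any window has CpG o/e > 0.75 *and* GC >
0.55; LCP if no window reaches o/e > 0.48; else ICP. CpG o/e is
#CpG · L / (#C · #G) over ACGT positions. All four thresholds and the span
are configuration values with these defaults. Gene clusters are maximal
runs of ≥ 5 successive same-class genes in (chrom, tx_start) order; any
intervening gene of another class breaks a run. Expression breadth counts
tissues with normalized expression above a threshold (default 1.0 — the
data carry no natural cutoff, and 1 tag·kb⁻¹·M⁻¹ is the conventional
detection floor); "near-universal" means breadth ≥ n_tissues − 1.

### Metaprofiles

Tag starts within ±1 kb of the TSS or TTS are binned at 5 bp, offsets
measured along the direction of transcription (TSS of a minus-strand gene
is its rightmost base; offsets are negated), summed over genes, and divided
by n_genes × library_size/10⁶. Genes are unweighted — each tag counts once
— and gene bodies shorter than the span are not masked; the window is
literal. Peak sharpness is summarized as max bin density over the mean of
the outermost 10% of bins (5% per side); a flat profile scores 1.

## The synthetic landscape

The generator plants exactly the structure the analysis assumes, with
defaults chosen as a realistic desk-scale rendition of the study
conditions:

- **Blocks**: per-chromosome alternating LOG/HOG runs with geometric
  lengths, mean 5 windows — one parameter reproducing "largely continuous"
  occupancy domains.
- **Tag counts**: Poisson per window (uniform placement, Bernoulli strands)
  at 100 (HOG) vs 20 (LOG) expected NO tags per window — a 5× contrast —
  and 80 vs 10 for RNA. Rates are modulated by exp(3·(GC − 0.475)) with
  per-window GC ~ U(0.35, 0.60), giving the positive GC–occupancy coupling
  seen in real chromatin, and by a fold-3 shift in the 6% of windows planted
  as tissue-specific (direction Bernoulli).
- **Genes**: placed in per-chromosome slots with jitter (no overlap of gene
  bodies or promoter spans), 2–10 kb long, 2–8 exons. Promoter classes are
  planted in geometric runs (mean 6, consecutive runs always differ) so the
  cluster caller can be scored exactly.
- **Promoter sequence**: first-order Markov chains with the transition out
  of C calibrated against the chain's stationary distribution so realized
  CpG o/e and GC hit their targets (a naive transition tweak biases o/e by
  ~25%). Targets: o/e 0.9/0.6/0.2 at GC 0.60/0.50/0.47 for HCP/ICP/LCP; the
  realized o/e of every emitted promoter is recorded as truth. Promoters
  are spliced into the genome FASTA, so classification runs through the
  same TSS-extraction path it would on a real assembly.
- **Breadth panel**: housekeeping genes expressed in ≥ 18 of 19 tissues,
  tissue-specific genes in ≤ 3, with P(housekeeping) of 0.8 in HOG windows
  vs 0.15 in LOG windows — the coupling between broad expression and
  high-occupancy chromatin.
- **Phasing**: positioned-nucleosome reads at TSS+50 bp (transcription
  orientation) with 2-bp Gaussian jitter over a uniform background, for the
  metaprofile contrast.

What the generator does *not* emulate: mappability and copy-number
artifacts, fragment-length effects, overdispersion beyond Poisson,
replicate structure, realistic transcript anatomy (UTRs, splicing), or
sequence-intrinsic nucleosome positioning. Passing the synthetic benchmarks
therefore demonstrates the correctness and calibration of the
*computations* under the assumed statistical structure — not robustness to
every artifact of real sequencing data.

## Problem sizes and numerics

The shipped experiments use 200–1,000 windows of 10–100 kb on 2–20 Mb
synthetic chromosomes and 100–200 genes — small enough to run in minutes,
large enough that every statistic is measured on hundreds to tens of
thousands of units (each reported quantity carries its n). Determinism: all
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; k-means uses a fixed `random_state`; reruns are
byte-identical. The Fisher implementation is checked against exhaustive
exact-integer enumeration of every table with both margins ≤ 100 (ties
compared as integers) to 10⁻¹⁰, and against an independent reference
implementation on random tables. Degenerate inputs fail loudly: zero
library sizes, empty gene sets, all-identical feature matrices, zero-variance
correlation inputs and invalid intervals all raise with context rather than
propagating NaNs.
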