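# nucleoscape

Chromosome-scale nucleosome-occupancy landscape analysis for histone ChIP-seq
(H3) and RNA-seq tag data.

Nucleosome density is not uniform along mammalian chromosomes: megabase-scale
blocks of relatively nucleosome-rich chromatin coincide with broadly
transcribed, CpG-rich gene neighborhoods, while nucleosome-poor blocks harbor
tissue-specific, low-CpG genes. `nucleoscape` implements the window-based
analysis used to expose this structure, end to end:

- **Window profiling** — chromosomes are tiled with fixed windows (default
  100 kb); tags are counted per window by 5′ start and normalized per million
  mapped tags; per-window GC and between-sample Pearson correlations are
  computed.
- **LOG/HOG classification** — k-means (k = 2) on z-scored occupancy and
  expression densities splits windows into low- and high-occupancy groups
  (LOG/HOG); maximal same-label runs form inactively/actively transcribed
  chromosomal blocks (ICB/ACB); genes take the label of the window holding
  their TSS.
- **Differential occupancy** — for two tissues, each window's tag counts
  *a*, *b* at library sizes *A*, *B* form the 2×2 table
  [[a, A−a], [b, B−b]]; a two-sided Fisher exact test (minimum-likelihood
  rule, the two-library design popularized by IDEG6) at α = 10⁻⁵ calls
  tissue-specific windows, merged into directional regions.
- **Gene features** — exonic tag density (tags·kb⁻¹ per million mapped
  tags), promoter CpG class (HCP/ICP/LCP from CpG observed/expected
  `o/e = #CpG · L / (#C · #G)` and GC in 500-bp windows over TSS−500..+2000),
  runs of ≥5 successive same-class genes, and expression breadth across a
  tissue panel.
- **Metaprofiles** — strand-aware average tag density around TSS/TTS
  (±1 kb, 5-bp bins) contrasting nucleosome positioning between gene groups.
- **Synthetic data** — a generator that plants all of the above structure
  (geometric occupancy blocks, Poisson tag counts with GC coupling,
  fold-shifted differential windows, CpG-controlled promoters, phased reads,
  housekeeping/tissue-specific breadth) and records the ground truth, so
  every stage can be scored.

## Worked example

```sh
nucleoscape run-all --seed 7 --out demo/
```

simulates two chromosomes of 5 Mb (100 windows of 100 kb, 200 genes, two
tissues), runs every stage, writes tracks/tables/BEDs plus `manifest.json`
into `demo/`, and prints the truth-vs-called metrics:

```json
{
  "window_label_accuracy": 1.0,
  "block_boundary_error_median": 0.0,
  "differential_recall": 0.875,
  "differential_fpr": 0.0,
  "promoter_class_accuracy": 0.965,
  "cluster_recovery_true_classes": 1.0,
  "replicate_no_r": 0.9851691433585441,
  "cross_tissue_no_r": 0.7074689174762487,
  "gc_no_r": 0.3197463090913243,
  "gc_no_p": 0.0011834584003465494,
  "group_expression_ranksum_p": 1.0411112987032973e-21,
  "hog_median_expression": 144.74209389955493,
  "log_median_expression": 0.0,
  "frac_windows_differential": 0.07,
  "metaprofile_peak_offset": 52.5
}
```

(abridged; one metric per line of `demo/evaluation.json`). Reading the
numbers: the two planted occupancy groups were recovered perfectly
(`window_label_accuracy` 1.0 with block boundaries exact); 87.5% of the
planted tissue-specific windows were called with no false positives; 96.5%
of promoters landed in their true CpG class and every planted run of ≥5
same-class genes was recovered from true classes; two occupancy samples
drawn from the same landscape correlate at r = 0.985 while two *tissues*
correlate at 0.71 (the planted ~6–7% differential windows pull them apart);
occupancy tracks GC (r = 0.32, p = 0.0012); HOG genes out-express LOG genes
(median 144.7 vs 0.0 tags·kb⁻¹·M⁻¹, rank-sum p ≈ 10⁻²¹); and the phased
nucleosome reads planted 50 bp downstream of the TSS peak in the bin
centered at +52.5 bp.

Each stage is also a standalone subcommand over files
(`simulate`, `profile`, `classify`, `differential`, `genes`, `metaprofile`,
`evaluate`) — see `nucleoscape --help` — and the same operations are
importable from the library (`nucleoscape.make_grid`,
`nucleoscape.fisher_window`, …).

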