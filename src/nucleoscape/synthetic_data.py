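"""Synthetic genomes, tags and promoters with planted ground truth.

The generator emulates the statistical structure the occupancy analysis
assumes, at desk scale:

* block-structured occupancy along chromosomes (geometric run lengths of
  low/high-occupancy windows) with coupled expression rates;
* Poisson tag counts per window, uniform placement within the window,
  with a multiplicative GC coupling;
* a fraction of windows carrying a tissue-specific occupancy (and
  expression) shift of a chosen fold;
* non-overlapping genes whose promoter sequences are synthesized at target
  CpG observed/expected ratios, with same-class genes planted in runs;
* a tissue panel in which housekeeping genes are expressed near-universally
  and tissue-specific genes in at most a few tissues;
* optionally, reads phased at a fixed offset downstream of each TSS for
  metaprofile tests.

Every planted quantity is recorded in :class:`SimTruth` so downstream
calls can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import ChromSizes, GeneModel, ReadTag
from .window_profile import WindowGrid, make_grid

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_landscape",
    "simulate_tags",
    "simulate_genome_fasta",
    "simulate_genes_and_promoters",
    "simulate_breadth_panel",
    "simulate_phased_tags",
]

# Target CpG observed/expected per promoter class, and the GC content each
# class is synthesized at.  High-CpG promoters must clear the GC > 0.55
# classification gate, so they are generated GC-richer; all classes stay in
# the 40-60% GC band typical of mammalian promoters.
CLASS_CPG_OE = {"HCP": 0.9, "ICP": 0.6, "LCP": 0.2}
CLASS_GC = {"HCP": 0.60, "ICP": 0.50, "LCP": 0.47}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic landscape.

    Rates are expected tags per full window for the base (non-shifted)
    state; ``hog_rate/log_rate = 5`` gives the clear occupancy contrast the
    clustering stage assumes.  ``frac_diff_windows = 0.06`` plants the ~6%
    of windows with a tissue-specific occupancy shift; ``diff_fold`` is the
    multiplicative shift in the enriched tissue.  ``gc_coupling`` is the
    exponential slope tying window GC to tag rate (rate *= exp(slope * (gc
    - 0.475))).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    window_size: int = 100_000
    block_length_mean: float = 5.0
    hog_rate: float = 100.0
    log_rate: float = 20.0
    expr_hog_rate: float = 80.0
    expr_log_rate: float = 10.0
    frac_diff_windows: float = 0.06
    diff_fold: float = 3.0
    gc_coupling: float = 3.0
    n_tissues_breadth: int = 19
    n_genes: int = 200
    promoter_run_mean: float = 6.0
    frac_hk_hog: float = 0.8    # P(housekeeping | HOG window)
    frac_hk_log: float = 0.15   # P(housekeeping | LOG window)

    def __post_init__(self):
        if min(self.hog_rate, self.expr_hog_rate) <= 0:
            raise ValueError("rates must be positive")
        if self.log_rate < 0 or self.expr_log_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.hog_rate <= self.log_rate:
            raise ValueError("hog_rate must exceed log_rate")
        if not 0 <= self.frac_diff_windows <= 1:
            raise ValueError("frac_diff_windows must be in [0, 1]")
        if self.diff_fold <= 1:
            raise ValueError("diff_fold must exceed 1")
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be at least one window")


@dataclass
class SimTruth:
    """Planted ground truth for every downstream stage."""

    config: SimConfig
    chrom_sizes: ChromSizes
    grid: WindowGrid
    window_label: np.ndarray        # "LOG"/"HOG" per window
    window_gc: np.ndarray           # target GC per window
    diff_flag: np.ndarray           # bool per window
    diff_direction: np.ndarray      # "A"/"B"/"" per window
    genes: list[GeneModel] = field(default_factory=list)
    gene_class: dict[str, str] = field(default_factory=dict)      # promoter class
    gene_class_runs: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    gene_realized_oe: dict[str, float] = field(default_factory=dict)
    gene_breadth_class: dict[str, str] = field(default_factory=dict)  # HK | TS

    def window_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["true_label"] = self.window_label
        df["true_gc"] = self.window_gc
        df["diff_flag"] = self.diff_flag
        df["diff_direction"] = self.diff_direction
        return df

    def gene_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tx_start": g.tx_start, "tx_end": g.tx_end,
                "true_class": self.gene_class.get(g.gene_id, ""),
                "realized_cpg_oe": self.gene_realized_oe.get(g.gene_id, np.nan),
                "breadth_class": self.gene_breadth_class.get(g.gene_id, ""),
                "true_group": str(self.window_label[self.grid.window_id(g.chrom, g.tss)]),
            })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.window_frame().to_csv(outdir / "truth_windows.tsv", sep="\t", index=False)
        if self.genes:
            self.gene_frame().to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


def _geometric_runs(rng: np.random.Generator, n: int, mean: float, labels: Sequence[str]):
    """Alternate labels in geometric-length runs covering n positions."""
    out = np.empty(n, dtype=object)
    pos = 0
    cur = rng.integers(len(labels))
    while pos < n:
        run = int(rng.geometric(1.0 / mean))
        out[pos:pos + run] = labels[cur]
        pos += run
        cur = (cur + 1) % len(labels)  # alternate so runs stay maximal
    return out


def simulate_landscape(config: SimConfig) -> SimTruth:
    """Plant the block-structured occupancy landscape and per-window covariates."""
    rng = np.random.default_rng(config.seed)
    chrom_sizes = ChromSizes({f"chr{i + 1}": config.chrom_length
                              for i in range(config.n_chroms)})
    grid = make_grid(chrom_sizes, config.window_size)
    n = grid.n_windows
    labels = np.empty(n, dtype=object)
    for chrom in chrom_sizes:
        sl = grid.chrom_slice(chrom)
        labels[sl] = _geometric_runs(rng, sl.stop - sl.start,
                                     config.block_length_mean, ["LOG", "HOG"])
    gc = np.clip(rng.uniform(0.35, 0.60, size=n), 0.0, 1.0)
    diff_flag = rng.random(n) < config.frac_diff_windows
    direction = np.where(diff_flag, np.where(rng.random(n) < 0.5, "A", "B"), "")
    return SimTruth(config, chrom_sizes, grid, labels, gc, diff_flag,
                    direction.astype(object))


def _window_rates(truth: SimTruth, channel: str, tissue: str) -> np.ndarray:
    cfg = truth.config
    if channel == "NO":
        base = np.where(truth.window_label == "HOG", cfg.hog_rate, cfg.log_rate)
    elif channel == "RNA":
        base = np.where(truth.window_label == "HOG", cfg.expr_hog_rate, cfg.expr_log_rate)
    else:
        raise ValueError(f"unknown channel {channel!r} (expected 'NO' or 'RNA')")
    if tissue not in ("A", "B"):
        raise ValueError(f"unknown tissue {tissue!r} (expected 'A' or 'B')")
    rates = base * np.exp(cfg.gc_coupling * (truth.window_gc - 0.475))
    shift = truth.diff_flag & (truth.diff_direction == tissue)
    return np.where(shift, rates * cfg.diff_fold, rates)


def simulate_tags(
    truth: SimTruth,
    channel: str = "NO",
    tissue: str = "A",
    seed: int | None = None,
) -> list[ReadTag]:
    """Poisson tag counts per window, uniform starts, Bernoulli(0.5) strands.

    Rates follow the planted window label (high vs low occupancy, or
    expressed vs silent for the RNA channel), scaled by the GC coupling and
    by ``diff_fold`` in windows planted as shifted toward this tissue.
    Terminal short windows get proportionally fewer tags.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rates = _window_rates(truth, channel, tissue)
    tags: list[ReadTag] = []
    read_len = 36
    for wid, (chrom, start, end) in enumerate(truth.grid.windows):
        lam = rates[wid] * (end - start) / cfg.window_size
        k = rng.poisson(lam)
        if k == 0:
            continue
        starts = rng.integers(start, end, size=k)
        strands = rng.random(k) < 0.5
        chrom_len = truth.chrom_sizes[chrom]
        for s, fwd in zip(starts, strands):
            e = min(int(s) + read_len, chrom_len)
            tags.append(ReadTag(chrom, int(s), e, "+" if fwd else "-"))
    return tags


def simulate_genome_fasta(truth: SimTruth, path: str | Path, seed: int | None = None,
                          line_width: int = 80) -> None:
    """Write a genome FASTA whose per-window GC matches the planted targets.

    Bases are drawn i.i.d. within each window at the window's target GC.
    Promoter spans planted by :func:`simulate_genes_and_promoters` are then
    overwritten with their CpG-controlled sequences, so promoter
    classification can run off this genome exactly as it would off a real
    assembly.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    seqs: dict[str, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in truth.chrom_sizes.items():
        seq = np.empty(length, dtype=np.uint8)
        sl = truth.grid.chrom_slice(chrom)
        for wid in range(sl.start, sl.stop):
            _, start, end = truth.grid.windows[wid]
            g = truth.window_gc[wid]
            p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
            seq[start:end] = rng.choice(bases, size=end - start, p=p)
        seqs[chrom] = seq
    for g in truth.genes:
        prom = _promoter_genomic_seq(g, truth)
        lo, hi = _promoter_genomic_span(g)
        lo = max(0, lo)
        seqs[g.chrom][lo:lo + len(prom)] = np.frombuffer(prom.encode(), dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), line_width):
                fh.write(s[i:i + line_width] + "\n")


PROMOTER_UP = 500
PROMOTER_DOWN = 2000


def _promoter_genomic_span(g: GeneModel) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - PROMOTER_UP, g.tss + PROMOTER_DOWN
    return g.tss - PROMOTER_DOWN + 1, g.tss + PROMOTER_UP + 1


def _promoter_genomic_seq(g: GeneModel, truth: SimTruth) -> str:
    seq = truth._promoter_seqs[g.gene_id]  # oriented 5'->3'
    if g.strand == "-":
        from .gene_features import revcomp
        seq = revcomp(seq)
    return seq


from functools import lru_cache


@lru_cache(maxsize=64)
def _calibrate_cpg_chain(target_oe: float, gc: float) -> tuple[np.ndarray, np.ndarray]:
    """Base and after-C transition probabilities whose stationary statistics hit the targets.

    Suppressing (or boosting) G after C shifts the chain's stationary
    composition away from the naive marginals, which would bias both the
    realized o/e and the GC.  A short fixed-point iteration on the
    stationary distribution removes that bias: the realized o/e of the
    chain is q / pi_G (q = P(G|C)), and GC is pi_C + pi_G.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    q = min(max(target_oe, 1e-6) * p[2], 0.95)
    for _ in range(40):
        after_c = p * (1 - q) / (1 - p[2])
        after_c[2] = q
        P = np.tile(p, (4, 1))
        P[1] = after_c
        # stationary distribution by power iteration
        pi = np.full(4, 0.25)
        for _ in range(60):
            pi = pi @ P
        q = min(max(target_oe, 1e-6) * pi[2], 0.95)
        gc_real = pi[1] + pi[2]
        scale = gc / gc_real
        p[1] *= scale
        p[2] *= scale
        p[0] = p[3] = (1 - p[1] - p[2]) / 2
    after_c = p * (1 - q) / (1 - p[2])
    after_c[2] = q
    return p, after_c


def synthesize_cpg_sequence(rng: np.random.Generator, length: int,
                            target_oe: float, gc: float) -> str:
    """First-order Markov sequence with CpG o/e ~= target at a given GC.

    The transition out of C sends a calibrated probability to G
    (see :func:`_calibrate_cpg_chain`) so the realized observed/expected
    CpG ratio and GC content of long sequences match the targets.
    """
    p, after_c = _calibrate_cpg_chain(target_oe, gc)
    cum_p = np.cumsum(p)
    cum_c = np.cumsum(after_c)
    u = rng.random(length)
    idx = np.empty(length, dtype=np.int64)
    cur = int(np.searchsorted(cum_p, u[0], side="right"))
    idx[0] = cur
    for i in range(1, length):
        cur = int(np.searchsorted(cum_c if cur == 1 else cum_p, u[i], side="right"))
        idx[i] = cur
    return "".join(np.array(list("ACGT"))[np.minimum(idx, 3)])


def simulate_genes_and_promoters(
    truth: SimTruth,
    seed: int | None = None,
    promoter_fasta: str | Path | None = None,
) -> list[GeneModel]:
    """Place non-overlapping genes and synthesize promoter sequences in planted class runs.

    Genes are laid out in per-chromosome slots (slot = chrom_length /
    genes-on-chrom) with random jitter, which guarantees no overlap of gene
    bodies or promoter spans.  Promoter classes are planted in runs of
    geometric length (consecutive runs always differ in class) so the
    gene-cluster caller can be scored exactly.  Realized CpG o/e of each
    emitted promoter is recorded as truth.
    """
    from .gene_features import cpg_observed_expected

    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    n = cfg.n_genes
    truth.genes = []
    truth._promoter_seqs = {}
    if n == 0:
        return []
    total_len = sum(truth.chrom_sizes[c] for c in truth.chrom_sizes)
    footprint = PROMOTER_UP + PROMOTER_DOWN + 12_000  # promoter + max gene + margin
    if n * footprint > total_len:
        raise ValueError(f"cannot place {n} genes without overlap "
                         f"(need {n * footprint} bp, have {total_len})")

    # plant promoter classes in runs; consecutive runs differ in class
    classes = list(CLASS_CPG_OE)
    gene_classes: list[str] = []
    prev = None
    while len(gene_classes) < n:
        choices = [c for c in classes if c != prev]
        cls = choices[rng.integers(len(choices))]
        run = int(rng.geometric(1.0 / cfg.promoter_run_mean))
        gene_classes.extend([cls] * run)
        prev = cls
    gene_classes = gene_classes[:n]

    # distribute genes over chromosomes proportionally to length
    chroms = list(truth.chrom_sizes)
    per_chrom = np.floor(np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
                         / total_len * n).astype(int)
    i = 0
    while per_chrom.sum() < n:
        per_chrom[i % len(chroms)] += 1
        i += 1

    gid = 0
    runs: list[tuple[str, list[str]]] = []
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        slot = truth.chrom_sizes[chrom] // count
        if slot < footprint:
            raise ValueError(f"gene density too high on {chrom}: slot {slot} < "
                             f"footprint {footprint}")
        for j in range(count):
            cls = gene_classes[gid]
            name = f"g{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2_000, 10_000))
            n_ex = int(rng.integers(2, 9))
            lo = j * slot + PROMOTER_DOWN + 100
            hi = (j + 1) * slot - PROMOTER_DOWN - length - 100
            tx_start = int(rng.integers(lo, max(lo + 1, hi)))
            tx_end = tx_start + length
            # exons: split the span into 2*n_ex-1 alternating blocks
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2,
                                      replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple((tx_start + int(bounds[2 * k]), tx_start + int(bounds[2 * k + 1]))
                          for k in range(n_ex))
            gene = GeneModel(name, chrom, strand, tx_start, tx_end, exons)
            prom = synthesize_cpg_sequence(rng, PROMOTER_UP + PROMOTER_DOWN,
                                           CLASS_CPG_OE[cls], CLASS_GC[cls])
            oe, _ = cpg_observed_expected(prom)
            truth.genes.append(gene)
            truth.gene_class[name] = cls
            truth.gene_realized_oe[name] = oe
            truth._promoter_seqs[name] = prom
            same_run = (runs and runs[-1][0] == cls and len(truth.genes) > 1
                        and truth.genes[-2].chrom == chrom)
            if same_run:
                runs[-1][1].append(name)
            else:
                runs.append((cls, [name]))
            gid += 1
    truth.gene_class_runs = [(cls, tuple(ids)) for cls, ids in runs]
    if promoter_fasta is not None:
        with open(promoter_fasta, "w") as fh:
            for g in truth.genes:
                fh.write(f">{g.gene_id}\n{truth._promoter_seqs[g.gene_id]}\n")
    return truth.genes


def simulate_breadth_panel(
    truth: SimTruth,
    seed: int | None = None,
    expressed_level: float = 20.0,
    silent_level: float = 0.2,
) -> pd.DataFrame:
    """Genes x tissues expression matrix with planted housekeeping/tissue-specific classes.

    Housekeeping genes are expressed (well above the breadth threshold of 1)
    in 18 or 19 of the tissues; tissue-specific genes in 1-3.  The chance a
    gene is housekeeping follows its occupancy group (frac_hk_hog vs
    frac_hk_log), reproducing the coupling between broad expression and
    high-occupancy regions.
    """
    cfg = truth.config
    if cfg.n_tissues_breadth < 2:
        raise ValueError("need at least 2 tissues for breadth")
    if not truth.genes:
        raise ValueError("simulate genes before the breadth panel")
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    nt = cfg.n_tissues_breadth
    mat = np.zeros((len(truth.genes), nt))
    for i, g in enumerate(truth.genes):
        grp = truth.window_label[truth.grid.window_id(g.chrom, g.tss)]
        p_hk = cfg.frac_hk_hog if grp == "HOG" else cfg.frac_hk_log
        is_hk = rng.random() < p_hk
        truth.gene_breadth_class[g.gene_id] = "HK" if is_hk else "TS"
        n_on = int(rng.integers(nt - 1, nt + 1)) if is_hk else int(rng.integers(1, 4))
        on = rng.choice(nt, size=n_on, replace=False)
        row = rng.uniform(0, silent_level, size=nt)
        row[on] = expressed_level * rng.lognormal(0, 0.5, size=n_on)
        mat[i] = row
    return pd.DataFrame(mat, index=[g.gene_id for g in truth.genes],
                        columns=[f"tissue{t + 1}" for t in range(nt)])


def simulate_phased_tags(
    genes: Sequence[GeneModel],
    chrom_sizes: ChromSizes,
    phase_offset: int = 50,
    jitter_sd: float = 2.0,
    reads_per_gene: float = 20.0,
    background_rate: float = 5.0,
    span: int = 1000,
    seed: int = 0,
) -> list[ReadTag]:
    """Reads phased at a fixed offset downstream of each TSS, plus uniform background.

    Emulates a positioned nucleosome: tag starts cluster at TSS +
    ``phase_offset`` (transcription orientation) with Gaussian jitter;
    ``background_rate`` reads per gene are spread uniformly over +/-span.
    """
    rng = np.random.default_rng(seed)
    tags: list[ReadTag] = []
    read_len = 36
    for g in genes:
        sign = 1 if g.strand == "+" else -1
        k = rng.poisson(reads_per_gene)
        offs = np.round(rng.normal(phase_offset, jitter_sd, size=k)).astype(int)
        kb = rng.poisson(background_rate)
        offs = np.concatenate([offs, rng.integers(-span, span, size=kb)])
        for off in offs:
            s = g.tss + sign * int(off)
            if 0 <= s < chrom_sizes[g.chrom] - read_len:
                tags.append(ReadTag(g.chrom, s, s + read_len,
                                    "+" if rng.random() < 0.5 else "-"))
    return tags
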