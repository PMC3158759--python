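"""Gene-level quantification and annotation.

Covers normalized expression (tags per kb of exon model per million mapped
tags), promoter CpG class (HCP/ICP/LCP from CpG observed/expected and GC of
the promoter region), runs of same-class neighboring genes, and expression
breadth across a tissue panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, ReadTag

__all__ = [
    "PromoterClass",
    "GeneClusterCall",
    "quantify_expression",
    "cpg_observed_expected",
    "classify_promoter",
    "classify_promoters",
    "find_gene_clusters",
    "expression_breadth",
    "PROMOTER_SPAN",
    "CPG_OE_HIGH",
    "CPG_OE_LOW",
    "GC_HIGH",
]

# Promoter scan: the span around the TSS scanned with 500-bp windows at
# 5-bp steps, and the CpG o/e / GC thresholds of the standard three-class
# promoter scheme (high-CpG needs one window with o/e > 0.75 AND GC > 0.55;
# low-CpG means no window reaches o/e > 0.48; the rest is intermediate).
PROMOTER_SPAN = (-500, 2000)    # relative to TSS, transcription orientation
SCAN_WINDOW = 500
SCAN_STEP = 5
CPG_OE_HIGH = 0.75
CPG_OE_LOW = 0.48
GC_HIGH = 0.55

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterClass:
    gene_id: str
    cls: str        # HCP | ICP | LCP
    cpg_oe: float   # best (max) 500-bp window o/e observed in the scan
    gc: float       # GC of the full promoter span
    span: tuple[int, int]


@dataclass(frozen=True)
class GeneClusterCall:
    chrom: str
    cls: str
    gene_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def quantify_expression(
    genes: Sequence[GeneModel],
    rna_tags: Iterable[ReadTag],
    library_size: int | None = None,
) -> dict[str, float]:
    """Exonic tag density per gene: count * 1e9 / (exonic bp * library size).

    A tag is counted for a gene when its 5' start falls inside any exon of
    that gene; a tag inside the exons of two overlapping genes counts for
    both (no fractional splitting).  ``library_size`` defaults to the number
    of tags supplied.
    """
    tags = list(rna_tags)
    if library_size is None:
        library_size = len(tags)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    starts_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {t.chrom for t in tags}:
        starts_by_chrom[chrom] = np.sort(
            np.array([t.start for t in tags if t.chrom == chrom], dtype=np.int64)
        )
    out: dict[str, float] = {}
    for g in genes:
        if g.exonic_length == 0:
            raise ValueError(f"gene {g.gene_id} has zero exonic length")
        starts = starts_by_chrom.get(g.chrom)
        count = 0
        if starts is not None:
            for s, e in g.exons:
                count += int(np.searchsorted(starts, e) - np.searchsorted(starts, s))
        out[g.gene_id] = count * 1e9 / (g.exonic_length * library_size)
    return out


def cpg_observed_expected(seq: str) -> tuple[float, float]:
    """CpG observed/expected ratio and GC fraction of a sequence.

    Over ACGT positions only (Ns are dropped): o/e = #CG * L / (#C * #G)
    with L the informative length; when the sequence has no C or no G the
    ratio is defined as 0.  Requires >= 50 informative bases.
    """
    seq = seq.upper()
    c = seq.count("C")
    g = seq.count("G")
    acgt = c + g + seq.count("A") + seq.count("T")
    if acgt < 50:
        raise ValueError(f"sequence has only {acgt} informative bases (need >= 50)")
    cg = seq.count("CG")
    gc = (c + g) / acgt
    oe = cg * acgt / (c * g) if c * g > 0 else 0.0
    return oe, gc


def _scan_windows(seq: str, window: int = SCAN_WINDOW, step: int = SCAN_STEP):
    """Yield (cpg_oe, gc) for each sliding window; vectorized via cumulative counts.

    Windows containing any N are skipped (their composition is unreliable).
    """
    n = len(seq)
    if n < window:
        return np.empty(0), np.empty(0)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_acgt = np.isin(arr, [ord(x) for x in "ACGT"]).astype(np.int32)
    is_cg = np.zeros(n, dtype=np.int32)
    is_cg[:-1] = is_c[:-1] & (arr[1:] == ord("G"))
    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    cc, cgc, cacgt, ccg = cum(is_c), cum(is_g), cum(is_acgt), cum(is_cg)
    starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    wc = cc[ends] - cc[starts]
    wg = cgc[ends] - cgc[starts]
    wacgt = cacgt[ends] - cacgt[starts]
    # CG dinucleotides fully inside the window
    wcg = ccg[ends - 1] - ccg[starts]
    ok = wacgt == window
    oe = np.zeros(len(starts))
    denom = wc * wg
    nz = ok & (denom > 0)
    oe[nz] = wcg[nz] * window / denom[nz]
    gc = np.where(ok, (wc + wg) / window, np.nan)
    return oe[ok], gc[ok]


def classify_promoter(seq: str, gene_id: str = "", span: tuple[int, int] = PROMOTER_SPAN) -> PromoterClass:
    """Classify one promoter sequence (already oriented 5'->3' of the gene).

    HCP: some 500-bp window has CpG o/e > 0.75 and GC > 0.55.
    LCP: no window reaches o/e > 0.48.  Everything else: ICP.
    Sequences shorter than one scan window are classified on the whole
    sequence as a single window.
    """
    if not seq:
        raise ValueError(f"empty promoter sequence for gene {gene_id!r}")
    oe, gc = _scan_windows(seq)
    if oe.size == 0:
        oe_w, gc_w = cpg_observed_expected(seq)
        oe = np.array([oe_w])
        gc = np.array([gc_w])
    if np.any((oe > CPG_OE_HIGH) & (gc > GC_HIGH)):
        cls = "HCP"
    elif not np.any(oe > CPG_OE_LOW):
        cls = "LCP"
    else:
        cls = "ICP"
    full_oe, full_gc = cpg_observed_expected(seq)
    return PromoterClass(gene_id, cls, float(oe.max()), full_gc, span)


def promoter_sequence(gene: GeneModel, fasta, span: tuple[int, int] = PROMOTER_SPAN) -> str:
    """Extract the promoter span around the TSS, oriented in the direction of transcription.

    Minus-strand promoters are reverse-complemented.  Spans running off a
    chromosome end are truncated.
    """
    up, down = span
    if gene.strand == "+":
        lo, hi = gene.tss + up, gene.tss + down
    else:
        lo, hi = gene.tss - down + 1, gene.tss - up + 1
    chrom_len = len(fasta[gene.chrom])
    lo, hi = max(0, lo), min(chrom_len, hi)
    seq = str(fasta[gene.chrom][lo:hi])
    return seq if gene.strand == "+" else revcomp(seq)


def classify_promoters(
    genes: Sequence[GeneModel],
    fasta,
    span: tuple[int, int] = PROMOTER_SPAN,
) -> dict[str, PromoterClass]:
    """Classify every gene's promoter from a genome (or per-gene promoter) FASTA.

    When the FASTA keys are gene ids, each record is taken as the
    pre-extracted oriented promoter; otherwise the promoter is cut from the
    gene's chromosome.
    """
    out: dict[str, PromoterClass] = {}
    for g in genes:
        if g.gene_id in fasta:
            seq = str(fasta[g.gene_id][:])
        else:
            seq = promoter_sequence(g, fasta, span)
        out[g.gene_id] = classify_promoter(seq, g.gene_id, span)
    return out


def find_gene_clusters(
    genes: Sequence[GeneModel],
    classes: Mapping[str, str],
    min_run: int = 5,
) -> list[GeneClusterCall]:
    """Maximal runs of >= min_run successive same-class genes.

    Successiveness is judged on the full gene list sorted by
    (chrom, tx_start, gene_id): a gene of another class between two
    same-class genes breaks the run.
    """
    ordered = sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    calls: list[GeneClusterCall] = []
    run: list[GeneModel] = []

    def flush():
        if len(run) >= min_run:
            calls.append(
                GeneClusterCall(run[0].chrom, classes[run[0].gene_id],
                                tuple(g.gene_id for g in run),
                                run[0].tx_start, max(g.tx_end for g in run))
            )
        run.clear()

    for g in ordered:
        if run and (g.chrom != run[-1].chrom or classes[g.gene_id] != classes[run[-1].gene_id]):
            flush()
        run.append(g)
    flush()
    return calls


def expression_breadth(
    matrix: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.Series:
    """Number of tissues in which each gene's normalized expression exceeds ``threshold``.

    ``matrix`` is genes x tissues (index = gene ids).
    """
    if matrix.shape[1] < 2:
        raise ValueError("breadth needs at least 2 tissues")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return (matrix > threshold).sum(axis=1)


def breadth_group_summary(
    breadth: pd.Series,
    assignment: Mapping[str, str],
    n_tissues: int,
) -> pd.DataFrame:
    """Fraction of each occupancy group expressed near-universally (breadth >= n_tissues - 1)."""
    rows = []
    for grp in sorted(set(assignment.values())):
        ids = [g for g, a in assignment.items() if a == grp and g in breadth.index]
        if not ids:
            continue
        b = breadth.loc[ids]
        rows.append({"group": grp, "n": len(ids),
                     "frac_universal": float((b >= n_tissues - 1).mean())})
    return pd.DataFrame(rows)
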