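"""Two-tissue differential nucleosome occupancy by Fisher's exact test on window counts.

Each window's tag count in tissue A is compared against tissue B with the
library sizes as margins: the 2x2 table is ``[[a, A-a], [b, B-b]]`` where a
and b are the window counts and A and B the mapped-tag totals.  This is the
classic two-library proportion test for read counts (the IDEG6 design).
P-values are two-sided by the minimum-likelihood rule: the sum of the
probabilities of every table (under the hypergeometric null with the same
margins) no more probable than the observed one.  Significant windows at a
stringent threshold (default 1e-5) are merged, when consecutive and
same-direction, into differential regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome_io import GeneModel
from .window_profile import WindowGrid

__all__ = [
    "DifferentialWindowCall",
    "DifferentialRegion",
    "fisher_window",
    "call_differential",
    "merge_regions",
    "genes_in_regions",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 1e-5

# Relative tolerance when comparing table probabilities for the two-sided
# sum; absorbs floating-point noise in mathematically tied tables.
_TIE_REL_EPS = 1e-7


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _support_pmf(n: int, A: int, B: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric pmf over all tables with margins (A, B) and total n = a + b.

    Returns (k values = possible counts a, pmf).  P(a=k) =
    C(A,k) C(B,n-k) / C(A+B,n).
    """
    lo = max(0, n - B)
    hi = min(n, A)
    k = np.arange(lo, hi + 1)
    logp = _log_binom(A, k) + _log_binom(B, n - k) - _log_binom(A + B, n)
    return k, np.exp(logp)


def fisher_window(a: int, b: int, A: int, B: int) -> float:
    """Two-sided Fisher exact p-value for window counts a, b at library sizes A, B.

    Two-sided by the minimum-likelihood method: sums the probability of every
    table with the same margins whose probability does not exceed the
    observed table's (within a small relative tolerance for ties).
    """
    a, b, A, B = int(a), int(b), int(A), int(B)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if A <= 0 or B <= 0:
        raise ValueError("library sizes must be positive")
    if a > A or b > B:
        raise ValueError("window count exceeds its library size")
    k, pmf = _support_pmf(a + b, A, B)
    p_obs = pmf[np.searchsorted(k, a)]
    p = float(pmf[pmf <= p_obs * (1 + _TIE_REL_EPS)].sum())
    return min(p, 1.0)


def fisher_many(a: np.ndarray, b: np.ndarray, A: int, B: int) -> np.ndarray:
    """Vectorized :func:`fisher_window` for shared library sizes.

    Windows with equal total count a+b share one hypergeometric family, so
    the pmf is built once per unique total.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors differ in length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if A <= 0 or B <= 0:
        raise ValueError("library sizes must be positive")
    if np.any(a > A) or np.any(b > B):
        raise ValueError("window count exceeds its library size")
    out = np.empty(a.shape, dtype=float)
    totals = a + b
    for n in np.unique(totals):
        sel = totals == n
        k, pmf = _support_pmf(int(n), A, B)
        # sort once; two-sided p is the cumulative mass up to each observed pmf
        order = np.argsort(pmf)
        csum = np.cumsum(pmf[order])
        p_obs = pmf[np.searchsorted(k, a[sel])]
        idx = np.searchsorted(pmf[order], p_obs * (1 + _TIE_REL_EPS), side="right")
        out[sel] = csum[idx - 1]
    return np.minimum(out, 1.0)


@dataclass(frozen=True)
class DifferentialWindowCall:
    window_id: int
    count_a: int
    count_b: int
    library_a: int
    library_b: int
    p: float
    direction: str          # "A-enriched" | "B-enriched" | "none"
    significant: bool


@dataclass(frozen=True)
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    direction: str
    window_ids: tuple[int, ...]
    min_p: float


def call_differential(
    grid: WindowGrid,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    library_a: int,
    library_b: int,
    alpha: float = DEFAULT_ALPHA,
) -> list[DifferentialWindowCall]:
    """One Fisher call per window; direction by comparing the count proportions.

    A window is A-enriched when a/A > b/B (B-enriched for <); exact
    proportion ties get direction "none" and are never significant.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    if counts_a.shape != (grid.n_windows,) or counts_b.shape != (grid.n_windows,):
        raise ValueError("count vector length does not match grid")
    pvals = fisher_many(counts_a, counts_b, library_a, library_b)
    # compare a/A vs b/B without division: a*B vs b*A
    lhs = counts_a * library_b
    rhs = counts_b * library_a
    calls = []
    for wid in range(grid.n_windows):
        if lhs[wid] > rhs[wid]:
            direction = "A-enriched"
        elif lhs[wid] < rhs[wid]:
            direction = "B-enriched"
        else:
            direction = "none"
        sig = bool(pvals[wid] < alpha and direction != "none")
        calls.append(
            DifferentialWindowCall(wid, int(counts_a[wid]), int(counts_b[wid]),
                                   library_a, library_b, float(pvals[wid]), direction, sig)
        )
    return calls


def merge_regions(grid: WindowGrid, calls: Sequence[DifferentialWindowCall]) -> list[DifferentialRegion]:
    """Merge consecutive significant same-direction windows into regions.

    Regions never cross chromosome boundaries; a lone significant window
    becomes a one-window region.
    """
    by_id = {c.window_id: c for c in calls}
    regions: list[DifferentialRegion] = []
    run: list[DifferentialWindowCall] = []

    def flush():
        if run:
            wids = tuple(c.window_id for c in run)
            chrom = grid.windows[wids[0]][0]
            regions.append(
                DifferentialRegion(chrom, grid.windows[wids[0]][1], grid.windows[wids[-1]][2],
                                   run[0].direction, wids, min(c.p for c in run))
            )
            run.clear()

    prev_chrom = None
    for wid in sorted(by_id):
        c = by_id[wid]
        chrom = grid.windows[wid][0]
        if not c.significant:
            flush()
        else:
            if run and (c.direction != run[0].direction
                        or wid != run[-1].window_id + 1
                        or chrom != prev_chrom):
                flush()
            run.append(c)
        prev_chrom = chrom
    flush()
    return regions


def genes_in_regions(
    regions: Sequence[DifferentialRegion],
    genes: Sequence[GeneModel],
    expr_a: dict[str, float] | None = None,
    expr_b: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Genes whose TSS falls inside a differential region, with an expression comparison.

    Returns one row per (region, gene).  When per-gene normalized expression
    for both tissues is supplied, ``expr_concordant`` marks genes whose
    expression is higher in the occupancy-enriched tissue; the fraction of
    concordant genes summarizes how occupancy shifts track transcription.
    """
    rows = []
    for rid, reg in enumerate(regions):
        for g in genes:
            if g.chrom == reg.chrom and reg.start <= g.tss < reg.end:
                row = {"region_id": rid, "chrom": reg.chrom, "region_start": reg.start,
                       "region_end": reg.end, "direction": reg.direction,
                       "gene_id": g.gene_id}
                if expr_a is not None and expr_b is not None:
                    ea, eb = expr_a.get(g.gene_id, np.nan), expr_b.get(g.gene_id, np.nan)
                    row["expr_a"] = ea
                    row["expr_b"] = eb
                    if reg.direction == "A-enriched":
                        row["expr_concordant"] = bool(ea > eb)
                    elif reg.direction == "B-enriched":
                        row["expr_concordant"] = bool(eb > ea)
                    else:
                        row["expr_concordant"] = False
                rows.append(row)
    cols = ["region_id", "chrom", "region_start", "region_end", "direction", "gene_id"]
    if expr_a is not None and expr_b is not None:
        cols += ["expr_a", "expr_b", "expr_concordant"]
    return pd.DataFrame(rows, columns=cols)


def write_calls_tsv(calls: Sequence[DifferentialWindowCall], path: str | Path) -> None:
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[DifferentialRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{len(r.window_ids)}\t.\n")
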