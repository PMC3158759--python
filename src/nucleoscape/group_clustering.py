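"""Joint clustering of windows on occupancy and expression into LOG/HOG, and block segmentation.

Windows are clustered with k-means (k=2) on z-scored nucleosome-occupancy
and expression densities.  The cluster with the higher mean occupancy is the
high-occupancy group (HOG); the other is the low-occupancy group (LOG).
Maximal runs of same-label windows form actively/inactively transcribed
chromosomal blocks (ACB for HOG runs, ICB for LOG runs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome_io import GeneModel
from .window_profile import SignalMatrix, WindowGrid

__all__ = [
    "LOG",
    "HOG",
    "Block",
    "OccupancySegmentation",
    "cluster_windows",
    "segment_blocks",
    "assign_genes",
    "compare_groups",
]

LOG = "LOG"
HOG = "HOG"
# Block role follows the label: high-occupancy runs are actively transcribed.
ROLE_OF_LABEL = {HOG: "ACB", LOG: "ICB"}


@dataclass(frozen=True)
class Block:
    chrom: str
    start: int
    end: int
    label: str          # LOG | HOG
    window_ids: tuple[int, ...]

    @property
    def role(self) -> str:
        return ROLE_OF_LABEL[self.label]

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)


@dataclass
class OccupancySegmentation:
    """Per-window LOG/HOG labels plus the maximal same-label blocks."""

    grid: WindowGrid
    labels: np.ndarray          # array of LOG/HOG strings, len n_windows
    blocks: list[Block]

    def labels_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["label"] = self.labels
        return df

    def write_labels(self, path: str | Path) -> None:
        self.labels_frame().to_csv(path, sep="\t", index=False)

    def write_blocks_bed(self, path: str | Path, min_windows: int = 1) -> None:
        with open(path, "w") as fh:
            for b in self.blocks:
                if b.n_windows >= min_windows:
                    fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.role}\t{b.n_windows}\t.\n")


def cluster_windows(
    matrix: SignalMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> OccupancySegmentation:
    """K-means (k=2) on z-scored occupancy + expression densities.

    Both channels enter the feature matrix; z-scoring keeps the (much
    denser) occupancy channel from dominating the Euclidean metric.  With
    k=2 the cluster whose mean raw occupancy density is higher is labeled
    HOG.  For exploratory k>2, clusters are labeled HOG1 >= HOG2 >= ... by
    descending mean occupancy.
    """
    X = matrix.values.copy()
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} windows, got {X.shape[0]}")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate feature matrix: all windows identical")
    if standardize:
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by mean occupancy (NO channel; all channels if untagged)
    no = matrix.columns_by_channel("NO")
    if no.shape[1] == 0:
        no = matrix.values
    mean_no = np.array([no[raw == c].mean() for c in range(k)])
    order = np.argsort(-mean_no)  # cluster ids, highest occupancy first
    if k == 2:
        names = {order[0]: HOG, order[1]: LOG}
    else:
        names = {c: f"HOG{i + 1}" for i, c in enumerate(order)}
    labels = np.array([names[c] for c in raw], dtype=object)
    return OccupancySegmentation(matrix.grid, labels, segment_blocks(matrix.grid, labels))


def segment_blocks(
    grid: WindowGrid,
    labels: Sequence[str],
    min_windows: int = 1,
) -> list[Block]:
    """Run-length encode per-window labels into maximal same-label blocks.

    Runs never cross chromosome boundaries.  ``min_windows`` filters the
    returned blocks (default 1 = report all); filtering never merges runs.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (grid.n_windows,):
        raise ValueError("label vector length does not match grid")
    blocks: list[Block] = []
    for chrom in grid.chrom_sizes:
        sl = grid.chrom_slice(chrom)
        ids = np.arange(sl.start, sl.stop)
        lab = labels[sl]
        run_start = 0
        for i in range(1, len(lab) + 1):
            if i == len(lab) or lab[i] != lab[run_start]:
                wids = tuple(ids[run_start:i])
                blocks.append(
                    Block(chrom, grid.windows[wids[0]][1], grid.windows[wids[-1]][2],
                          str(lab[run_start]), wids)
                )
                run_start = i
    return [b for b in blocks if b.n_windows >= min_windows]


def assign_genes(
    genes: Sequence[GeneModel],
    segmentation: OccupancySegmentation,
    ) -> dict[str, str]:
    """Assign each gene the label of the window containing its TSS."""
    grid = segmentation.grid
    out: dict[str, str] = {}
    for g in genes:
        wid = grid.window_id(g.chrom, g.tss)
        out[g.gene_id] = str(segmentation.labels[wid])
    return out


def compare_groups(
    assignment: Mapping[str, str],
    measures: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Five-number summaries per group and rank-sum p-value per measure.

    ``measures`` maps measure name -> {gene_id: value} (e.g. expression and
    occupancy density).  Returns a tidy frame with one row per
    (measure, group) carrying min/q1/median/q3/max, n, and the two-sided
    Wilcoxon rank-sum p-value for LOG vs HOG (repeated on both rows).  Uses
    the exact null distribution for small groups, normal approximation
    otherwise (scipy's default switch).
    """
    groups = sorted(set(assignment.values()))
    rows = []
    for name, values in measures.items():
        by_group = {
            grp: np.array([values[g] for g in assignment if assignment[g] == grp and g in values])
            for grp in groups
        }
        for grp, v in by_group.items():
            if v.size == 0:
                raise ValueError(f"group {grp} has no genes with measure {name!r}")
        if len(groups) == 2:
            a, b = (by_group[g] for g in groups)
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = np.nan
        for grp in groups:
            v = by_group[grp]
            q = np.percentile(v, [0, 25, 50, 75, 100])
            rows.append({"measure": name, "group": grp, "n": v.size,
                         "min": q[0], "q1": q[1], "median": q[2], "q3": q[3],
                         "max": q[4], "ranksum_p": p})
    return pd.DataFrame(rows)
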