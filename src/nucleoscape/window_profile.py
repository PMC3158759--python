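"""Fixed-width genome windowing, per-window tag counting/normalization, GC and profile correlation.

Chromosomes are tiled with non-overlapping windows (default 100 kb, the
terminal window may be short).  Tags are assigned to windows by their 5'
start coordinate; densities are expressed per million mapped tags so that
samples of different sequencing depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ChromSizes, ReadTag

__all__ = [
    "WindowGrid",
    "SignalMatrix",
    "make_grid",
    "count_tags",
    "normalize",
    "window_gc",
    "correlate_profiles",
]

DEFAULT_WINDOW_SIZE = 100_000


@dataclass(frozen=True)
class WindowGrid:
    """Dense genome partition: windows tile each chromosome from 0 in order.

    Window ids are 0..N-1 in genome order (chromosome order as given in the
    chrom.sizes table, then position).
    """

    chrom_sizes: ChromSizes
    window_size: int
    windows: tuple[tuple[str, int, int], ...]
    _chrom_offset: dict = field(repr=False, default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def chrom_of(self, window_id: int) -> str:
        return self.windows[window_id][0]

    def window_id(self, chrom: str, pos: int) -> int:
        """Window containing genomic position ``pos`` on ``chrom``."""
        if chrom not in self._chrom_offset:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._chrom_offset[chrom] + pos // self.window_size

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of window ids belonging to one chromosome."""
        off = self._chrom_offset[chrom]
        n = -(-self.chrom_sizes[chrom] // self.window_size)
        return slice(off, off + n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["chrom", "start", "end"]).assign(
            window_id=np.arange(self.n_windows)
        )


@dataclass
class SignalMatrix:
    """Windows x samples matrix of normalized tag densities.

    ``channels`` tags each sample column as nucleosome-occupancy ("NO") or
    expression ("RNA"); ``library_sizes`` holds the mapped-tag totals used
    for normalization.
    """

    grid: WindowGrid
    values: np.ndarray          # shape (n_windows, n_samples)
    samples: list[str]
    channels: list[str]         # "NO" | "RNA" per sample
    library_sizes: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_windows, len(self.samples)):
            raise ValueError("signal matrix shape does not match grid/samples")
        if len(self.channels) != len(self.samples) or len(self.library_sizes) != len(self.samples):
            raise ValueError("per-sample metadata length mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("signal values must be finite and non-negative")

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]

    def columns_by_channel(self, channel: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.channels) if c == channel]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        for i, s in enumerate(self.samples):
            df[s] = self.values[:, i]
        return df

    def write_tsv(self, path: str | Path) -> None:
        header = "\t".join(f"{s}:{c}:{n}" for s, c, n in
                           zip(self.samples, self.channels, self.library_sizes))
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# samples\t{header}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, chrom_sizes: ChromSizes | None = None) -> "SignalMatrix":
        with open(path) as fh:
            meta = fh.readline().rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t")
        samples, channels, libs = [], [], []
        for m in meta:
            s, c, n = m.rsplit(":", 2)
            samples.append(s); channels.append(c); libs.append(int(n))
        if chrom_sizes is None:
            sizes = df.groupby("chrom", sort=False)["end"].max()
            chrom_sizes = ChromSizes(dict(sizes))
        wsize = int((df["end"] - df["start"]).max())
        grid = make_grid(chrom_sizes, wsize)
        return cls(grid, df[samples].to_numpy(), samples, channels, libs)


def make_grid(chrom_sizes: ChromSizes, window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile each chromosome with ``window_size`` windows (terminal window may be short)."""
    window_size = int(window_size)
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    windows: list[tuple[str, int, int]] = []
    offsets: dict[str, int] = {}
    for chrom, length in chrom_sizes.items():
        offsets[chrom] = len(windows)
        for start in range(0, length, window_size):
            windows.append((chrom, start, min(start + window_size, length)))
    return WindowGrid(chrom_sizes, window_size, tuple(windows), offsets)


def count_tags(
    grid: WindowGrid,
    tags: Iterable[ReadTag],
    lenient: bool = False,
) -> tuple[np.ndarray, int]:
    """Count tags per window by 5' start coordinate.

    Returns (raw counts, library size).  The sum of counts always equals the
    library size: each tag lands in exactly one window.  Tags on chromosomes
    absent from the grid raise unless ``lenient`` (then they are skipped and
    excluded from the library size).
    """
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    n = 0
    for t in tags:
        try:
            wid = grid.window_id(t.chrom, t.start)
        except (KeyError, ValueError):
            if lenient:
                continue
            raise
        counts[wid] += 1
        n += 1
    return counts, n


def normalize(raw_counts: np.ndarray, library_size: int) -> np.ndarray:
    """Tags per window per million mapped tags: raw * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(raw_counts, dtype=float) * 1e6 / library_size


def window_gc(grid: WindowGrid, fasta) -> np.ndarray:
    """GC fraction per window: (G+C)/(A+C+G+T); all-N windows give NaN.

    ``fasta`` is a pyfaidx.Fasta (or any mapping of chrom -> sequence
    supporting slicing and ``str()``).
    """
    gc = np.full(grid.n_windows, np.nan)
    for wid, (chrom, start, end) in enumerate(grid.windows):
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        seq = str(fasta[chrom][start:end]).upper()
        g = seq.count("G") + seq.count("C")
        acgt = g + seq.count("A") + seq.count("T")
        if acgt > 0:
            gc[wid] = g / acgt
    return gc


def correlate_profiles(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two window profiles.

    Windows where either value is non-finite are dropped; requires >=3
    remaining windows and non-zero variance in both.  Returns (r, two-sided
    p-value from the t distribution with N-2 df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite paired windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
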