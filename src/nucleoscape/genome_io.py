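"""Core genomic types and readers/writers for the plain-text formats the pipeline touches.

All internal coordinates are 0-based half-open.  BED is taken as-is; GTF
(1-based, closed) is converted on read.  Gene tables are exchanged in the
refFlat convention (geneName, name, chrom, strand, txStart, txEnd, cdsStart,
cdsEnd, exonCount, exonStarts, exonEnds).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "ReadTag",
    "GeneModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tags",
    "write_tags",
    "read_genes",
    "write_genes",
    "select_isoform",
    "write_bedgraph",
    "read_bedgraph",
]


class GenomeIOError(ValueError):
    """Malformed input file or record violating a genomic invariant."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bp) table.

    Names must be unique and lengths positive; iteration order is the order
    chromosomes appear in the source file, which fixes genome order for
    window ids downstream.
    """

    sizes: Mapping[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise GenomeIOError("empty chromosome sizes table")
        for name, length in self.sizes.items():
            if int(length) < 1:
                raise GenomeIOError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "sizes", dict(self.sizes))

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __iter__(self):
        return iter(self.sizes)

    def __len__(self):
        return len(self.sizes)

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    def items(self):
        return self.sizes.items()


@dataclass(frozen=True, order=True)
class ReadTag:
    """One aligned sequence tag; the unit of all counting."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid tag interval {self.chrom}:{self.start}-{self.end} (start >= end or negative)"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """Transcript model: span, strand and ordered disjoint exons.

    ``tss``/``tts`` are strand-aware: for a minus-strand gene the TSS is
    ``tx_end`` (the rightmost base is transcribed first).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    tx_id: str = ""

    def __post_init__(self):
        if not self.tx_id:
            object.__setattr__(self, "tx_id", self.gene_id)
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise GenomeIOError(f"gene {self.gene_id}: invalid span {self.tx_start}-{self.tx_end}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise GenomeIOError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise GenomeIOError(f"gene {self.gene_id}: empty exon {s}-{e}")
            if s < self.tx_start or e > self.tx_end:
                raise GenomeIOError(
                    f"gene {self.gene_id}: exon {s}-{e} outside transcript span "
                    f"{self.tx_start}-{self.tx_end}"
                )
            if prev_end is not None and s < prev_end:
                raise GenomeIOError(f"gene {self.gene_id}: overlapping exons at {s}")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column chrom.sizes table (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1],
                     names=["chrom", "length"], dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise GenomeIOError(f"duplicate chromosome {dup!r} in {path}")
    return ChromSizes(dict(zip(df["chrom"], df["length"].astype(int))))


def write_chrom_sizes(chrom_sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_tags(
    path: str | Path,
    chrom_sizes: ChromSizes | None = None,
    collapse_duplicates: bool = False,
) -> list[ReadTag]:
    """Read aligned tags from a BED3/BED6 file.

    The strand column (field 6) is optional and defaults to "+".  When
    ``chrom_sizes`` is given every record is validated against it.  Duplicate
    tags are kept unless ``collapse_duplicates`` is set (identical
    chrom/start/end/strand collapses to one tag).
    """
    tags: list[ReadTag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(f"{path}: malformed BED line {lineno}: {line!r}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomeIOError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start >= end:
                raise GenomeIOError(f"{path}: start >= end at line {lineno}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise GenomeIOError(f"{path}: unknown chromosome {chrom!r} at line {lineno}")
                if end > chrom_sizes[chrom]:
                    raise GenomeIOError(
                        f"{path}: tag end {end} beyond {chrom} length "
                        f"{chrom_sizes[chrom]} at line {lineno}"
                    )
            tags.append(ReadTag(chrom, start, end, strand))
    if collapse_duplicates:
        tags = sorted(set(tags))
    return tags


def write_tags(tags: Iterable[ReadTag], path: str | Path) -> None:
    """Write tags as BED6 (name ".", score 0)."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t.\t0\t{t.strand}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_genes_gtf(path: str | Path) -> list[GeneModel]:
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GenomeIOError(f"{path}: malformed GTF line {lineno}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            tx = attr.get("transcript_id") or attr.get("gene_id")
            if tx is None:
                raise GenomeIOError(f"{path}: exon without transcript_id at line {lineno}")
            gene = attr.get("gene_id", tx)
            # GTF is 1-based closed; convert to 0-based half-open.
            s, e = int(start) - 1, int(end)
            rec = per_tx.get(tx)
            if rec is None:
                per_tx[tx] = rec = {"chrom": chrom, "strand": strand, "gene": gene, "exons": []}
                order.append(tx)
            rec["exons"].append((s, e))
    models = []
    for tx in order:
        rec = per_tx[tx]
        exons = sorted(rec["exons"])
        models.append(
            GeneModel(rec["gene"], rec["chrom"], rec["strand"],
                      exons[0][0], exons[-1][1], tuple(exons), tx_id=tx)
        )
    return models


def _read_genes_refflat(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["geneName", "name", "chrom", "strand", "txStart", "txEnd",
               "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds"],
        dtype=str,
    )
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exonStarts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exonEnds).rstrip(",").split(",")]
        if len(starts) != len(ends) or len(starts) != int(row.exonCount):
            raise GenomeIOError(f"gene {row.name}: inconsistent exon blocks")
        models.append(
            GeneModel(str(row.geneName), str(row.chrom), str(row.strand),
                      int(row.txStart), int(row.txEnd), tuple(zip(starts, ends)),
                      tx_id=str(row.name))
        )
    return models


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a GTF (by ``.gtf`` suffix) or refFlat table."""
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_genes_gtf(path)
    return _read_genes_refflat(path)


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as a refFlat table (geneName column repeats gene_id)."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.gene_id}\t{g.tx_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{g.tx_start}\t{g.tx_start}\t{g.exon_count}\t{starts}\t{ends}\n"
            )


def select_isoform(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Keep one model per gene_id: the isoform with the most exons.

    Ties on exon count go to the longer transcript span, then to the
    lexicographically smaller gene_id, so the result is order-invariant.
    Output is sorted by (chrom, tx_start, gene_id).
    """
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key = (m.exon_count, m.tx_end - m.tx_start)
        cur_key = (cur.exon_count, cur.tx_end - cur.tx_start)
        if key > cur_key or (key == cur_key and m.tx_id < cur.tx_id):
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda g: (g.chrom, g.tx_start, g.gene_id))


def write_bedgraph(grid, values, path: str | Path) -> None:
    """Write one value per window as a 4-column BedGraph track.

    ``grid`` is a :class:`~nucleoscape.window_profile.WindowGrid`; values must
    be finite and one per window.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_windows,):
        raise GenomeIOError(
            f"value count {values.shape} does not match window count {grid.n_windows}"
        )
    if not np.all(np.isfinite(values)):
        raise GenomeIOError("non-finite value in BedGraph output")
    with open(path, "w") as fh:
        for (chrom, start, end), v in zip(grid.windows, values):
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6f}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column BedGraph into a DataFrame (chrom, start, end, value)."""
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str, "start": int, "end": int, "value": float})
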