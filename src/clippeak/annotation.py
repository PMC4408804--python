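"""Genomic coordinate universe: extended exons, exon islands, windows, miRNA regions.

The pipeline summarizes reads over a fixed coordinate universe built once
from the annotation:

1. gene envelopes are extended at their ends (default 200 bp at the 5'
   end, 750 bp at the 3' end) to compensate for missing UTR annotation;
2. overlapping or book-ended extended exons on the same strand are
   concatenated into disjoint *exon islands*;
3. each island is tiled with consecutive 150-bp windows (the last window
   of an island may be shorter);
4. pre-miRNA coordinates are extended 1000 bp on each side into putative
   pri-miRNA regions, truncated at any overlapping extended exon, and
   dropped entirely when the pre-miRNA itself overlaps an exon.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError

log = logging.getLogger("clippeak")

DEFAULT_EXT5 = 200
DEFAULT_EXT3 = 750
DEFAULT_WINDOW = 150
DEFAULT_MIRNA_EXT = 1000

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand '.' only in strand-agnostic contexts."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise DataError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Window:
    interval: GenomicInterval
    island_id: str
    index_in_island: int

    @property
    def window_id(self) -> str:
        return f"{self.island_id}:{self.index_in_island}"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ExonIsland:
    island_id: str
    interval: GenomicInterval
    source_genes: list[str]
    windows: list[Window] = field(default_factory=list)


@dataclass
class MirnaRegion:
    mirna_name: str
    pre_interval: GenomicInterval
    extended_interval: GenomicInterval
    truncated_5p: bool = False
    truncated_3p: bool = False


def extend_gene_regions(
    exons: pd.DataFrame,
    ext5: int = DEFAULT_EXT5,
    ext3: int = DEFAULT_EXT3,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend each gene's envelope ext5 bp at its 5' end and ext3 bp at its 3' end.

    The extension is applied to the first/last exon of the gene (by
    genomic coordinate, mirrored for minus-strand genes), not per internal
    exon; coordinates are clipped at 0 and the chromosome length.  Genes on
    chromosomes absent from ``chrom_sizes`` are rejected with a warning.
    """
    if ext5 < 0 or ext3 < 0:
        raise DataError("extensions must be non-negative")
    out = []
    for (gene_id, chrom, strand), grp in exons.groupby(
        ["gene_id", "chrom", "strand"], sort=True
    ):
        if chrom_sizes is not None and chrom not in chrom_sizes:
            log.warning("gene %s on unknown chromosome %s: skipped", gene_id, chrom)
            continue
        clen = chrom_sizes[chrom] if chrom_sizes is not None else None
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy().copy()
        ends = grp["end"].to_numpy().copy()
        up, down = (ext5, ext3) if strand == "+" else (ext3, ext5)
        starts[0] = max(starts[0] - up, 0)
        ends[-1] = ends[-1] + down
        if clen is not None:
            ends[-1] = min(ends[-1], clen)
        for s, e in zip(starts, ends):
            out.append((chrom, int(s), int(e), strand, gene_id))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "strand", "gene_id"])


def build_exon_islands(exons: pd.DataFrame) -> list[ExonIsland]:
    """Concatenate overlapping or book-ended exon records per strand.

    Book-ended intervals are merged as well so windows never split at an
    artificial seam.  Islands on the same strand are pairwise disjoint;
    a locus may host one island per strand.
    """
    islands: list[ExonIsland] = []
    for (chrom, strand), grp in exons.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        cur_genes: set[str] = set()
        n = 0

        def flush():
            nonlocal n
            if cur_start is None:
                return
            iid = f"isl_{chrom}_{'p' if strand == '+' else 'm'}_{n:04d}"
            islands.append(
                ExonIsland(
                    island_id=iid,
                    interval=GenomicInterval(chrom, cur_start, cur_end, strand),
                    source_genes=sorted(cur_genes),
                )
            )
            n += 1

        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
                cur_genes = {row.gene_id}
            elif row.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, row.end)
                cur_genes.add(row.gene_id)
            else:
                flush()
                cur_start, cur_end = row.start, row.end
                cur_genes = {row.gene_id}
        flush()
    return islands


def tile_windows(island: ExonIsland, width: int = DEFAULT_WINDOW) -> list[Window]:
    """Tile an island with consecutive windows of ``width`` bp.

    The tiling partitions the island exactly: the last window may be
    shorter than ``width``.
    """
    if width <= 0:
        raise DataError("window width must be positive")
    iv = island.interval
    windows = []
    for idx, s in enumerate(range(iv.start, iv.end, width)):
        e = min(s + width, iv.end)
        windows.append(
            Window(GenomicInterval(iv.chrom, s, e, iv.strand), island.island_id, idx)
        )
    return windows


def build_mirna_regions(
    premirnas: pd.DataFrame,
    extended_exons: pd.DataFrame,
    ext: int = DEFAULT_MIRNA_EXT,
    chrom_sizes: dict[str, int] | None = None,
) -> list[MirnaRegion]:
    """Extend pre-miRNAs into putative pri-miRNA regions.

    ``premirnas`` is a BED6-shaped DataFrame (chrom, start, end, name,
    score, strand).  A pre-miRNA overlapping any extended exon (either
    strand) is discarded; otherwise its +-ext flanks are truncated at the
    boundary of the nearest overlapping exon.
    """
    if ext < 0:
        raise DataError("miRNA extension must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for row in extended_exons.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)

    regions: list[MirnaRegion] = []
    for row in premirnas.itertuples(index=False):
        try:
            pre = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        except (DataError, ValueError) as e:
            log.warning("malformed pre-miRNA record %s: %s", getattr(row, "name", "?"), e)
            continue
        tree = trees.get(pre.chrom, IntervalTree())
        if tree.overlap(pre.start, pre.end):
            log.info("pre-miRNA %s overlaps an exon region: discarded", row.name)
            continue
        ext_start = max(pre.start - ext, 0)
        ext_end = pre.end + ext
        if chrom_sizes is not None and pre.chrom in chrom_sizes:
            ext_end = min(ext_end, chrom_sizes[pre.chrom])
        trunc5 = trunc3 = False
        up_hits = tree.overlap(ext_start, pre.start)
        if up_hits:
            ext_start = max(h.end for h in up_hits)
            trunc5 = True
        down_hits = tree.overlap(pre.end, ext_end)
        if down_hits:
            ext_end = min(h.begin for h in down_hits)
            trunc3 = True
        regions.append(
            MirnaRegion(
                mirna_name=str(row.name),
                pre_interval=pre,
                extended_interval=GenomicInterval(pre.chrom, ext_start, ext_end, pre.strand),
                truncated_5p=trunc5,
                truncated_3p=trunc3,
            )
        )
    return regions


class WindowUniverse:
    """Islands plus their window tiling, with fast 5'-position lookup.

    Built once per run from the extended exon table; the ingest and peak
    modules address windows exclusively through this object.
    """

    def __init__(self, islands: list[ExonIsland], width: int = DEFAULT_WINDOW):
        self.width = width
        self.islands = islands
        self.windows: list[Window] = []
        for isl in islands:
            isl.windows = tile_windows(isl, width)
            self.windows.extend(isl.windows)
        self.window_ids = [w.window_id for w in self.windows]
        self._index = {wid: i for i, wid in enumerate(self.window_ids)}
        # per (chrom, strand): sorted start/end arrays for searchsorted lookup
        self._lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_key: dict[tuple[str, str], list[int]] = {}
        for i, w in enumerate(self.windows):
            by_key.setdefault((w.interval.chrom, w.interval.strand), []).append(i)
        for key, idxs in by_key.items():
            idxs = sorted(idxs, key=lambda i: self.windows[i].interval.start)
            starts = np.array([self.windows[i].interval.start for i in idxs])
            ends = np.array([self.windows[i].interval.end for i in idxs])
            self._lookup[key] = (starts, ends, np.array(idxs))

    @classmethod
    def from_exons(cls, extended_exons: pd.DataFrame, width: int = DEFAULT_WINDOW):
        return cls(build_exon_islands(extended_exons), width)

    def __len__(self) -> int:
        return len(self.windows)

    def window_index(self, window_id: str) -> int:
        return self._index[window_id]

    def locate(self, chrom: str, pos: int, strand: str | None = None) -> list[int]:
        """Indices of windows containing ``pos`` (both strands when strand is None)."""
        strands = STRANDS if strand is None else (strand,)
        hits = []
        for st in strands:
            entry = self._lookup.get((chrom, st))
            if entry is None:
                continue
            starts, ends, idxs = entry
            j = int(np.searchsorted(starts, pos, side="right")) - 1
            if j >= 0 and pos < ends[j]:
                hits.append(int(idxs[j]))
        return hits

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                w.window_id,
                w.interval.chrom,
                w.interval.start,
                w.interval.end,
                w.interval.strand,
                w.island_id,
                w.index_in_island,
                w.length,
            )
            for w in self.windows
        ]
        return pd.DataFrame(
            rows,
            columns=["window_id", "chrom", "start", "end", "strand", "island_id", "index_in_island", "length"],
        )

    def islands_frame(self) -> pd.DataFrame:
        rows = [
            (
                isl.island_id,
                isl.interval.chrom,
                isl.interval.start,
                isl.interval.end,
                isl.interval.strand,
                ",".join(isl.source_genes),
            )
            for isl in self.islands
        ]
        return pd.DataFrame(
            rows, columns=["island_id", "chrom", "start", "end", "strand", "source_genes"]
        )


def mirna_regions_frame(regions: list[MirnaRegion]) -> pd.DataFrame:
    rows = [
        (
            r.mirna_name,
            r.extended_interval.chrom,
            r.extended_interval.start,
            r.extended_interval.end,
            r.extended_interval.strand,
            r.pre_interval.start,
            r.pre_interval.end,
            r.truncated_5p,
            r.truncated_3p,
        )
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_name", "chrom", "start", "end", "strand",
            "pre_start", "pre_end", "truncated_5p", "truncated_3p",
        ],
    )
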