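"""Coordinate geometry: extensions, islands, tiling, miRNA regions."""

import numpy as np
import pandas as pd
import pytest

from clippeak.annotation import (
    ExonIsland,
    GenomicInterval,
    WindowUniverse,
    build_exon_islands,
    build_mirna_regions,
    extend_gene_regions,
    tile_windows,
)
from clippeak.errors import DataError
from clippeak.io import read_bed12_exons

SIZES = {"chr1": 100_000}


def exon_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


class TestExtendGeneRegions:
    def test_plus_strand_extension(self):
        out = extend_gene_regions(exon_df([("chr1", 1000, 2000, "+", "g1")]), 200, 750, SIZES)
        assert (out.start.iloc[0], out.end.iloc[0]) == (800, 2750)

    def test_minus_strand_mirrors(self):
        out = extend_gene_regions(exon_df([("chr1", 1000, 2000, "-", "g1")]), 200, 750, SIZES)
        assert (out.start.iloc[0], out.end.iloc[0]) == (250, 2200)

    def test_clipped_at_chromosome_start(self):
        out = extend_gene_regions(exon_df([("chr1", 100, 600, "+", "g1")]), 200, 750, SIZES)
        assert out.start.iloc[0] == 0

    def test_extension_applies_to_gene_envelope_only(self):
        rows = [("chr1", 1000, 1200, "+", "g1"), ("chr1", 1500, 1700, "+", "g1")]
        out = extend_gene_regions(exon_df(rows), 200, 750, SIZES).sort_values("start")
        assert list(out.start) == [800, 1500]
        assert list(out.end) == [1200, 2450]

    def test_unknown_chromosome_skipped(self):
        rows = [("chrUn", 10, 20, "+", "g1"), ("chr1", 1000, 2000, "+", "g2")]
        out = extend_gene_regions(exon_df(rows), 200, 750, SIZES)
        assert list(out.gene_id) == ["g2"]


class TestExonIslands:
    def test_overlap_merges(self):
        isl = build_exon_islands(exon_df([("chr1", 0, 300, "+", "a"), ("chr1", 200, 500, "+", "b")]))
        assert len(isl) == 1
        assert (isl[0].interval.start, isl[0].interval.end) == (0, 500)
        assert isl[0].source_genes == ["a", "b"]

    def test_disjoint_preserved_and_adjacency_merged(self):
        isl = build_exon_islands(exon_df([("chr1", 0, 300, "+", "a"), ("chr1", 400, 500, "+", "b")]))
        assert len(isl) == 2
        isl2 = build_exon_islands(exon_df([("chr1", 0, 300, "+", "a"), ("chr1", 300, 500, "+", "b")]))
        assert len(isl2) == 1

    def test_strands_never_merge(self):
        isl = build_exon_islands(exon_df([("chr1", 0, 300, "+", "a"), ("chr1", 200, 500, "-", "b")]))
        assert len(isl) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(200):
            s = int(rng.integers(0, 50_000))
            rows.append(("chr1", s, s + int(rng.integers(50, 800)), "+" if i % 2 else "-", f"g{i}"))
        first = build_exon_islands(exon_df(rows))
        again = build_exon_islands(
            exon_df(
                [
                    (i.interval.chrom, i.interval.start, i.interval.end, i.interval.strand, i.island_id)
                    for i in first
                ]
            )
        )
        assert [(i.interval.start, i.interval.end, i.interval.strand) for i in first] == [
            (i.interval.start, i.interval.end, i.interval.strand) for i in again
        ]


class TestTiling:
    @pytest.mark.parametrize(
        "length,expected",
        [(450, [150, 150, 150]), (500, [150, 150, 150, 50]), (100, [100])],
    )
    def test_window_lengths(self, length, expected):
        isl = ExonIsland("i0", GenomicInterval("chr1", 1000, 1000 + length, "+"), ["g"])
        ws = tile_windows(isl, 150)
        assert [w.length for w in ws] == expected
        assert ws[0].interval.start == 1000 and ws[-1].interval.end == 1000 + length

    def test_tiling_partitions_random_islands(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 2_000))
            isl = ExonIsland("i", GenomicInterval("chr1", s, e, "+"), ["g"])
            ws = tile_windows(isl)
            assert sum(w.length for w in ws) == e - s
            for w1, w2 in zip(ws, ws[1:]):
                assert w1.interval.end == w2.interval.start


def premirna_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestMirnaRegions:
    EXONS = exon_df([("chr1", 4000, 4500, "+", "g1")])

    def test_free_standing_full_extension(self):
        regions = build_mirna_regions(
            premirna_df([("chr1", 15000, 15100, "mirA", 0, "+")]), self.EXONS, 1000, SIZES
        )
        r = regions[0]
        assert (r.extended_interval.start, r.extended_interval.end) == (14000, 16100)
        assert not (r.truncated_5p or r.truncated_3p)

    def test_truncated_at_exon_boundary(self):
        regions = build_mirna_regions(
            premirna_df([("chr1", 5000, 5100, "mirB", 0, "+")]), self.EXONS, 1000, SIZES
        )
        r = regions[0]
        assert (r.extended_interval.start, r.extended_interval.end) == (4500, 6100)
        assert r.truncated_5p and not r.truncated_3p

    def test_overlapping_exon_discarded(self):
        regions = build_mirna_regions(
            premirna_df([("chr1", 4450, 4550, "mirC", 0, "+")]), self.EXONS, 1000, SIZES
        )
        assert regions == []

    def test_no_surviving_region_touches_exons(self):
        rng = np.random.default_rng(9)
        exons = exon_df(
            [
                ("chr1", int(s), int(s) + 400, "+", f"g{i}")
                for i, s in enumerate(rng.integers(0, 90_000, 40))
            ]
        )
        mirs = premirna_df(
            [
                ("chr1", int(s), int(s) + 80, f"m{i}", 0, "+")
                for i, s in enumerate(rng.integers(0, 90_000, 40))
            ]
        )
        regions = build_mirna_regions(mirs, exons, 1000, SIZES)
        for r in regions:
            for e in exons.itertuples(index=False):
                assert not (r.extended_interval.start < e.end and e.start < r.extended_interval.end)


class TestWindowUniverse:
    def test_locate_by_strand(self):
        uni = WindowUniverse.from_exons(
            exon_df([("chr1", 0, 300, "+", "a"), ("chr1", 0, 300, "-", "b")])
        )
        plus = uni.locate("chr1", 10, "+")
        minus = uni.locate("chr1", 10, "-")
        both = uni.locate("chr1", 10)
        assert len(plus) == 1 and len(minus) == 1
        assert sorted(both) == sorted(plus + minus)
        assert uni.locate("chr1", 400, "+") == []

    def test_window_ids_unique(self):
        uni = WindowUniverse.from_exons(exon_df([("chr1", 0, 1000, "+", "a")]))
        assert len(set(uni.window_ids)) == len(uni)


def test_bed12_expansion_matches_exon_table(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "chr1\t1000\t3000\tg1\t0\t+\t1000\t3000\t0\t2\t200,300\t0,1700\n"
    )
    df = read_bed12_exons(bed)
    assert list(df.itertuples(index=False, name=None)) == [
        ("chr1", 1000, 1200, "+", "g1"),
        ("chr1", 2700, 3000, "+", "g1"),
    ]


def test_interval_validation():
    with pytest.raises(DataError):
        GenomicInterval("chr1", 10, 10, "+")
    with pytest.raises(DataError):
        GenomicInterval("chr1", 0, 10, "x")
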