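"""Alignment ingest: window counting, mutation extraction, coverage."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_bam, sam_line
from clippeak.annotation import WindowUniverse
from clippeak.errors import DataError
from clippeak.ingest import (
    count_reads_in_windows,
    coverage_at_position,
    coverage_tracks,
    extract_mutation_events,
)

SIZES = {"chr1": 10_000}


def universe_one_window(strand="+"):
    exons = pd.DataFrame(
        [("chr1", 1000, 1150, strand, "g1")],
        columns=["chrom", "start", "end", "strand", "gene_id"],
    )
    return WindowUniverse.from_exons(exons)


SEQ30 = "A" * 30


class TestWindowCounting:
    def test_plus_reads_counted_in_plus_window(self, tmp_path):
        bam = make_bam(
            tmp_path / "a.bam",
            [sam_line(f"r{i}", "chr1", 1010 + i, SEQ30) for i in range(3)],
            SIZES,
        )
        table, rep = count_reads_in_windows(bam, universe_one_window("+"))
        assert table["count"].tolist() == [3]
        assert rep.admitted == 3

    def test_strand_filter_zeroes_wrong_strand(self, tmp_path):
        bam = make_bam(
            tmp_path / "a.bam",
            [sam_line(f"r{i}", "chr1", 1010, SEQ30, strand="-") for i in range(3)],
            SIZES,
        )
        table, rep = count_reads_in_windows(bam, universe_one_window("+"), stranded=True)
        assert table["count"].tolist() == [0]
        # unstranded counting (the RNA-seq convention) admits both strands
        table2, _ = count_reads_in_windows(bam, universe_one_window("+"), stranded=False)
        assert table2["count"].tolist() == [3]

    def test_unique_positions_deduplicates(self, tmp_path):
        bam = make_bam(
            tmp_path / "a.bam",
            [sam_line(f"r{i}", "chr1", 1020, SEQ30) for i in range(10)],
            SIZES,
        )
        table, _ = count_reads_in_windows(bam, universe_one_window("+"))
        assert table["count"].tolist() == [10]
        assert table["unique_positions"].tolist() == [1]

    def test_five_prime_assignment_for_minus_reads(self, tmp_path):
        # minus-strand read starting left of the window but ending inside it
        bam = make_bam(
            tmp_path / "a.bam",
            [sam_line("r0", "chr1", 990, SEQ30, strand="-")],  # span [990,1020), 5'=1019
            SIZES,
        )
        table, _ = count_reads_in_windows(bam, universe_one_window("-"))
        assert table["count"].tolist() == [1]

    def test_conservation_and_drop_tally(self, tmp_path):
        inside = [sam_line(f"i{k}", "chr1", 1005 + k, SEQ30) for k in range(4)]
        outside = [sam_line(f"o{k}", "chr1", 3000 + k, SEQ30) for k in range(5)]
        low_mapq = [sam_line("bad", "chr1", 1005, SEQ30, mapq=3)]
        bam = make_bam(tmp_path / "a.bam", inside + outside + low_mapq, SIZES)
        table, rep = count_reads_in_windows(bam, universe_one_window("+"))
        assert rep.admitted == 9
        assert table["count"].sum() + rep.dropped_outside_windows == rep.admitted
        assert rep.skipped_filtered == 1

    def test_unindexed_input_fails_fast(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n")
        with pytest.raises(DataError):
            count_reads_in_windows(str(sam), universe_one_window("+"))

    def test_matches_bruteforce_interval_lookup(self, small_dataset):
        # oracle: recount every read against the window frame directly
        import pysam

        from clippeak.annotation import WindowUniverse, extend_gene_regions

        cfg = small_dataset.config
        sizes = {c: len(s) for c, s in small_dataset.sequences.items()}
        ext = extend_gene_regions(small_dataset.exons, cfg.ext5, cfg.ext3, sizes)
        uni = WindowUniverse.from_exons(ext, cfg.window_width)
        table, rep = count_reads_in_windows(small_dataset.paths["clip"], uni)

        wframe = uni.to_frame()
        brute = np.zeros(len(wframe), dtype=int)
        lookup = list(wframe.itertuples())
        with pysam.AlignmentFile(small_dataset.paths["clip"]) as bam:
            n_adm = 0
            for read in bam.fetch():
                if read.mapping_quality < 10 or read.is_secondary or read.is_supplementary:
                    continue
                n_adm += 1
                pos = read.reference_end - 1 if read.is_reverse else read.reference_start
                strand = "-" if read.is_reverse else "+"
                for w in lookup:
                    if (
                        w.chrom == read.reference_name
                        and w.strand == strand
                        and w.start <= pos < w.end
                    ):
                        brute[w.Index] += 1
                        break
        assert rep.admitted == n_adm
        assert np.array_equal(table["count"].to_numpy(), brute)


class TestMutationExtraction:
    def test_deletion_position_from_cigar(self, tmp_path):
        line = sam_line("r0", "chr1", 100, "C" * 20, cigar="10M1D10M", md="10^A10")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        dele = ev[ev.subtype == "deletion"]
        assert len(dele) == 1 and dele.position.iloc[0] == 110

    def test_multibase_deletion_single_event_at_first_base(self, tmp_path):
        line = sam_line("r0", "chr1", 100, "C" * 20, cigar="10M3D10M", md="10^AAA10")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        dele = ev[ev.subtype == "deletion"]
        assert len(dele) == 1 and dele.position.iloc[0] == 110

    def test_substitutions_counted_independently(self, tmp_path):
        # two isolated mismatches; no indels
        line = sam_line("r0", "chr1", 100, "C" * 20, cigar="20M", md="5A8T5")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        assert (ev.subtype == "substitution").sum() == 2
        assert sorted(ev[ev.subtype == "substitution"].position) == [105, 114]
        assert (ev.subtype == "deletion").sum() == 0

    def test_adjacent_substitutions_merge_to_one_event(self, tmp_path):
        line = sam_line("r0", "chr1", 100, "C" * 20, cigar="20M", md="5AT13")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        subs = ev[ev.subtype == "substitution"]
        assert len(subs) == 1
        assert subs.position.iloc[0] == 105
        assert subs.ref.iloc[0] == "AT"

    def test_insertion_anchored_at_preceding_base(self, tmp_path):
        line = sam_line("r0", "chr1", 100, "C" * 21, cigar="10M1I10M", md="20")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        ins = ev[ev.subtype == "insertion"]
        assert len(ins) == 1 and ins.position.iloc[0] == 109

    def test_missing_md_skips_substitutions_with_counter(self, tmp_path):
        sam = tmp_path / "x.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:10000\n")
            fh.write("r0\t0\tchr1\t101\t60\t20M\t*\t0\t0\t" + "C" * 20 + "\t" + "I" * 20 + "\n")
        import pysam

        bam = tmp_path / "x.bam"
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        ev, counters = extract_mutation_events(str(bam))
        assert counters["reads_missing_md"] == 1
        assert len(ev[ev.subtype == "substitution"]) == 0

    def test_planted_mutations_round_trip(self, tmp_path):
        # a read carrying one of each subtype yields exactly three events
        line = sam_line(
            "r0", "chr1", 200, "G" * 30, cigar="5M1D10M1I14M", md="3T1^A24"
        )
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        ev, _ = extract_mutation_events(bam)
        got = sorted(zip(ev.subtype, ev.position))
        # 5M covers 200-204, D deletes 205, 10M covers 206-215, I anchors at 215
        assert got == [("deletion", 205), ("insertion", 215), ("substitution", 203)]


class TestCoverage:
    def test_single_read_span(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [sam_line("r0", "chr1", 100, SEQ30)], SIZES)
        assert coverage_at_position(bam, "chr1", 110) == 1
        assert coverage_at_position(bam, "chr1", 99) == 0
        assert coverage_at_position(bam, "chr1", 130) == 0

    def test_deletion_spanned_base_counts_as_covered(self, tmp_path):
        line = sam_line("r0", "chr1", 100, "C" * 20, cigar="10M2D10M", md="10^AA10")
        bam = make_bam(tmp_path / "a.bam", [line], SIZES)
        assert coverage_at_position(bam, "chr1", 111) == 1

    def test_tracks_equal_per_position_queries(self, tmp_path):
        rng = np.random.default_rng(2)
        lines = []
        for i in range(60):
            start = int(rng.integers(100, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < 0.3:
                lines.append(
                    sam_line(f"r{i}", "chr1", start, "C" * 20, cigar="10M2D10M",
                             md="10^AA10", strand=strand)
                )
            else:
                lines.append(sam_line(f"r{i}", "chr1", start, SEQ30, strand=strand))
        bam = make_bam(tmp_path / "a.bam", lines, SIZES)
        tracks = coverage_tracks(bam)
        for pos in range(90, 460, 7):
            for strand in "+-":
                want = coverage_at_position(bam, "chr1", pos, strand)
                got = int(tracks.get(("chr1", strand), np.zeros(1))[pos]) if ("chr1", strand) in tracks else 0
                assert got == want, (pos, strand)
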