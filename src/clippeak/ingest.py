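"""Alignment ingest: window counts, mutation events, per-position coverage.

Reads are admitted when primary (not secondary/supplementary), mapped,
and at or above a mapping-quality threshold (default 10).  A read is
assigned to the single window containing its 5' end: the leftmost aligned
base for forward reads, the rightmost for reverse reads.  CLIP libraries
are strand-specific, so CLIP counting requires the read strand to match
the window strand; RNA-seq counting combines both strands.

Mutations are extracted per read from the CIGAR plus MD tag as three
independent subtypes (substitution, deletion, insertion).  A run of
consecutive same-type mutated bases yields a single event at the run's
first reference base; insertions are anchored at the reference base
preceding the inserted sequence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation import WindowUniverse
from .errors import DataError

log = logging.getLogger("clippeak")

SUBTYPES = ("substitution", "deletion", "insertion")
DEFAULT_MIN_MAPQ = 10

# CIGAR ops that consume reference and count as covering a position:
# M, D, =, X.  Skipped regions (N) do not cover.
_COVERING_OPS = {0, 2, 7, 8}


def _admitted(read, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and read.mapping_quality >= min_mapq
    )


def _five_prime(read) -> int:
    return read.reference_end - 1 if read.is_reverse else read.reference_start


def _open_bam(path):
    try:
        bam = pysam.AlignmentFile(str(path), "rb")
    except (OSError, ValueError) as e:
        raise DataError(f"cannot open alignment file {path}: {e}") from e
    try:
        bam.check_index()
    except (AttributeError, ValueError) as e:
        bam.close()
        raise DataError(f"{path} has no index; sort and index it first") from e
    return bam


@dataclass
class IngestReport:
    admitted: int = 0
    dropped_outside_windows: int = 0
    skipped_unknown_chrom: int = 0
    skipped_filtered: int = 0
    read_lengths: Counter = None

    def modal_read_length(self) -> int:
        if not self.read_lengths:
            raise DataError("no admitted reads")
        return self.read_lengths.most_common(1)[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("admitted", self.admitted),
                ("dropped_outside_windows", self.dropped_outside_windows),
                ("skipped_unknown_chrom", self.skipped_unknown_chrom),
                ("skipped_filtered", self.skipped_filtered),
                ("modal_read_length", self.modal_read_length() if self.read_lengths else 0),
            ],
            columns=["counter", "value"],
        )


def count_reads_in_windows(
    bam_path,
    universe: WindowUniverse,
    stranded: bool = True,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[pd.DataFrame, IngestReport]:
    """Per-window read counts keyed by 5'-end position.

    Returns ``(table, report)`` where ``table`` has one row per window with
    columns (window_id, count, unique_positions); unique_positions is the
    number of distinct admitted 5' positions in the window.  With
    ``stranded=True`` a read only counts toward the window on its own
    strand; otherwise it counts toward any window covering the position
    (one per strand at most).
    """
    n = len(universe)
    counts = np.zeros(n, dtype=np.int64)
    positions: dict[int, set] = {}
    report = IngestReport(read_lengths=Counter())
    known = set(k[0] for k in universe._lookup)

    with _open_bam(bam_path) as bam:
        refs = set(bam.references)
        for read in bam.fetch(until_eof=False):
            if not _admitted(read, min_mapq):
                report.skipped_filtered += 1
                continue
            chrom = read.reference_name
            if chrom not in known and chrom not in refs:
                report.skipped_unknown_chrom += 1
                continue
            report.admitted += 1
            report.read_lengths[read.query_length] += 1
            pos = _five_prime(read)
            strand = "-" if read.is_reverse else "+"
            hits = universe.locate(chrom, pos, strand if stranded else None)
            if not hits:
                report.dropped_outside_windows += 1
                continue
            for i in hits:
                counts[i] += 1
                positions.setdefault(i, set()).add(pos)

    table = universe.to_frame()[["window_id"]].copy()
    table["count"] = counts
    table["unique_positions"] = [len(positions.get(i, ())) for i in range(n)]
    return table, report


def extract_mutation_events(
    bam_path,
    subtypes=SUBTYPES,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[pd.DataFrame, dict]:
    """Mutation events per (read, run), split by subtype.

    Substitution calling needs the MD tag; reads without it are skipped
    for substitutions and tallied.  Returns ``(events, counters)`` where
    events has columns (chrom, position, strand, subtype, read_id,
    read_start, ref, obs).
    """
    wanted = set(subtypes)
    bad = wanted - set(SUBTYPES)
    if bad:
        raise DataError(f"unknown mutation subtypes: {sorted(bad)}")
    rows = []
    counters = {"reads_scanned": 0, "reads_missing_md": 0}
    with _open_bam(bam_path) as bam:
        for read in bam.fetch(until_eof=False):
            if not _admitted(read, min_mapq):
                continue
            counters["reads_scanned"] += 1
            has_md = read.has_tag("MD")
            if not has_md:
                counters["reads_missing_md"] += 1
            rows.extend(_read_events(read, wanted, has_md))
    events = pd.DataFrame(
        rows, columns=["chrom", "position", "strand", "subtype", "read_id", "read_start", "ref", "obs"]
    )
    return events, counters


def _read_events(read, wanted: set, has_md: bool):
    """Mutation runs of one read: one event per run, at its first reference base.

    Deletion and insertion runs come straight from the CIGAR (each D/I
    operation is already maximal); substitution runs come from the
    MD-derived aligned pairs, merging consecutive mismatched reference
    positions.  Insertions are anchored at the reference base preceding
    the inserted sequence.
    """
    chrom = read.reference_name
    strand = "-" if read.is_reverse else "+"
    qseq = read.query_sequence or ""
    runs = []  # (subtype, first_ref_pos, ref_content, obs_content)

    rpos = read.reference_start
    qpos = 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            rpos += ln
            qpos += ln
        elif op == 2:  # D
            runs.append(("deletion", rpos, "N" * ln, ""))
            rpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 1:  # I
            anchor = max(rpos - 1, read.reference_start)
            runs.append(("insertion", anchor, "", qseq[qpos : qpos + ln]))
            qpos += ln
        elif op == 4:  # S
            qpos += ln
        # H, P consume nothing relevant here

    if "substitution" in wanted and has_md:
        cur = None  # [first_ref_pos, next_ref_pos, ref, obs]
        for q, r, rbase in read.get_aligned_pairs(with_seq=True):
            if q is None or r is None:
                continue
            if rbase is not None and rbase.islower():
                if cur is not None and r == cur[1]:
                    cur[1] += 1
                    cur[2] += rbase.upper()
                    cur[3] += qseq[q]
                else:
                    if cur is not None:
                        runs.append(("substitution", cur[0], cur[2], cur[3]))
                    cur = [r, r + 1, rbase.upper(), qseq[q]]
        if cur is not None:
            runs.append(("substitution", cur[0], cur[2], cur[3]))

    return [
        (chrom, int(pos), strand, kind, read.query_name, int(read.reference_start), ref_c, obs_c)
        for kind, pos, ref_c, obs_c in runs
        if kind in wanted
    ]


def _covered_intervals(read):
    """Reference intervals covered by the alignment (M/D/=/X consume and cover)."""
    out = []
    pos = read.reference_start
    start = None
    for op, ln in read.cigartuples:
        if op in _COVERING_OPS:
            if start is None:
                start = pos
            pos += ln
        else:
            if op == 3:  # N: break coverage
                if start is not None:
                    out.append((start, pos))
                    start = None
                pos += ln
            # I, S, H, P consume no reference
    if start is not None:
        out.append((start, pos))
    return out


def coverage_at_position(
    bam_path, chrom: str, position: int, strand: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> int:
    """Number of admitted reads whose aligned span covers ``position``.

    Reference bases deleted from a read still count as covered: the
    deletion evidence at a base comes from exactly such reads.
    """
    with _open_bam(bam_path) as bam:
        return _coverage(bam, chrom, position, strand, min_mapq)


def _coverage(bam, chrom, position, strand, min_mapq) -> int:
    y = 0
    if chrom not in set(bam.references):
        return 0
    for read in bam.fetch(chrom, position, position + 1):
        if not _admitted(read, min_mapq):
            continue
        if strand is not None and ("-" if read.is_reverse else "+") != strand:
            continue
        if any(s <= position < e for s, e in _covered_intervals(read)):
            y += 1
    return y


def coverage_for_positions(
    bam_path, positions: pd.DataFrame, min_mapq: int = DEFAULT_MIN_MAPQ
) -> np.ndarray:
    """Vector of coverages for a (chrom, position, strand) DataFrame."""
    out = np.zeros(len(positions), dtype=np.int64)
    with _open_bam(bam_path) as bam:
        for i, row in enumerate(positions.itertuples(index=False)):
            out[i] = _coverage(bam, row.chrom, int(row.position), row.strand, min_mapq)
    return out


def coverage_tracks(
    bam_path, min_mapq: int = DEFAULT_MIN_MAPQ
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base, per-strand coverage arrays for the whole file in one pass.

    Equivalent to :func:`coverage_at_position` at every base (deletion-
    spanned bases count as covered), but O(reads) instead of O(positions
    x reads).  Keys are (chrom, strand).
    """
    diffs: dict[tuple[str, str], np.ndarray] = {}
    with _open_bam(bam_path) as bam:
        sizes = dict(zip(bam.references, bam.lengths))
        for read in bam.fetch(until_eof=False):
            if not _admitted(read, min_mapq):
                continue
            key = (read.reference_name, "-" if read.is_reverse else "+")
            d = diffs.get(key)
            if d is None:
                d = diffs[key] = np.zeros(sizes[read.reference_name] + 1, dtype=np.int32)
            for s, e in _covered_intervals(read):
                d[s] += 1
                d[e] -= 1
    return {k: np.cumsum(v[:-1], dtype=np.int32) for k, v in diffs.items()}


def count_reads_in_regions(
    bam_path,
    regions: pd.DataFrame,
    stranded: bool = True,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> np.ndarray:
    """Total reads per region (rows: chrom, start, end, strand), by 5' position."""
    out = np.zeros(len(regions), dtype=np.int64)
    with _open_bam(bam_path) as bam:
        refs = set(bam.references)
        for i, row in enumerate(regions.itertuples(index=False)):
            if row.chrom not in refs:
                continue
            lo = max(int(row.start) - 1000, 0)
            for read in bam.fetch(row.chrom, lo, int(row.end) + 1000):
                if not _admitted(read, min_mapq):
                    continue
                if stranded and ("-" if read.is_reverse else "+") != row.strand:
                    continue
                pos = _five_prime(read)
                if int(row.start) <= pos < int(row.end):
                    out[i] += 1
    return out
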