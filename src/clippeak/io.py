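"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open everywhere (BED convention); exon-level
annotation is accepted either as a five-column TSV
(chrom, start, end, strand, gene_id) or as BED12 with exon blocks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .errors import DataError

log = logging.getLogger("clippeak")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

EXON_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_exon_table(path) -> pd.DataFrame:
    """Exon-level TSV: chrom, start, end, strand, gene_id (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 5:
        raise DataError(f"{path}: expected >= 5 columns (chrom start end strand gene_id)")
    if list(df.iloc[0, :3]) == ["chrom", "start", "end"]:
        df = df.iloc[1:]
    df = df.iloc[:, :5]
    df.columns = EXON_COLUMNS
    df = df.astype({"start": int, "end": int})
    bad = df["strand"].isin(["+", "-"]) == False  # noqa: E712
    if bad.any():
        raise DataError(f"{path}: exon records must carry strand + or -")
    return df.reset_index(drop=True)


def read_bed12_exons(path) -> pd.DataFrame:
    """Expand BED12 blocks into the exon table; the name field is the gene id."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise DataError(f"{path}:{ln}: BED12 requires 12 fields")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(v) for v in f[10].rstrip(",").split(",")]
            starts = [int(v) for v in f[11].rstrip(",").split(",")]
            for sz, st in zip(sizes, starts):
                rows.append((chrom, start + st, start + st + sz, strand, name))
    return pd.DataFrame(rows, columns=EXON_COLUMNS)


def read_annotation(path) -> pd.DataFrame:
    """Dispatch on extension: .bed/.bed12 -> BED12 blocks, else exon TSV."""
    p = Path(path)
    if p.suffix in {".bed", ".bed12"}:
        return read_bed12_exons(p)
    return read_exon_table(p)


def read_bed6(path) -> pd.DataFrame:
    """BED6 -> DataFrame(chrom, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise DataError(f"{path}:{ln}: BED6 requires 6 fields")
            try:
                rows.append((f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]))
            except ValueError as e:
                raise DataError(f"{path}:{ln}: malformed BED record: {e}") from e
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed6(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.strand}\n")


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fasta(records, path, width: int = 70) -> None:
    """records: iterable of (header, sequence)."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    out, header, chunks = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        out.append((header, "".join(chunks)))
    return out


def chrom_sizes(fasta_path) -> dict[str, int]:
    """Chromosome lengths from a FASTA (builds the .fai on first use)."""
    fa = Fasta(str(fasta_path))
    return {name: len(fa[name]) for name in fa.keys()}


def config_hash(obj) -> str:
    """Short stable digest of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
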