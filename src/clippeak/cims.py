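"""Crosslink-induced mutation site (CIMS) analysis.

Reverse transcription through a residual crosslinked peptide introduces
mutations — chiefly deletions — at the protein contact base, so recurrent
mutations pinpoint binding at single-nucleotide resolution.  Each mutation
subtype (substitution, deletion, insertion) is analyzed independently:

1. events at the same (chrom, strand, position) are clustered;
2. each cluster is tested with an inclusive binomial upper tail
   P(X >= a | y, p), where a is the mutation count, y the coverage at the
   position, and p the genome-wide per-base rate of that subtype,
   estimated as (total events) / (admitted reads x read length);
3. clusters on homopolymer runs (>= 5 identical bases by default, a known
   sequencing artifact) or supported by fewer than 3 distinct read start
   positions (a PCR-amplification guard) are removed;
4. p-values are Benjamini-Hochberg adjusted per subtype (after
   filtering), clusters with q <= 0.05 are ranked, the top 500 kept, and
   each site is extended +-15 bp for downstream motif discovery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .io import revcomp, write_fasta
from .stats import bh_adjust, binomial_tail_pvalue

log = logging.getLogger("clippeak")

DEFAULT_FLANK = 10
DEFAULT_REPEAT_MIN = 5
DEFAULT_MIN_UNIQUE = 3
DEFAULT_TOP_N = 500
DEFAULT_BH_MAX = 0.05
DEFAULT_SITE_EXT = 15

CLUSTER_COLUMNS = [
    "chrom", "position", "strand", "subtype", "a", "y", "unique_supports", "p_value",
]


def estimate_mutation_rate(events: pd.DataFrame, n_reads: int, read_length: int) -> dict[str, float]:
    """Genome-wide per-base mutation rate per subtype.

    rate = (number of events of the subtype) / (n_reads * read_length).
    Subtypes with zero events get rate 0 and are skipped by the test.
    """
    if n_reads <= 0 or read_length <= 0:
        raise DataError("n_reads and read_length must be positive")
    denom = float(n_reads) * float(read_length)
    counts = events.groupby("subtype").size() if len(events) else pd.Series(dtype=int)
    rates = {}
    for subtype in ("substitution", "deletion", "insertion"):
        rates[subtype] = float(counts.get(subtype, 0)) / denom
        if rates[subtype] == 0.0:
            log.info("no %s events: subtype will not be tested", subtype)
    return rates


def cluster_events(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse events sharing (chrom, strand, subtype, position) into clusters.

    ``a`` is the number of supporting reads, ``unique_supports`` the number
    of distinct read start positions among them (PCR-duplicate guard).
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["chrom", "position", "strand", "subtype", "a", "unique_supports"])
    grouped = (
        events.groupby(["chrom", "position", "strand", "subtype"], sort=True)
        .agg(a=("read_id", "size"), unique_supports=("read_start", "nunique"))
        .reset_index()
    )
    return grouped


def score_clusters(clusters: pd.DataFrame, coverage: np.ndarray, rates: dict[str, float]) -> pd.DataFrame:
    """Attach coverage y and the binomial upper-tail p-value to each cluster."""
    out = clusters.copy()
    out["y"] = np.asarray(coverage, dtype=np.int64)
    if np.any(out["a"].to_numpy() > out["y"].to_numpy()):
        raise DataError("cluster mutation count exceeds coverage; coverage must count deletion-spanning reads")
    pvals = np.ones(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        p = rates.get(row.subtype, 0.0)
        if p <= 0.0:
            pvals[i] = np.nan  # subtype not testable
        else:
            pvals[i] = binomial_tail_pvalue(int(row.a), int(row.y), p)
    out["p_value"] = pvals
    out = out[~out["p_value"].isna()].reset_index(drop=True)
    return out[CLUSTER_COLUMNS]


def _runs(seq: str, unit: int = 1):
    """Maximal tandem runs of a repeat unit of length ``unit`` in seq.

    Yields (start_offset, end_offset, n_repeats).  unit=1 gives plain
    homopolymer runs.
    """
    n = len(seq)
    i = 0
    while i + unit <= n:
        u = seq[i : i + unit]
        if "N" in u.upper():
            i += 1
            continue
        j = i + unit
        while j + unit <= n and seq[j : j + unit] == u:
            j += unit
        reps = (j - i) // unit
        if reps > 1 or unit == 1:
            yield i, i + reps * unit, reps
        i = i + unit if reps == 1 else j


def _on_tandem_repeat(genome, chrom: str, position: int, flank: int, repeat_min: int,
                      units=(1,)) -> bool:
    """True when a tandem run of >= repeat_min units overlaps ``position``.

    ``genome`` is a pyfaidx.Fasta (or mapping of chrom -> sequence).
    units=(1,) checks homopolymers only; add 2 and 3 for di-/tri-nucleotide
    tandems.
    """
    seq = str(genome[chrom][max(position - flank, 0): position + flank + 1]).upper()
    offset = max(position - flank, 0)
    for unit in units:
        for s, e, reps in _runs(seq, unit):
            if reps >= repeat_min and offset + s <= position < offset + e:
                return True
    return False


def filter_clusters(
    clusters: pd.DataFrame,
    genome,
    flank: int = DEFAULT_FLANK,
    repeat_min: int = DEFAULT_REPEAT_MIN,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    tandem_units=(1,),
) -> pd.DataFrame:
    """Remove artifact-prone clusters.

    Removed: clusters overlapping a tandem run of >= repeat_min
    identical units near the position (sequencing artifact), clusters
    with fewer than min_unique distinct supporting read starts (PCR
    bias), and clusters whose position falls outside the chromosome.
    Removal reasons are tallied in the log.
    """
    keep = np.ones(len(clusters), dtype=bool)
    reasons = {"tandem_repeat": 0, "few_unique_supports": 0, "outside_chromosome": 0}
    chrom_len = {c: len(genome[c]) for c in _genome_keys(genome)}
    for i, row in enumerate(clusters.itertuples(index=False)):
        if row.chrom not in chrom_len or not (0 <= row.position < chrom_len[row.chrom]):
            keep[i] = False
            reasons["outside_chromosome"] += 1
            continue
        if row.unique_supports < min_unique:
            keep[i] = False
            reasons["few_unique_supports"] += 1
            continue
        if _on_tandem_repeat(genome, row.chrom, int(row.position), flank, repeat_min, tandem_units):
            keep[i] = False
            reasons["tandem_repeat"] += 1
    for reason, n in reasons.items():
        if n:
            log.info("filter_clusters removed %d clusters: %s", n, reason)
    return clusters[keep].reset_index(drop=True)


def _genome_keys(genome):
    try:
        return list(genome.keys())
    except AttributeError:
        return list(genome)


def rank_and_select_sites(
    clusters: pd.DataFrame,
    genome=None,
    top_n: int = DEFAULT_TOP_N,
    bh_max: float = DEFAULT_BH_MAX,
    ext: int = DEFAULT_SITE_EXT,
    fasta_path=None,
) -> pd.DataFrame:
    """BH-adjust per subtype, keep q <= bh_max, rank, take the top_n.

    Ties are broken deterministically by (q, raw p, chrom, position).
    Site intervals are the position +-ext (2*ext+1 bp).  When ``genome``
    is given, strand-oriented site sequences are attached (and written as
    FASTA to ``fasta_path`` if set) for external motif tools; minus-strand
    sites are reverse-complemented since the motif is an RNA motif.
    """
    if len(clusters) == 0:
        log.info("rank_and_select_sites: empty input")
        return clusters.assign(bh_q=[], rank=[], site_start=[], site_end=[])
    parts = []
    for subtype, grp in clusters.groupby("subtype", sort=True):
        grp = grp.copy()
        grp["bh_q"] = bh_adjust(grp["p_value"].to_numpy())
        grp = grp[grp["bh_q"] <= bh_max]
        grp = grp.sort_values(
            ["bh_q", "p_value", "chrom", "position"], kind="mergesort"
        ).head(top_n)
        grp["rank"] = np.arange(1, len(grp) + 1)
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True) if parts else clusters.head(0)
    out["site_start"] = np.maximum(out["position"] - ext, 0)
    out["site_end"] = out["position"] + ext + 1

    if genome is not None and len(out):
        chrom_len = {c: len(genome[c]) for c in _genome_keys(genome)}
        seqs = []
        for row in out.itertuples(index=False):
            end = min(int(row.site_end), chrom_len[row.chrom])
            seq = str(genome[row.chrom][int(row.site_start): end]).upper()
            if row.strand == "-":
                seq = revcomp(seq)
            seqs.append(seq)
        out = out.assign(site_seq=seqs)
        if fasta_path is not None:
            records = [
                (
                    f"{r.chrom}:{r.site_start}-{r.site_end}:{r.strand}:{r.subtype}",
                    r.site_seq,
                )
                for r in out.itertuples(index=False)
            ]
            write_fasta(records, fasta_path)
    return out.reset_index(drop=True)
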