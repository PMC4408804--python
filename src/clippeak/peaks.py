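"""Window peak calling: dynamic Poisson background x NB regression.

Each 150-bp exon window i carries a CLIP count x_i (strand-specific) and
an RNA-seq count r_i (both strands combined, used as the matching
control).  Two background models are combined:

* a *dynamic Poisson* whose mean for window i is the maximum of locally
  estimated per-base RNA-seq rates — over each gene the window belongs
  to, each extended exon containing it, and its surrounding exon island —
  rescaled to the window length.  Taking the maximum deliberately errs
  conservative where local expression varies;
* a *negative-binomial regression* of CLIP on log RNA-seq fitted globally
  over all exon windows, capturing the CLIP/RNA-seq relatedness and the
  overdispersion of CLIP given RNA-seq.

Both yield strict upper tails P(X > x_i); their product is the combined
p-value used for ranking.  Windows whose number of distinct read start
positions does not exceed the genome-wide third quartile are excluded
before ranking (PCR-artifact guard); the top 2000 windows are retained
and the top 500 are extended +-100 bp for motif discovery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import WindowUniverse
from .errors import DataError
from .io import revcomp, write_fasta
from .nbfit import NBRegressionFit, fit_nb_regression
from .stats import nb_tail, poisson_tail, product_pvalue

log = logging.getLogger("clippeak")

DEFAULT_TOP_N = 2000
DEFAULT_TOP_M = 500
DEFAULT_PEAK_EXT = 100


def normalize_rnaseq(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Scale RNA-seq window counts onto the CLIP scale.

    s = (total CLIP reads in exon windows) / (total RNA-seq reads in exon
    windows); r_i = raw_rnaseq_i * s.  Returns (table with column
    ``rnaseq_norm``, s).
    """
    clip_total = float(table["clip_count"].sum())
    rna_total = float(table["rnaseq_count"].sum())
    if rna_total <= 0:
        raise DataError("total RNA-seq count over exon windows is zero")
    s = clip_total / rna_total
    out = table.copy()
    out["rnaseq_norm"] = out["rnaseq_count"] * s
    return out, s


def _membership(universe: WindowUniverse, extended_exons: pd.DataFrame) -> pd.DataFrame:
    """(window_idx, gene_id, exon_idx) rows for every window/exon overlap."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for exon_idx, row in enumerate(extended_exons.itertuples(index=False)):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, (row.gene_id, exon_idx)
        )
    rows = []
    for widx, w in enumerate(universe.windows):
        iv = w.interval
        tree = trees.get((iv.chrom, iv.strand))
        if tree is None:
            raise DataError(f"window {w.window_id} has no parent exon records")
        hits = tree.overlap(iv.start, iv.end)
        if not hits:
            raise DataError(f"window {w.window_id} overlaps no extended exon")
        for h in hits:
            gene_id, exon_idx = h.data
            rows.append((widx, gene_id, exon_idx))
    return pd.DataFrame(rows, columns=["window_idx", "gene_id", "exon_idx"])


def estimate_background(
    universe: WindowUniverse,
    table: pd.DataFrame,
    extended_exons: pd.DataFrame,
    floor_one_read_per_island: bool = True,
) -> np.ndarray:
    """Dynamic Poisson mean per window, on the count scale.

    Per-base rates are (normalized RNA-seq counts summed over member
    windows) / (summed member window length), computed per gene, per
    extended exon, and per island; the window's rate is the maximum of
    all applicable rates, multiplied by the window's own length.  The
    rate is floored at 1 normalized read per island to avoid a zero
    background where RNA-seq is locally silent.
    """
    if "rnaseq_norm" not in table.columns:
        raise DataError("run normalize_rnaseq first")
    r = table["rnaseq_norm"].to_numpy(dtype=float)
    lengths = np.array([w.length for w in universe.windows], dtype=float)

    # island rates
    island_ids = [w.island_id for w in universe.windows]
    df = pd.DataFrame({"island_id": island_ids, "r": r, "length": lengths})
    isl = df.groupby("island_id").agg(r_sum=("r", "sum"), len_sum=("length", "sum"))
    isl["rate"] = isl["r_sum"] / isl["len_sum"]
    island_rate = df["island_id"].map(isl["rate"]).to_numpy()
    island_len = df["island_id"].map(isl["len_sum"]).to_numpy()

    # gene and exon rates through the membership table
    mem = _membership(universe, extended_exons)
    mem["r"] = r[mem["window_idx"].to_numpy()]
    mem["length"] = lengths[mem["window_idx"].to_numpy()]

    gene = mem.groupby("gene_id").agg(r_sum=("r", "sum"), len_sum=("length", "sum"))
    gene["rate"] = gene["r_sum"] / gene["len_sum"]
    mem["gene_rate"] = mem["gene_id"].map(gene["rate"])

    exon = mem.groupby("exon_idx").agg(r_sum=("r", "sum"), len_sum=("length", "sum"))
    exon["rate"] = exon["r_sum"] / exon["len_sum"]
    mem["exon_rate"] = mem["exon_idx"].map(exon["rate"])

    per_window = mem.groupby("window_idx")[["gene_rate", "exon_rate"]].max()
    n = len(universe)
    gene_rate = np.zeros(n)
    exon_rate = np.zeros(n)
    gene_rate[per_window.index.to_numpy()] = per_window["gene_rate"].to_numpy()
    exon_rate[per_window.index.to_numpy()] = per_window["exon_rate"].to_numpy()

    rate = np.maximum.reduce([gene_rate, exon_rate, island_rate])
    if floor_one_read_per_island:
        rate = np.maximum(rate, 1.0 / island_len)
    return rate * lengths


def call_peaks(
    universe: WindowUniverse,
    table: pd.DataFrame,
    extended_exons: pd.DataFrame,
    fit: NBRegressionFit | None = None,
    top_n: int = DEFAULT_TOP_N,
    top_m: int = DEFAULT_TOP_M,
    ext: int = DEFAULT_PEAK_EXT,
    min_fit_windows: int = 200,
    allow_poisson_only: bool = False,
    calibrated: bool = False,
    genome=None,
    fasta_path=None,
) -> tuple[pd.DataFrame, NBRegressionFit | None, dict]:
    """Full peak stage on a window count table.

    ``table`` needs columns window_id, clip_count, rnaseq_count,
    unique_positions, aligned with ``universe``.  Returns
    (ranked peaks, NB fit, info dict with s, lambda, quartile cutoff).
    """
    table, s = normalize_rnaseq(table)
    lam = estimate_background(universe, table, extended_exons)
    x = table["clip_count"].to_numpy(dtype=np.int64)
    r = table["rnaseq_norm"].to_numpy(dtype=float)

    if fit is None:
        try:
            fit = fit_nb_regression(x, r, min_windows=min_fit_windows)
        except DataError:
            fit = None
        if fit is not None and not fit.converged:
            fit = None
        if fit is None and not allow_poisson_only:
            raise DataError(
                "NB regression did not converge; rerun with allow_poisson_only to proceed"
            )

    p_pois = np.array([poisson_tail(int(xi), li) for xi, li in zip(x, lam)])
    if fit is not None:
        mu = fit.mu(r)
        p_nb = np.empty(len(x))
        for i, (xi, mi) in enumerate(zip(x, mu)):
            p_nb[i] = nb_tail(int(xi), float(mi), fit.alpha)
    else:
        p_nb = np.ones(len(x))

    full = universe.to_frame()
    full["clip_count"] = x
    full["rnaseq_norm"] = r
    full["unique_positions"] = table["unique_positions"].to_numpy()
    full["lambda"] = lam
    full["p_poisson"] = p_pois
    full["p_nb"] = p_nb
    full["p_combined"] = product_pvalue(p_pois, p_nb, calibrated=calibrated)

    q3 = float(np.percentile(full["unique_positions"].to_numpy(), 75))
    kept = full[full["unique_positions"] > q3].copy()
    kept = kept.sort_values(
        ["p_combined", "chrom", "start"], kind="mergesort"
    ).head(top_n)
    kept["rank"] = np.arange(1, len(kept) + 1)
    kept["ext_start"] = np.maximum(kept["start"] - ext, 0)
    kept["ext_end"] = kept["end"] + ext

    info = {"s": s, "unique_positions_q3": q3, "n_windows": len(full),
            "n_after_quartile_filter": int((full["unique_positions"] > q3).sum())}

    if genome is not None and fasta_path is not None and len(kept):
        chrom_len = {c: len(genome[c]) for c in genome.keys()}
        records = []
        for row in kept.head(top_m).itertuples(index=False):
            end = min(int(row.ext_end), chrom_len[row.chrom])
            seq = str(genome[row.chrom][int(row.ext_start): end]).upper()
            if row.strand == "-":
                seq = revcomp(seq)
            records.append((f"{row.chrom}:{row.ext_start}-{row.ext_end}:{row.strand}:{row.window_id}", seq))
        write_fasta(records, fasta_path)

    return kept.reset_index(drop=True), fit, info


def enrichment_score(
    peaks: pd.DataFrame, partition: pd.DataFrame
) -> pd.DataFrame:
    """Peak enrichment per transcript region class (5'UTR / CDS / 3'UTR).

    score(region) = n_peaks_in_region / (total region length / n_genes),
    with peaks assigned by window midpoint.  ``partition`` rows:
    (region_type, chrom, start, end, strand, gene_id).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in partition.itertuples(index=False):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, row.region_type
        )
    counts: dict[str, int] = {}
    for row in peaks.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        tree = trees.get((row.chrom, row.strand))
        if tree is None:
            continue
        hits = tree.overlap(mid, mid + 1)
        for h in hits:
            counts[h.data] = counts.get(h.data, 0) + 1

    rows = []
    for region_type, grp in partition.groupby("region_type", sort=True):
        total_len = int((grp["end"] - grp["start"]).sum())
        n_genes = grp["gene_id"].nunique()
        n_peaks = counts.get(region_type, 0)
        if total_len == 0 or n_genes == 0:
            log.warning("region class %s has zero length: score undefined", region_type)
            score = np.nan
        else:
            score = n_peaks / (total_len / n_genes)
        rows.append((region_type, n_peaks, total_len, n_genes, score))
    return pd.DataFrame(
        rows, columns=["region_type", "n_peaks", "total_length", "n_genes", "enrich_score"]
    )
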