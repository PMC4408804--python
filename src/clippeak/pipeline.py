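"""End-to-end orchestration with a config object, plus concordance reports.

``run_pipeline`` chains annotation -> ingest -> {CIMS, peaks, miRNA} and
writes every table with the configuration hash, so a rerun on identical
inputs is byte-identical.  Outputs are assembled in a work subdirectory
and promoted to the output directory only when the run succeeds; on a
stage failure the partial outputs stay quarantined under
``<outdir>/quarantine``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import annotation as ann
from . import cims as cims_mod
from . import ingest, peaks as peaks_mod
from .errors import ClippeakError, ConfigError, DataError, StageError
from .io import chrom_sizes, config_hash, read_annotation, read_bed6, write_bed6, write_tsv
from .mirna import score_mirna_regions
from .stats import binomial_tail_pvalue

log = logging.getLogger("clippeak")


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; defaults mirror the method."""

    genome: str = ""
    annotation: str = ""
    mirna_bed: str = ""
    clip_bams: list = field(default_factory=list)
    rnaseq_bam: str = ""
    outdir: str = "clippeak_out"

    window_width: int = ann.DEFAULT_WINDOW
    ext5: int = ann.DEFAULT_EXT5
    ext3: int = ann.DEFAULT_EXT3
    mirna_ext: int = ann.DEFAULT_MIRNA_EXT
    cims_top: int = cims_mod.DEFAULT_TOP_N
    cims_ext: int = cims_mod.DEFAULT_SITE_EXT
    peak_top: int = peaks_mod.DEFAULT_TOP_N
    peak_top_fasta: int = peaks_mod.DEFAULT_TOP_M
    peak_ext: int = peaks_mod.DEFAULT_PEAK_EXT
    bh_max: float = cims_mod.DEFAULT_BH_MAX
    repeat_min: int = cims_mod.DEFAULT_REPEAT_MIN
    min_unique: int = cims_mod.DEFAULT_MIN_UNIQUE
    cims_flank: int = cims_mod.DEFAULT_FLANK
    min_mapq: int = ingest.DEFAULT_MIN_MAPQ
    read_length: int | None = None   # None: modal admitted read length
    mirna_min_regions: int = 20
    allow_partial: bool = False
    allow_poisson_only: bool = False
    calibrated_combination: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hashable_dict(self) -> dict:
        """Parameters plus input file names; where the files live and where
        outputs go does not change what the run computes."""
        d = self.to_dict()
        d.pop("outdir")
        for key in ("genome", "annotation", "mirna_bed", "rnaseq_bam"):
            d[key] = Path(d[key]).name if d[key] else ""
        d["clip_bams"] = [Path(p).name for p in d["clip_bams"]]
        return d

    def hash(self) -> str:
        return config_hash(self.hashable_dict())

    def validate(self):
        if not self.clip_bams:
            raise ConfigError("at least one CLIP alignment file is required")
        required = [self.genome, self.annotation, *self.clip_bams]
        if self.mirna_bed:
            required.append(self.mirna_bed)
        if self.rnaseq_bam:
            required.append(self.rnaseq_bam)
        for p in required:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not self.rnaseq_bam and not self.allow_partial:
            raise ConfigError(
                "no RNA-seq control: the peak stage cannot run (set allow_partial "
                "to run CIMS and miRNA stages only)"
            )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns {frames, paths, metadata}."""
    cfg.validate()
    chash = cfg.hash()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    work = outdir / "quarantine"
    if work.exists():
        shutil.rmtree(work)
    work.mkdir()
    header = f"clippeak config_hash={chash}"

    try:
        result = _run_stages(cfg, work, header)
    except ClippeakError:
        raise
    except Exception as e:  # unexpected stage crash
        raise StageError(f"pipeline stage failed: {e}") from e

    # promote outputs; quarantine dir disappears on success
    for item in sorted(work.iterdir()):
        target = outdir / item.name
        if target.exists():
            target.unlink()
        item.rename(target)
    work.rmdir()
    result["paths"] = {k: str(outdir / Path(v).name) for k, v in result["paths"].items()}
    return result


def _run_stages(cfg: PipelineConfig, work: Path, header: str) -> dict:
    genome = Fasta(cfg.genome)
    sizes = chrom_sizes(cfg.genome)
    exons = read_annotation(cfg.annotation)
    extended = ann.extend_gene_regions(exons, cfg.ext5, cfg.ext3, sizes)
    universe = ann.WindowUniverse.from_exons(extended, cfg.window_width)
    log.info("built %d islands, %d windows", len(universe.islands), len(universe))

    paths: dict[str, str] = {}
    frames: dict[str, pd.DataFrame] = {}
    meta: dict = {"config_hash": header.split("=", 1)[1], "config": cfg.hashable_dict()}

    wframe = universe.to_frame()
    bed = wframe.rename(columns={"window_id": "name"})[
        ["chrom", "start", "end", "name"]
    ].assign(score=0, strand=wframe["strand"])
    write_bed6(bed, work / "windows.bed", header)
    write_tsv(universe.islands_frame(), work / "islands.tsv", header)
    paths["windows"] = str(work / "windows.bed")
    paths["islands"] = str(work / "islands.tsv")

    # ---- ingest ------------------------------------------------------
    clip_bam = cfg.clip_bams[0]
    clip_tables = []
    reports = []
    for bam in cfg.clip_bams:
        t, rep = ingest.count_reads_in_windows(bam, universe, stranded=True, min_mapq=cfg.min_mapq)
        clip_tables.append(t)
        reports.append(rep)
    clip_table, clip_report = clip_tables[0], reports[0]

    counts = wframe.copy()
    counts["clip_count"] = clip_table["count"]
    counts["unique_positions"] = clip_table["unique_positions"]
    if cfg.rnaseq_bam:
        rna_table, rna_report = ingest.count_reads_in_windows(
            cfg.rnaseq_bam, universe, stranded=False, min_mapq=cfg.min_mapq
        )
        counts["rnaseq_count"] = rna_table["count"]
        meta["rnaseq_admitted"] = rna_report.admitted
    else:
        counts["rnaseq_count"] = 0
    meta["clip_admitted"] = clip_report.admitted
    meta["clip_dropped_outside_windows"] = clip_report.dropped_outside_windows
    write_tsv(counts, work / "window_counts.tsv", header)
    paths["window_counts"] = str(work / "window_counts.tsv")
    frames["window_counts"] = counts

    if len(cfg.clip_bams) > 1:
        rep_rows = []
        for i in range(len(clip_tables)):
            for j in range(i + 1, len(clip_tables)):
                rho = replicate_correlation(clip_tables[i], clip_tables[j])
                rep_rows.append((Path(cfg.clip_bams[i]).name, Path(cfg.clip_bams[j]).name, rho))
        rep_df = pd.DataFrame(rep_rows, columns=["replicate_a", "replicate_b", "pearson_log"])
        write_tsv(rep_df, work / "replicate_correlation.tsv", header)
        paths["replicate_correlation"] = str(work / "replicate_correlation.tsv")
        frames["replicate_correlation"] = rep_df

    # ---- CIMS --------------------------------------------------------
    events, ev_counters = ingest.extract_mutation_events(clip_bam, min_mapq=cfg.min_mapq)
    read_len = cfg.read_length or clip_report.modal_read_length()
    rates = cims_mod.estimate_mutation_rate(events, clip_report.admitted, read_len)
    meta["mutation_rates"] = rates
    meta["read_length_used"] = read_len
    clusters = cims_mod.cluster_events(events)
    tracks = ingest.coverage_tracks(clip_bam, min_mapq=cfg.min_mapq)
    cov = np.array(
        [
            int(tracks.get((r.chrom, r.strand), np.zeros(1, dtype=np.int32))[int(r.position)])
            if (r.chrom, r.strand) in tracks
            else 0
            for r in clusters.itertuples(index=False)
        ],
        dtype=np.int64,
    )
    tested = cims_mod.score_clusters(clusters, cov, rates)
    filtered = cims_mod.filter_clusters(
        tested, genome, flank=cfg.cims_flank, repeat_min=cfg.repeat_min,
        min_unique=cfg.min_unique,
    )
    sites = cims_mod.rank_and_select_sites(
        filtered, genome, top_n=cfg.cims_top, bh_max=cfg.bh_max, ext=cfg.cims_ext,
        fasta_path=work / "cims_sites.fasta",
    )
    write_tsv(tested, work / "cims_clusters.tsv", header)
    write_tsv(sites.drop(columns=["site_seq"], errors="ignore"), work / "cims_sites.tsv", header)
    if len(sites):
        site_bed = sites.rename(columns={"site_start": "start", "site_end": "end"})
        site_bed = site_bed.assign(name=site_bed["subtype"] + ":" + site_bed["rank"].astype(str),
                                   score=0)[["chrom", "start", "end", "name", "score", "strand"]]
        write_bed6(site_bed, work / "cims_sites.bed", header)
        paths["cims_sites_bed"] = str(work / "cims_sites.bed")
    paths["cims_clusters"] = str(work / "cims_clusters.tsv")
    paths["cims_sites"] = str(work / "cims_sites.tsv")
    paths["cims_fasta"] = str(work / "cims_sites.fasta")
    frames["cims_clusters"] = tested
    frames["cims_sites"] = sites

    # ---- peaks -------------------------------------------------------
    if cfg.rnaseq_bam:
        peak_df, fit, info = peaks_mod.call_peaks(
            universe, counts, extended,
            top_n=cfg.peak_top, top_m=cfg.peak_top_fasta, ext=cfg.peak_ext,
            allow_poisson_only=cfg.allow_poisson_only,
            calibrated=cfg.calibrated_combination,
            genome=genome, fasta_path=work / "peak_sites.fasta",
        )
        write_tsv(peak_df, work / "peaks.tsv", header)
        with np.errstate(divide="ignore"):
            score = np.minimum(-np.log10(np.maximum(peak_df["p_combined"], 1e-300)), 1000.0)
        peak_bed = peak_df.assign(name=peak_df["window_id"], score=score.round(2))[
            ["chrom", "start", "end", "name", "score", "strand"]
        ]
        write_bed6(peak_bed, work / "peaks.bed", header)
        fit_report = {
            "a": fit.a if fit else None,
            "b": fit.b if fit else None,
            "alpha": fit.alpha if fit else None,
            "se": fit.se if fit else None,
            "log_likelihood": fit.log_likelihood if fit else None,
            "normalization_s": info["s"],
            "unique_positions_q3": info["unique_positions_q3"],
            "n_windows": info["n_windows"],
            "n_after_quartile_filter": info["n_after_quartile_filter"],
            "config_hash": meta["config_hash"],
        }
        with open(work / "model_fit.json", "w") as fh:
            json.dump(fit_report, fh, indent=2, sort_keys=True)
        paths.update(
            peaks=str(work / "peaks.tsv"), peaks_bed=str(work / "peaks.bed"),
            peak_fasta=str(work / "peak_sites.fasta"), model_fit=str(work / "model_fit.json"),
        )
        frames["peaks"] = peak_df
        meta["model_fit"] = fit_report
    else:
        log.warning("no RNA-seq control: peak stage skipped (allow_partial)")

    # ---- miRNA regions -----------------------------------------------
    if cfg.mirna_bed:
        premirnas = read_bed6(cfg.mirna_bed)
        regions = ann.build_mirna_regions(premirnas, extended, cfg.mirna_ext, sizes)
        region_frame = ann.mirna_regions_frame(regions)
        if len(region_frame) >= cfg.mirna_min_regions:
            x = ingest.count_reads_in_regions(
                clip_bam, region_frame, stranded=True, min_mapq=cfg.min_mapq
            )
            mirna_df, mfit = score_mirna_regions(
                region_frame, x, min_regions=cfg.mirna_min_regions
            )
            write_tsv(mirna_df, work / "mirna_results.tsv", header)
            paths["mirna_results"] = str(work / "mirna_results.tsv")
            frames["mirna_results"] = mirna_df
            meta["mirna_fit"] = {"mu": mfit.mu, "alpha": mfit.alpha, "n": mfit.n}
        else:
            log.warning(
                "only %d miRNA regions survive (< %d): miRNA stage skipped",
                len(region_frame), cfg.mirna_min_regions,
            )
        mr_bed = region_frame.rename(columns={"mirna_name": "name"}).assign(score=0)[
            ["chrom", "start", "end", "name", "score", "strand"]
        ]
        write_bed6(mr_bed, work / "mirna_regions.bed", header)
        paths["mirna_regions"] = str(work / "mirna_regions.bed")
        frames["mirna_regions"] = region_frame

    with open(work / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    paths["metadata"] = str(work / "run_metadata.json")
    return {"frames": frames, "paths": paths, "metadata": meta}


def replicate_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame, log_transform: bool = True
) -> float:
    """Pearson correlation of per-window counts between two count tables.

    Computed on log(count + 1) by default; tables must share a window
    universe (joined on window_id).
    """
    col_a = "count" if "count" in table_a.columns else "clip_count"
    col_b = "count" if "count" in table_b.columns else "clip_count"
    merged = table_a[["window_id", col_a]].merge(
        table_b[["window_id", col_b]], on="window_id", suffixes=("_a", "_b")
    )
    if len(merged) == 0:
        raise DataError("window universes are disjoint: cannot correlate")
    a = merged.iloc[:, 1].to_numpy(dtype=float)
    b = merged.iloc[:, 2].to_numpy(dtype=float)
    if log_transform:
        a, b = np.log1p(a), np.log1p(b)
    if a.std() == 0 or b.std() == 0:
        raise DataError("degenerate (constant) counts: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _count_motif(seq: str, motif: str) -> int:
    """Overlapping occurrence count."""
    n, i = 0, seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def motif_count_report(
    site_seqs: list[str], motif: str, background_seqs: list[str]
) -> dict:
    """Motif frequency in site sequences vs length-matched background.

    Rates are occurrences per scannable position; the binomial comparison
    tests whether site occurrences exceed the background rate.
    """
    if not site_seqs:
        raise DataError("empty site sequence set")
    if any(len(motif) > len(s) for s in site_seqs + background_seqs):
        raise DataError("motif longer than some sequences")
    k = len(motif)
    site_occ = sum(_count_motif(s.upper(), motif) for s in site_seqs)
    site_pos = sum(len(s) - k + 1 for s in site_seqs)
    bg_occ = sum(_count_motif(s.upper(), motif) for s in background_seqs)
    bg_pos = sum(len(s) - k + 1 for s in background_seqs)
    site_rate = site_occ / site_pos if site_pos else 0.0
    bg_rate = bg_occ / bg_pos if bg_pos else 0.0
    degenerate = site_occ == 0 and bg_occ == 0
    ratio = site_rate / bg_rate if bg_rate > 0 else float("inf") if site_occ else float("nan")
    p = 1.0
    if not degenerate and bg_rate > 0:
        p = binomial_tail_pvalue(site_occ, site_pos, min(bg_rate, 1.0))
    return {
        "motif": motif,
        "site_occurrences": site_occ,
        "site_rate": site_rate,
        "background_occurrences": bg_occ,
        "background_rate": bg_rate,
        "rate_ratio": ratio,
        "p_value": p,
        "degenerate": degenerate,
        "mean_per_site_sequence": site_occ / len(site_seqs),
    }


def sample_background_sequences(
    genome, islands: pd.DataFrame, n: int, length: int, seed: int,
    exclude: pd.DataFrame | None = None,
) -> list[str]:
    """Length-matched background sequences from exon islands, avoiding sites.

    ``exclude`` rows need chrom/start/end (e.g. the called site table).
    """
    rng = np.random.default_rng([seed, 97])
    excl: dict[str, list[tuple[int, int]]] = {}
    if exclude is not None:
        for r in exclude.itertuples(index=False):
            excl.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    rows = islands.reset_index(drop=True)
    out: list[str] = []
    guard = 0
    while len(out) < n and guard < 100 * n:
        guard += 1
        row = rows.iloc[int(rng.integers(0, len(rows)))]
        if row.end - row.start <= length:
            continue
        s = int(rng.integers(row.start, row.end - length))
        if any(s < e2 and s2 < s + length for s2, e2 in excl.get(row.chrom, ())):
            continue
        out.append(str(genome[row.chrom][s : s + length]).upper())
    return out
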