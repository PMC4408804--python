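import pysam
import pytest

from clippeak.pipeline import PipelineConfig, run_pipeline
from clippeak.simulate import SimulationConfig, simulate_dataset

# Small-scale study conditions used throughout the unit tests; the
# acceptance tests use the full default SimulationConfig.
SMALL = dict(
    n_chromosomes=1,
    chromosome_length=250_000,
    n_genes=12,
    n_mirnas=22,
    mirnas_in_exon=1,
    clip_depth=20_000,
    rnaseq_depth=30_000,
    n_binding_sites=10,
)


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    kw = dict(SMALL)
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallsim")
    return simulate_dataset(small_config(), outdir)


def pipeline_config_for(gt, outdir, **overrides) -> PipelineConfig:
    kw = dict(
        genome=gt.paths["genome"],
        annotation=gt.paths["exons"],
        mirna_bed=gt.paths["premirnas"],
        clip_bams=[gt.paths["clip"]],
        rnaseq_bam=gt.paths["rnaseq"],
        outdir=str(outdir),
    )
    kw.update(overrides)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallrun")
    cfg = pipeline_config_for(small_dataset, outdir)
    return run_pipeline(cfg), cfg


def make_bam(path, records, chrom_sizes):
    """Write a sorted+indexed BAM from raw SAM body lines.

    ``records``: iterable of tab-joined SAM fields (no header).
    """
    sam = str(path) + ".sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in sorted(chrom_sizes.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for rec in records:
            fh.write(rec + "\n")
    pysam.sort("-o", str(path), sam)
    pysam.index(str(path))
    return str(path)


def sam_line(
    name, chrom, pos0, seq, cigar=None, strand="+", mapq=60, md=None, flag_extra=0
):
    """One SAM body line; pos0 is 0-based."""
    cigar = cigar or f"{len(seq)}M"
    md = md if md is not None else str(len(seq))
    flag = (16 if strand == "-" else 0) | flag_extra
    return (
        f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t"
        f"{seq}\t{'I' * len(seq)}\tMD:Z:{md}\tNM:i:0"
    )
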