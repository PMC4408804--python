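"""Self-contained synthetic HITS-CLIP fixtures with ground truth.

The generator realizes the statistical structure the pipeline assumes:

* a random genome carrying multi-exon genes on both strands and
  intergenic pre-miRNAs;
* unstranded RNA-seq window counts driven by per-gene lognormal
  expression (Poisson sampling);
* strand-specific CLIP window counts drawn negative-binomially around
  mu_i = exp(a_true + b_true * log(r_i + 1)), i.e. correlated with but
  overdispersed relative to RNA-seq, multiplied by a fold enrichment at
  planted binding sites;
* GGAG motifs planted in the genome at binding sites (reverse
  complemented for minus-strand sites so the RNA carries the motif);
* crosslink-induced deletions at the planted site position in a
  configured fraction of site-covering reads, on top of background
  substitution/deletion/insertion sequencing errors, SNP-like recurrent
  substitutions, and homopolymer decoys;
* truth tables for every planted signal.

Reads are single-end, fixed length, ungapped apart from the planted
mutations — emulating short nuclease-trimmed CLIP fragments without
modeling splicing.  Everything is reproducible byte-for-byte from the
seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import annotation as ann
from .errors import ConfigError
from .io import revcomp, write_bed6, write_fasta, write_tsv

log = logging.getLogger("clippeak")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_genes: int = 100
    exons_per_gene: int = 3
    exon_length: int = 500
    intron_length: int = 300
    n_mirnas: int = 30
    mirnas_in_exon: int = 0          # decoys that must be discarded downstream
    pre_mirna_length: int = 80
    mirna_hot_n: int = 2
    mirna_background_mean: float = 8.0
    mirna_hot_enrichment: float = 15.0
    rnaseq_depth: int = 300_000
    clip_depth: int = 200_000
    read_length: int = 36
    n_binding_sites: int = 100
    site_enrichment: float = 8.0
    # Per covering read at a bound site; fixed at 20x the per-base background
    # deletion rate.  The level is pinned by the study conditions: recovering
    # >= 90% of sites through the >=3-unique-mutation filter at coverage 30
    # needs P(Binom(30, rate) >= 3) >= 0.9, i.e. rate >= ~0.18.
    crosslink_deletion_rate: float = 0.2
    background_mutation_rates: dict = field(
        default_factory=lambda: {
            "substitution": 2e-3,
            "deletion": 1e-2,
            "insertion": 5e-4,
        }
    )
    snp_positions: int = 30
    snp_fractions: tuple = (0.5, 1.0)
    tandem_repeat_insertions: int = 30
    repeat_run_length: int = 8
    motif: str = "GGAG"
    motif_copies: int = 2
    expression_sigma: float = 0.75
    a_true: float = 1.0
    b_true: float = 0.8
    nb_dispersion: float = 0.3       # alpha_true; 0 -> Poisson CLIP counts
    window_width: int = ann.DEFAULT_WINDOW
    ext5: int = ann.DEFAULT_EXT5
    ext3: int = ann.DEFAULT_EXT3

    def validate(self):
        for name, rate in self.background_mutation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"background rate {name}={rate} outside [0, 1]")
        if not 0.0 <= self.crosslink_deletion_rate <= 1.0:
            raise ConfigError("crosslink_deletion_rate outside [0, 1]")
        if self.site_enrichment < 1.0:
            raise ConfigError("site_enrichment must be >= 1")
        if self.clip_depth <= 0 or self.rnaseq_depth <= 0:
            raise ConfigError("depths must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snp_fractions"] = list(self.snp_fractions)
        return d


@dataclass
class GenomeTruth:
    """In-memory product of genome/annotation simulation plus file paths."""

    config: SimulationConfig
    sequences: dict            # chrom -> bytearray
    exons: pd.DataFrame        # original (unextended) exon table
    premirnas: pd.DataFrame    # BED6 frame
    sites: pd.DataFrame        # planted binding sites
    snps: pd.DataFrame
    repeats: pd.DataFrame
    mirna_truth: pd.DataFrame
    partition: pd.DataFrame    # 5'UTR / CDS / 3'UTR per gene
    gene_expression: pd.DataFrame
    paths: dict = field(default_factory=dict)

    def sequence(self, chrom: str) -> str:
        return self.sequences[chrom].decode()


def _place_units(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes and pre-miRNAs on evenly spaced slots per chromosome."""
    gene_span = cfg.exons_per_gene * cfg.exon_length + (cfg.exons_per_gene - 1) * cfg.intron_length
    margin = max(cfg.ext5, cfg.ext3) + 1500
    units = []  # (kind, serial)
    units += [("gene", i) for i in range(cfg.n_genes)]
    units += [("mirna", i) for i in range(cfg.n_mirnas - cfg.mirnas_in_exon)]
    per_chrom = int(np.ceil(len(units) / cfg.n_chromosomes))
    slot = cfg.chromosome_length // (per_chrom + 1)
    if slot < gene_span + 2 * margin:
        raise ConfigError(
            f"regions don't fit: slot width {slot} < gene span {gene_span} + margins; "
            "increase chromosome_length or reduce gene count/size"
        )
    # deterministic interleave: miRNAs spread evenly among genes
    order = []
    n_g = cfg.n_genes
    n_m = cfg.n_mirnas - cfg.mirnas_in_exon
    step = max(n_g // max(n_m, 1), 1)
    gi = mi = 0
    while gi < n_g or mi < n_m:
        for _ in range(step):
            if gi < n_g:
                order.append(("gene", gi)); gi += 1
        if mi < n_m:
            order.append(("mirna", mi)); mi += 1

    exon_rows, mirna_rows = [], []
    for u, (kind, serial) in enumerate(order):
        chrom = f"chr{u % cfg.n_chromosomes + 1}"
        slot_idx = u // cfg.n_chromosomes
        base = (slot_idx + 1) * slot
        strand = "+" if (serial % 2 == 0) else "-"
        if kind == "gene":
            gid = f"gene{serial:04d}"
            for e in range(cfg.exons_per_gene):
                s = base + e * (cfg.exon_length + cfg.intron_length)
                exon_rows.append((chrom, s, s + cfg.exon_length, strand, gid))
        else:
            name = f"mir-{serial + 1:03d}"
            s = base + gene_span // 2
            mirna_rows.append((chrom, s, s + cfg.pre_mirna_length, name, 0, strand))
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    premirnas = pd.DataFrame(
        mirna_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return exons, premirnas


def simulate_genome_and_annotation(cfg: SimulationConfig, outdir) -> GenomeTruth:
    """Generate genome FASTA, annotation, pre-miRNA BED and truth tables."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 11])

    exons, premirnas = _place_units(cfg, rng)

    # decoy miRNAs placed inside an exon: must be discarded downstream
    decoy_rows = []
    if cfg.mirnas_in_exon > 0:
        genes = exons["gene_id"].unique()
        for i in range(cfg.mirnas_in_exon):
            g = exons[exons["gene_id"] == genes[i % len(genes)]].iloc[0]
            s = int(g.start) + 10
            decoy_rows.append(
                (g.chrom, s, s + cfg.pre_mirna_length, f"mir-exonic-{i:02d}", 0, g.strand)
            )
        premirnas = pd.concat(
            [premirnas, pd.DataFrame(decoy_rows, columns=premirnas.columns)],
            ignore_index=True,
        )

    sequences = {
        f"chr{i + 1}": bytearray(
            "".join(_BASES[rng.integers(0, 4, cfg.chromosome_length)]), "ascii"
        )
        for i in range(cfg.n_chromosomes)
    }
    chrom_sizes = {c: len(s) for c, s in sequences.items()}

    # windows are needed to pick site-hosting windows and intensities later
    extended = ann.extend_gene_regions(exons, cfg.ext5, cfg.ext3, chrom_sizes)
    universe = ann.WindowUniverse.from_exons(extended, cfg.window_width)

    expr = pd.DataFrame(
        {
            "gene_id": sorted(exons["gene_id"].unique()),
            "expression": rng.lognormal(0.0, cfg.expression_sigma, exons["gene_id"].nunique()),
        }
    )

    sites = _plant_sites(cfg, rng, universe, exons, expr, sequences)
    snps = _plant_snps(cfg, rng, exons, sites, sequences)
    repeats = _plant_repeats(cfg, rng, exons, sites, sequences)

    partition = _region_partition(cfg, exons, chrom_sizes)

    mirna_truth = premirnas.copy()
    hot = np.zeros(len(mirna_truth), dtype=bool)
    eligible = [i for i, n in enumerate(mirna_truth["name"]) if not n.startswith("mir-exonic")]
    hot_idx = rng.choice(eligible, size=min(cfg.mirna_hot_n, len(eligible)), replace=False)
    hot[np.sort(hot_idx)] = True
    mirna_truth["hot"] = hot
    mirna_truth["should_discard"] = mirna_truth["name"].str.startswith("mir-exonic")

    paths = {
        "genome": outdir / "genome.fa",
        "exons": outdir / "genes.tsv",
        "premirnas": outdir / "premirnas.bed",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_snps": outdir / "truth_snps.tsv",
        "truth_repeats": outdir / "truth_repeats.tsv",
        "truth_mirnas": outdir / "truth_mirnas.tsv",
        "partition": outdir / "truth_partition.tsv",
        "expression": outdir / "truth_expression.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_fasta(((c, bytes(s).decode()) for c, s in sorted(sequences.items())), paths["genome"])
    write_tsv(exons, paths["exons"])
    write_bed6(premirnas, paths["premirnas"])
    write_tsv(sites, paths["truth_sites"])
    write_tsv(snps, paths["truth_snps"])
    write_tsv(repeats, paths["truth_repeats"])
    write_tsv(mirna_truth, paths["truth_mirnas"])
    write_tsv(partition, paths["partition"])
    write_tsv(expr, paths["expression"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    return GenomeTruth(
        config=cfg,
        sequences=sequences,
        exons=exons,
        premirnas=premirnas,
        sites=sites,
        snps=snps,
        repeats=repeats,
        mirna_truth=mirna_truth,
        partition=partition,
        gene_expression=expr,
        paths={k: str(v) for k, v in paths.items()},
    )


def _plant_sites(cfg, rng, universe, exons, expr, sequences) -> pd.DataFrame:
    """Pick host windows in well-expressed genes and write motifs into the genome."""
    med = float(np.median(expr["expression"]))
    good_genes = set(expr.loc[expr["expression"] >= med, "gene_id"])
    gene_lookup = {}
    for row in exons.itertuples(index=False):
        gene_lookup.setdefault((row.chrom, row.strand), []).append((row.start, row.end, row.gene_id))

    def host_gene(w):
        for s, e, g in gene_lookup.get((w.interval.chrom, w.interval.strand), []):
            if w.interval.start < e and s < w.interval.end:
                return g
        return None

    def clean_context(chrom, site):
        # a crosslink planted on a homopolymer run >= 5 is removed by the
        # repeat filter no matter how strong the signal; such truth records
        # would be undetectable by construction, so site hosts avoid them
        lo = max(site - 12, 0)
        seq = bytes(sequences[chrom][lo : site + 13]).decode()
        run, prev = 1, ""
        for off, b in enumerate(seq):
            run = run + 1 if b == prev else 1
            prev = b
            if run >= 5 and lo + off - run + 1 <= site <= lo + off:
                return False
        return True

    eligible = []
    for i, w in enumerate(universe.windows):
        if w.length != cfg.window_width:
            continue
        g = host_gene(w)
        if g in good_genes and clean_context(
            w.interval.chrom, w.interval.start + cfg.window_width // 2
        ):
            eligible.append((i, g))
    if len(eligible) < cfg.n_binding_sites:
        raise ConfigError(
            f"only {len(eligible)} windows eligible to host {cfg.n_binding_sites} binding sites"
        )
    pick = rng.choice(len(eligible), size=cfg.n_binding_sites, replace=False)
    rows = []
    for j in np.sort(pick):
        widx, gene = eligible[j]
        w = universe.windows[widx]
        site = w.interval.start + cfg.window_width // 2
        motif = cfg.motif if w.interval.strand == "+" else revcomp(cfg.motif)
        k = len(cfg.motif)
        # motif copies flank the crosslink base so reads keep them intact
        offsets = [-(4 + k), 4]
        for c in range(min(cfg.motif_copies, len(offsets))):
            pos = site + offsets[c]
            sequences[w.interval.chrom][pos : pos + k] = motif.encode()
        rows.append(
            (
                w.interval.chrom, w.interval.strand, w.window_id,
                w.interval.start, w.interval.end, site, gene, cfg.site_enrichment,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "strand", "window_id", "window_start", "window_end",
                 "site_pos", "gene_id", "enrichment"],
    )


def _exonic_positions_away_from_sites(cfg, rng, exons, sites, n, min_dist=200):
    taken = [(r.chrom, r.site_pos) for r in sites.itertuples(index=False)]
    out = []
    ex = exons.reset_index(drop=True)
    guard = 0
    while len(out) < n and guard < 50 * n:
        guard += 1
        row = ex.iloc[int(rng.integers(0, len(ex)))]
        pos = int(rng.integers(row.start + 20, row.end - 20))
        if all(c != row.chrom or abs(pos - p) >= min_dist for c, p in taken):
            taken.append((row.chrom, pos))
            out.append((row.chrom, pos, row.strand))
    return out


def _plant_snps(cfg, rng, exons, sites, sequences) -> pd.DataFrame:
    rows = []
    for chrom, pos, strand in _exonic_positions_away_from_sites(
        cfg, rng, exons, sites, cfg.snp_positions
    ):
        ref = chr(sequences[chrom][pos])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        frac = float(rng.choice(np.asarray(cfg.snp_fractions)))
        rows.append((chrom, pos, strand, ref, alt, frac))
    return pd.DataFrame(rows, columns=["chrom", "position", "strand", "ref", "alt", "fraction"])


def _plant_repeats(cfg, rng, exons, sites, sequences) -> pd.DataFrame:
    rows = []
    for chrom, pos, strand in _exonic_positions_away_from_sites(
        cfg, rng, exons, sites, cfg.tandem_repeat_insertions
    ):
        base = str(rng.choice(list("ACGT")))
        run = base * cfg.repeat_run_length
        sequences[chrom][pos : pos + len(run)] = run.encode()
        rows.append((chrom, pos, pos + len(run), strand, base))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "base"])


def _region_partition(cfg, exons, chrom_sizes) -> pd.DataFrame:
    """5'UTR = 5' extension, CDS = annotated exons, 3'UTR = 3' extension."""
    rows = []
    for (gid, chrom, strand), grp in exons.groupby(["gene_id", "chrom", "strand"]):
        lo, hi = int(grp["start"].min()), int(grp["end"].max())
        if strand == "+":
            utr5 = (max(lo - cfg.ext5, 0), lo)
            utr3 = (hi, min(hi + cfg.ext3, chrom_sizes[chrom]))
        else:
            utr5 = (hi, min(hi + cfg.ext5, chrom_sizes[chrom]))
            utr3 = (max(lo - cfg.ext3, 0), lo)
        rows.append(("5UTR", chrom, utr5[0], utr5[1], strand, gid))
        rows.append(("3UTR", chrom, utr3[0], utr3[1], strand, gid))
        for r in grp.itertuples(index=False):
            rows.append(("CDS", chrom, int(r.start), int(r.end), strand, gid))
    return pd.DataFrame(
        rows, columns=["region_type", "chrom", "start", "end", "strand", "gene_id"]
    )


# ---------------------------------------------------------------------------
# read-level simulation


def _window_intensities(cfg: SimulationConfig, gt: GenomeTruth, universe):
    """Expected RNA-seq and CLIP counts per window from the truth model."""
    expr = dict(zip(gt.gene_expression["gene_id"], gt.gene_expression["expression"]))
    gene_lookup = {}
    for row in gt.exons.itertuples(index=False):
        gene_lookup.setdefault(row.chrom, []).append((row.start, row.end, row.gene_id))

    n = len(universe)
    r0 = np.zeros(n)
    for i, w in enumerate(universe.windows):
        iv = w.interval
        total = 0.0
        for s, e, g in gene_lookup.get(iv.chrom, []):
            # RNA-seq is unstranded: any overlapping gene contributes
            if iv.start < e + cfg.ext3 and s - cfg.ext3 < iv.end:
                total += expr[g]
        r0[i] = total * (w.length / cfg.window_width)
    r0 = np.maximum(r0, 1e-3)
    lam_rna = cfg.rnaseq_depth * r0 / r0.sum()

    mu0 = np.exp(cfg.a_true + cfg.b_true * np.log(lam_rna + 1.0))
    site_widx = np.array(
        [universe.window_index(wid) for wid in gt.sites["window_id"]], dtype=int
    )
    mu0[site_widx] *= gt.sites["enrichment"].to_numpy()
    mu_clip = cfg.clip_depth * mu0 / mu0.sum()
    return lam_rna, mu_clip, site_widx


def _build_read(ref_bytes: bytes, span_start: int, read_length: int, muts):
    """Construct (seq, cigar, md, nm, ref_consumed) for one read.

    ``muts``: list of (ref_offset, kind, payload) with offsets relative to
    ``span_start``; payload is the alt base for substitutions, the deleted
    length for deletions, and the inserted sequence for insertions
    (anchored after the base at the offset).  The query length is fixed at
    ``read_length``.
    """
    seq = []
    cig = []  # list of [op_char, length]
    md = []
    md_run = 0
    nm = 0
    subs = {o: p for o, k, p in muts if k == "substitution"}
    dels = {o: p for o, k, p in muts if k == "deletion"}
    inss = {o: p for o, k, p in muts if k == "insertion"}

    def add_cig(op, ln):
        if ln <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1][1] += ln
        else:
            cig.append([op, ln])

    qlen = 0
    rpos = 0  # offset into the reference span
    while qlen < read_length:
        if rpos in dels:
            d = dels.pop(rpos)
            md.append(str(md_run)); md_run = 0
            md.append("^" + ref_bytes[rpos : rpos + d].decode())
            add_cig("D", d)
            nm += d
            rpos += d
            continue
        base = chr(ref_bytes[rpos])
        if rpos in subs:
            alt = subs[rpos]
            seq.append(alt)
            md.append(str(md_run)); md_run = 0
            md.append(base)
            nm += 1
        else:
            seq.append(base)
            md_run += 1
        add_cig("M", 1)
        qlen += 1
        if rpos in inss and qlen < read_length:
            ins = inss[rpos]
            ins = ins[: read_length - qlen]
            seq.append(ins)
            add_cig("I", len(ins))
            nm += len(ins)
            qlen += len(ins)
        rpos += 1
    md.append(str(md_run))
    cigar = "".join(f"{ln}{op}" for op, ln in cig)
    return "".join(seq), cigar, "".join(md), nm, rpos


def _sample_background_muts(cfg, rng, read_length, forbidden):
    """Background mutation (offset, kind, payload) list for one read."""
    muts = []
    used = set(forbidden)
    for kind, rate in sorted(cfg.background_mutation_rates.items()):
        k = rng.binomial(read_length - 6, rate)
        for _ in range(k):
            for _try in range(10):
                o = int(rng.integers(2, read_length - 3))
                if o not in used and (o + 1) not in used and (o - 1) not in used:
                    used.add(o)
                    break
            else:
                continue
            if kind == "substitution":
                muts.append((o, kind, "SUB"))  # alt base resolved later against ref
            elif kind == "deletion":
                muts.append((o, kind, 1))
            else:
                muts.append((o, kind, str(rng.choice(list("ACGT")))))
    return muts


def simulate_reads(cfg: SimulationConfig, gt: GenomeTruth, outdir) -> dict:
    """Write sorted, indexed CLIP and RNA-seq BAMs realizing the truth model.

    Randomness is split in two streams.  The NB over-dispersion is a
    *biological* layer — per-window binding intensity around mu_i — keyed
    to the truth's seed, so replicate libraries simulated from the same
    truth share it and reproduce each other better than they track RNA-seq
    abundance.  Read sampling (Poisson counts, placement, sequencing
    errors) is *technical* and keyed to ``cfg.seed``: change it to obtain
    an independent replicate of the same biology.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 29])
    rng_bio = np.random.default_rng([gt.config.seed, 37])
    L = cfg.read_length

    chrom_sizes = {c: len(s) for c, s in gt.sequences.items()}
    extended = ann.extend_gene_regions(gt.exons, cfg.ext5, cfg.ext3, chrom_sizes)
    universe = ann.WindowUniverse.from_exons(extended, cfg.window_width)
    lam_rna, mu_clip, site_widx = _window_intensities(cfg, gt, universe)

    rna_counts = rng.poisson(lam_rna)
    if cfg.nb_dispersion > 0:
        lam_clip = rng_bio.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu_clip)
    else:
        lam_clip = mu_clip
    clip_counts = rng.poisson(lam_clip)

    site_of_window = {}
    for row in gt.sites.itertuples(index=False):
        site_of_window[universe.window_index(row.window_id)] = int(row.site_pos)
    snps_by_chrom = {}
    for row in gt.snps.itertuples(index=False):
        snps_by_chrom.setdefault(row.chrom, []).append(
            (int(row.position), row.alt, float(row.fraction))
        )

    clip_sam = outdir / "clip.unsorted.sam"
    rna_sam = outdir / "rnaseq.unsorted.sam"
    serial = 0

    def sam_header(fh):
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in sorted(chrom_sizes):
            fh.write(f"@SQ\tSN:{c}\tLN:{chrom_sizes[c]}\n")

    with open(clip_sam, "w") as fh:
        sam_header(fh)
        for widx, w in enumerate(universe.windows):
            c = int(clip_counts[widx])
            if c == 0:
                continue
            iv = w.interval
            site = site_of_window.get(widx)
            for _ in range(c):
                serial += 1
                # 5' ends spread across the window, as real CLIP fragments do;
                # only reads that happen to span the crosslink base can carry
                # the crosslink-induced deletion
                pos = int(rng.integers(iv.start, iv.end))
                if iv.strand == "+":
                    start = min(pos, chrom_sizes[iv.chrom] - 2 * L)
                else:
                    start = max(pos - L + 1, 0)
                _write_read(
                    fh, cfg, rng, gt, f"clip{serial:08d}", iv.chrom, start,
                    iv.strand, site, snps_by_chrom.get(iv.chrom, ()),
                )

    # CLIP reads over miRNA regions (strand-matched, no RNA-seq there)
    regions = ann.build_mirna_regions(gt.premirnas, extended, chrom_sizes=chrom_sizes)
    region_frame = ann.mirna_regions_frame(regions)
    with open(clip_sam, "a") as fh:
        for row in region_frame.itertuples(index=False):
            truth_row = gt.mirna_truth[gt.mirna_truth["name"] == row.mirna_name]
            hot = bool(truth_row["hot"].iloc[0]) if len(truth_row) else False
            mean = cfg.mirna_background_mean * (cfg.mirna_hot_enrichment if hot else 1.0)
            if cfg.nb_dispersion > 0:
                lam = float(rng_bio.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mean))
            else:
                lam = mean
            c = int(rng.poisson(lam))
            lo = max(int(row.pre_start) - 50, int(row.start))
            hi = min(int(row.pre_end) + 50, int(row.end))
            for _ in range(c):
                serial += 1
                p = int(rng.integers(lo, hi))
                start = p if row.strand == "+" else max(p - L + 1, 0)
                start = min(start, chrom_sizes[row.chrom] - 2 * L)
                _write_read(
                    fh, cfg, rng, gt, f"clip{serial:08d}", row.chrom, start,
                    row.strand, None, snps_by_chrom.get(row.chrom, ()),
                )

    serial = 0
    with open(rna_sam, "w") as fh:
        sam_header(fh)
        for widx, w in enumerate(universe.windows):
            c = int(rna_counts[widx])
            if c == 0:
                continue
            iv = w.interval
            for _ in range(c):
                serial += 1
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(iv.start, iv.end))
                if strand == "+":
                    start = min(pos, chrom_sizes[iv.chrom] - 2 * L)
                else:
                    start = max(pos - L + 1, 0)
                ref = bytes(gt.sequences[iv.chrom][start : start + L])
                flag = 0 if strand == "+" else 16
                fh.write(
                    f"rna{serial:08d}\t{flag}\t{iv.chrom}\t{start + 1}\t60\t{L}M\t*\t0\t0\t"
                    f"{ref.decode()}\t{'I' * L}\tMD:Z:{L}\tNM:i:0\n"
                )

    paths = {}
    for name, sam in (("clip", clip_sam), ("rnaseq", rna_sam)):
        bam = outdir / f"{name}.bam"
        # --no-PG keeps the header free of the input path: reruns must be
        # byte-identical
        pysam.sort("--no-PG", "-o", str(bam), str(sam))
        pysam.index(str(bam))
        sam.unlink()
        paths[name] = str(bam)
    return paths


def _write_read(fh, cfg, rng, gt, name, chrom, start, strand, site, snps):
    """Assemble one CLIP read with planted and background mutations."""
    L = cfg.read_length
    muts = []
    forbidden = []
    if site is not None:
        off = site - start
        if 0 <= off < L and rng.random() < cfg.crosslink_deletion_rate:
            muts.append((off, "deletion", 1))
        forbidden.append(off)
    for pos, alt, frac in snps:
        off = pos - start
        if 0 <= off < L and off not in forbidden and rng.random() < frac:
            muts.append((off, "substitution", alt))
            forbidden.append(off)
    muts.extend(_sample_background_muts(cfg, rng, L, forbidden))
    muts.sort(key=lambda m: m[0])

    span = bytes(gt.sequences[chrom][start : start + L + 8])
    resolved = []
    for o, kind, payload in muts:
        if kind == "substitution" and payload == "SUB":
            ref_base = chr(span[o])
            choices = [b for b in "ACGT" if b != ref_base]
            payload = choices[int(rng.integers(0, 3))]
        resolved.append((o, kind, payload))
    seq, cigar, md, nm, _ = _build_read(span, start, L, resolved)
    flag = 0 if strand == "+" else 16
    fh.write(
        f"{name}\t{flag}\t{chrom}\t{start + 1}\t60\t{cigar}\t*\t0\t0\t"
        f"{seq}\t{'I' * len(seq)}\tMD:Z:{md}\tNM:i:{nm}\n"
    )


def simulate_dataset(cfg: SimulationConfig, outdir) -> GenomeTruth:
    """Genome + annotation + reads in one call; paths collected on the truth."""
    gt = simulate_genome_and_annotation(cfg, outdir)
    gt.paths.update(simulate_reads(cfg, gt, outdir))
    return gt


# ---------------------------------------------------------------------------
# truth evaluation


def evaluate_against_truth(
    peaks: pd.DataFrame,
    cims_sites: pd.DataFrame,
    truth_sites: pd.DataFrame,
    match_tolerance: int = 10,
) -> dict:
    """Recovery report of pipeline output against the planted truth.

    * peak recall: fraction of planted site windows present in the ranked
      peak list (by window identity);
    * CIMS recall: fraction of planted crosslink positions with a selected
      deletion-subtype site within ``match_tolerance`` bp, with the median
      absolute positional error over recovered sites;
    * false-discovery tally among deletion CIMS calls.
    """
    peak_windows = set(peaks["window_id"]) if len(peaks) else set()
    dele = cims_sites[cims_sites["subtype"] == "deletion"] if len(cims_sites) else cims_sites

    per_site = []
    for row in truth_sites.itertuples(index=False):
        in_peaks = row.window_id in peak_windows
        dist = np.inf
        if len(dele):
            same = dele[(dele["chrom"] == row.chrom) & (dele["strand"] == row.strand)]
            if len(same):
                dist = int(np.min(np.abs(same["position"].to_numpy() - row.site_pos)))
        per_site.append((row.window_id, row.site_pos, in_peaks, dist))
    report = pd.DataFrame(
        per_site, columns=["window_id", "site_pos", "detected_in_peaks", "cims_distance"]
    )

    detected = report["cims_distance"] <= match_tolerance
    truth_pos = {
        (r.chrom, r.strand): [] for r in truth_sites.itertuples(index=False)
    }
    for r in truth_sites.itertuples(index=False):
        truth_pos[(r.chrom, r.strand)].append(r.site_pos)
    fd = 0
    for r in dele.itertuples(index=False):
        positions = truth_pos.get((r.chrom, r.strand), [])
        if not positions or np.min(np.abs(np.array(positions) - r.position)) > match_tolerance:
            fd += 1

    return {
        "n_truth_sites": int(len(report)),
        "peak_recall": float(report["detected_in_peaks"].mean()) if len(report) else 0.0,
        "cims_recall": float(detected.mean()) if len(report) else 0.0,
        "cims_median_distance": float(
            report.loc[detected, "cims_distance"].median()
        ) if detected.any() else float("nan"),
        "cims_false_discoveries": int(fd),
        "n_cims_deletion_calls": int(len(dele)),
        "per_site": report,
    }
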