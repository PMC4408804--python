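# Methods

`clippeak` identifies protein–RNA binding sites from HITS-CLIP
sequencing by two complementary routes — window-level peak calling
against an RNA-seq-informed background, and single-nucleotide
crosslink-induced mutation site (CIMS) analysis — plus a one-sample test
for miRNA precursor regions, where RNA-seq is not a valid control.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## Coordinate universe

Genes frequently lack UTR annotation, so each gene envelope is extended
200 bp at its 5′ end and 750 bp at its 3′ end (strand-aware; clipped at
chromosome bounds) before any counting.  Overlapping or book-ended
extended exons on the same strand are concatenated into disjoint *exon
islands*; adjacency is merged so windows never split at an artificial
seam.  Islands are tiled with consecutive 150-bp windows, the last
window of an island possibly shorter; the tiling is an exact partition.
Pre-miRNA intervals are extended ±1000 bp into putative pri-miRNA
regions, truncated at the boundary of any overlapping extended exon
(either strand — RNA-seq is unstranded, so exon-adjacent signal is
ambiguous regardless of strand), and a pre-miRNA that itself overlaps an
exon is discarded.  All coordinates are 0-based half-open; BED output
follows the same convention.

## Read handling

Admitted alignments are primary, mapped, and at mapping quality ≥ 10
(configurable).  A read belongs to the single window containing its 5′
end (leftmost aligned base for forward reads, rightmost for reverse
reads); this makes window counts sum-conserving — every admitted read is
in exactly one window or tallied as dropped.  CLIP libraries are
strand-specific, so CLIP counting requires read strand to match window
strand; RNA-seq counts combine both strands.  Per-window
`unique_positions` counts distinct admitted 5′ positions and feeds the
PCR-artifact guard below.

Coverage at a position counts reads whose aligned span (M/D/=/X
operations) includes it.  Reference bases deleted from a read count as
covered: the deletion evidence at a base comes from exactly those reads,
and excluding them could make the mutation count exceed coverage.

## CIMS model

Mutations are extracted per read from CIGAR + MD as three independent
subtypes (substitution, deletion, insertion).  A run of consecutive
mutated bases is one event at its first reference base; insertions
anchor at the reference base preceding the inserted sequence.  Events at
the same (chromosome, strand, position, subtype) form a cluster with
mutation count *a*, coverage *y* (strand-matched, since the library is
stranded), and `unique_supports` — the number of distinct read start
positions among supporting reads.

Each subtype's genome-wide per-base rate is

    p = (number of events of the subtype) / (admitted reads × read length)

with the read length taken from configuration or, by default, the modal
admitted read length.  A cluster is scored with the inclusive binomial
upper tail P(X ≥ a | y, p).  Two filters remove known artifacts before
multiple-testing adjustment: clusters overlapping a homopolymer run of
≥ 5 identical bases near the position (sequencing errors concentrate on
such runs; di-/tri-nucleotide tandem detection is available but off by
default, as the canonical artifact is the homopolymer), and clusters
with fewer than 3 unique supporting read starts (PCR amplification).
Benjamini–Hochberg adjustment is applied per subtype over the
filter-survivors; sites with q ≤ 0.05 are ranked (ties broken by raw p,
then coordinate — outputs are deterministic), the top 500 per subtype
kept, and each extended ±15 bp (31 nt) for motif discovery.  Site
sequences are strand-oriented (reverse-complemented on the minus strand)
because the recognized motif is an RNA motif.

Only positions with a ≥ 1 are tested.  This conditioning makes the
realized false-discovery proportion on strong-signal data exceed the
nominal q level (the tested family is enriched for non-null-looking
positions); under a full null, rejections remain at or below nominal, as
the calibration tests verify.

## Peak model

RNA-seq window counts are first scaled to the CLIP scale by
s = (total CLIP in exon windows)/(total RNA-seq in exon windows);
r_i = s · raw_i.

**Dynamic Poisson.**  Per-base background rates are estimated from the
normalized RNA-seq counts at three scopes: each gene the window overlaps
(sum of member-window counts over summed member-window length), each
extended exon containing it, and its exon island.  The window's rate is
the maximum of all applicable rates — deliberately conservative where a
window belongs to several genes or local expression varies — then
multiplied by the window's own length to give λ_i on the count scale.
Length adjustment enters through λ only: the observed count stays an
integer, since a Poisson pmf on length-normalized non-integer counts is
ill-defined.  Where RNA-seq is locally silent, the rate is floored at
one normalized read per island to avoid a zero-mean background with
infinite surprise.

**NB regression.**  Globally over all exon windows, CLIP counts follow
a negative binomial with log E(X | r) = a + b·log(r + 1) and variance
μ + αμ² (α → 0 is Poisson).  The pseudocount 1 handles r = 0 and is
configurable.  The likelihood is maximized directly over (a, b, log α)
with L-BFGS-B from three starts (a moment estimate of α, 0.1, and 1.0);
standard errors come from the finite-difference observed information,
with the delta method mapping se(log α) to se(α).  Convergence failure
aborts the run unless `allow_poisson_only` is set, in which case the NB
factor is 1.

**Combination.**  Both models give strict upper tails P(X > x_i); the
combined score is their product,

    p_combined(x_i) = P(X > x_i | λ_i) × P(X > x_i | r_i, a, b, α),

used as the ranking score.  Under independence the product's exact null
distribution is P(P₁P₂ ≤ c) = c·(1 − log c) (the two-test Fisher
combination on the product scale); `calibrated_combination` maps the
product through it when a calibrated p-value is wanted.  The plain
product is the default because it is conservative as a p-value (it is
≤ both factors) and the ranking is identical either way.

Before ranking, windows whose `unique_positions` does not strictly
exceed the third quartile across all windows are excluded.  The top 2000
windows are retained; the top 500 are extended ±100 bp and emitted as
FASTA for motif tools.  A per-region-class enrichment summary is
available:

    EnrichScore(region) = n_peaks_in_region / (region length / n_genes)

with peaks assigned by window midpoint over a 5′UTR/CDS/3′UTR partition.

## miRNA regions

Poly(A)-selected RNA-seq says nothing about miRNA loci, so extended
miRNA regions are scored one-sample: a single NB(μ, α) is fitted by
maximum likelihood to the strand-matched CLIP read totals of all
surviving regions (for this parameterization the MLE of μ is the sample
mean, so α is profiled in one dimension; a non-positive moment estimate
of α degenerates to Poisson).  Each region gets P(X > x | μ̂, α̂) and BH
adjustment over all regions.  Counts are raw totals; because truncation
makes regions unequal in length, a length-exposure offset is available
(`length_offset`) but off by default.  The fit requires ≥ 20 regions.

## Synthetic data

The generator produces a self-contained study: a random genome
(default 2 chromosomes × 500 kb) with 100 three-exon genes on both
strands, 30 intergenic pre-miRNAs, per-gene lognormal expression
(σ = 0.75), RNA-seq counts Poisson around expression-proportional window
intensities (300k reads), and CLIP counts negative-binomial
(α = 0.3) around μ_i = exp(a + b·log(r_i + 1)) with b = 0.8, scaled to
200k reads.  One hundred binding sites are planted in full-width windows
of genes above median expression, each with 8× fold enrichment, two GGAG
motifs flanking the crosslink base (reverse-complemented on minus-strand
sites so the transcript carries the motif), and a 1-bp deletion in 20%
of reads spanning the crosslink.  Background mutations are planted per
read at 2×10⁻³ (substitution), 10⁻² (deletion) and 5×10⁻⁴ (insertion)
per base; the crosslink deletion rate is thus 20× the background
deletion rate.  The absolute level is pinned by the study conditions
rather than free: surviving the ≥3-unique-mutation filter in ≥ 90% of
sites at coverage 30 requires P(Binom(30, rate) ≥ 3) ≥ 0.9, i.e. a
crosslink rate of at least ~0.18.  SNP-like recurrent substitutions
(50% or 100% of overlapping reads at 30 fixed positions) contaminate the
substitution channel, homopolymer runs of 8 are planted as repeat-filter
decoys, and sites are planted only at positions not already inside a
homopolymer run — a crosslink on such a run is removed by the filter by
construction and would make the truth table self-contradictory.

Randomness is split into two streams: the NB over-dispersion layer
(per-window binding intensity) is keyed to the truth's seed and shared
by all replicate libraries simulated from the same truth, while Poisson
sampling, read placement and sequencing errors are keyed to the
replicate's own seed.  This is what makes two replicates reproduce each
other better than either tracks RNA-seq abundance — with a single
stream the ordering provably inverts, since
corr(rep, rep) = s/(s+n) < √(s/(s+n)) ≈ corr(rep, RNA-seq) when the
mean structure is shared.

Reads are single-end, fixed 36 nt, ungapped apart from planted
mutations, with constant quality strings — emulating short
nuclease-trimmed CLIP fragments without splicing, sequencer error
profiles, or PCR-duplicate families.  MD/NM tags are written exactly, so
mutation extraction round-trips.  Everything is byte-reproducible from
the seed (`samtools sort --no-PG` keeps headers path-free).

**What passing tests show — and don't.**  The fixtures demonstrate that
the implementation recovers exactly the signal structure the models
assume: NB-distributed counts around a log-linear mean, point deletions
at crosslink sites, uniform background errors.  Real CLIP data add
splicing, mappability structure, non-uniform crosslinking efficiency,
sequence-dependent error rates, and PCR families; recovery rates on the
fixtures are statements about correctness of the machinery, not about
sensitivity on real libraries.

## Numerical and testing choices

* Tails use scipy's survival functions; tests compare them to
  independent brute-force series summation (exact binomial
  coefficients, log-gamma pmf terms) at relative error ≤ 10⁻⁸–10⁻¹⁰.
* The NB regression MLE is cross-checked against an independently
  implemented likelihood (statsmodels `NegativeBinomial`) and against
  Poisson regression in the α → 0 limit.
* BH adjustment is delegated to statsmodels' step-up implementation and
  checked against a hand-written step-up oracle.
* FDR-calibration simulations run at the count level (coverage and
  mutation counts drawn directly, the package's test and BH applied)
  rather than writing hundreds of alignment files; this isolates the
  statistical procedure and keeps 200-replicate runs to seconds.  Test
  problem sizes (default fixture for recovery, n = 10,000 for parameter
  recovery, 200 replicates for calibration) were chosen as the smallest
  scales at which the assertions are statistically stable.
* Degenerate inputs fail loudly: zero RNA-seq totals, all-zero miRNA
  counts, a > y clusters, empty interval, unindexed alignments.
* All rankings break ties deterministically (adjusted p, raw p,
  chromosome, coordinate), and every output file carries a hash of the
  run configuration (parameters plus input file names), so reruns on the
  same inputs are byte-identical.

## Known limitations

* Spliced (N-CIGAR) reads are handled for coverage but fragments are
  not reconstructed; soft-clip rescue and base-quality recalibration are
  out of scope.
* Substitution CIMS are contaminated by SNPs; the package flags no
  genotypes and relies on the subtype separation (deletions carry most
  crosslink information) as the mitigation.
* One CLIP replicate is the analysis unit; multi-replicate input
  produces per-replicate counts and a log-scale Pearson concordance
  report (window-identity based), not a joint model.
* The product combination is conservative as a p-value; calibrated
  output assumes independence of the two background models, which holds
  only approximately since both are estimated from the same RNA-seq.
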