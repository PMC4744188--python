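# Methods

This note documents the models, parameter choices, and numerical conventions
behind `rtscan`, and what the simulation-based validation does and does not
establish about real data.

## Gene models and gene sets

All transcripts of a gene are merged into a single model per gene: the exon
set is the interval union over transcripts, the gene interval the min/max
extent. Coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted at the boundary, BED12 is used as-is.

Read-through calling needs an unambiguous downstream zone, so two gene sets
are derived from the annotation:

* **Eligible genes** — no other annotated gene, on either strand, overlaps
  the 5-kb clear zone downstream of the TTS. Genes whose body overlaps
  another gene are also excluded, since their downstream windows would be
  ambiguous. The filter tests *any overlap* of a gene body with the zone
  (rather than, say, only gene starts falling in it); this is the stricter
  and deterministic reading. Zones truncated by a chromosome end are tested
  as truncated; genes whose truncated zone holds fewer windows than the
  calling rule needs are excluded with reason `truncated_zone`.
* **Tandem pairs** — for each gene, the nearest gene on the same chromosome
  *and strand* whose TSS lies 3' of the gene's TTS. Same-strand restriction
  is deliberate: invasion of and intergenic splicing into the downstream gene
  require co-directional transcription. The clear-zone filter, in contrast,
  considers neighbours on either strand.

## The read-through caller

Per gene and sample pair, coverage in the 4-kb zone downstream of the TTS is
summed in 100-bp windows, normalised to RPKM, and compared to the matched
control as a per-window fold change with a pseudocount (default 0.1 RPKM,
configurable; required to keep zero-control windows finite). A gene is called
when **more than six** windows (i.e. ≥ 7 of 40) show a fold change **of at
least** 1.5 — both thresholds read literally, `>= 1.5` inclusive and `> 6`
strict. Pre-filters, in order, with the first applicable reason recorded:

1. clear-zone eligibility (above);
2. activity: control gene-body RPKM strictly above the 25th percentile of
   the control distribution, computed over *all* annotated genes including
   zeros (the reference distribution is configurable because other choices —
   e.g. expressed genes only — are defensible);
3. truncated downstream zone;
4. overall expression increase: gene-body fold change ≥ 1.5 excludes the
   gene. No standard threshold exists for this exclusion; 1.5 mirrors the
   window threshold and is configurable and echoed into the run manifest.

**Read-through length** is the contiguous run of passing windows starting at
the TTS-proximal-most passing window (not the distal-most passing window);
the contiguous-run rule matches the physical picture of a decaying polymerase
wave and is what orders genes in the heatmap matrices.

The caller is deterministic — a thresholded count, not a statistical test —
and is scale-invariant to multiplying both samples' coverage and library
sizes by a common factor.

## Invasion and the correlation screen

For a called upstream gene with a tandem pair, the downstream gene body is
partitioned into 100-bp windows from its 5' end; the **invaded fraction** is
the length of the contiguous run of windows at fold change ≥ 1.5 *starting at
the first window*, divided by gene length (capped at 1). Elevation detached
from the gene's 5' end is not invasion: physical invasion is continuous with
the intergenic tail. The intergenic interval's fold change is reported
alongside; a zero-length intergenic interval yields a flagged undefined value.

The cohort screen correlates, per tandem pair across sample pairs, the
upstream gene's read-through level with the downstream gene's expression
change. Both quantities are log2 RPKM fold changes — the read-through level
over the 4-kb downstream zone (matching the heatmap quantity; using the
read-through length instead is exposed as an option), the expression change
over the downstream gene body. Spearman correlation is the default (robust to
fold-change outliers; Pearson is an option, and the choice is recorded in the
output). Pairs need ≥ 10 informative sample pairs by default (in the cohort
pipeline, a sample is informative for a pair when the upstream gene is called
in it); constant vectors are flagged and excluded from the multiple-testing
family. Benjamini–Hochberg step-up adjustment across all tested pairs defines
significance at q < 0.05.

## Chimera calling

Junction records (chrom, donor, acceptor, strand, read id; 0-based) support a
read-through chimera when the donor coordinate matches an exon 3' boundary of
the upstream gene and the acceptor an exon 5' boundary of the downstream gene
of the *same* tandem pair. A ±3 bp tolerance absorbs alignment jitter around
exon edges. Junction span must be ≥ 100 bp; reads are deduplicated by read id
per junction before counting, and ≥ 2 distinct reads are required per call.
Only cis, same-chromosome, same-strand tandem chimeras are in scope —
interchromosomal fusions arise by rearrangement, not termination failure.
Exon ranks are defined on the merged gene model (rank 1 = last exon of the
upstream gene counting from its 3' end; rank 1 = first exon of the downstream
gene), so alternative last exons collapse into the merged model's ranks.

## Cohort statistics

Samples with more than `cutoff` read-through genes (default 200) form the
'high' stratum, the rest 'low'; the boundary is strict (`201 → high`,
`200 → low`). Survival uses days and a 0/1 event flag; Kaplan–Meier curves
and the two-group log-rank test are computed via lifelines, with tied event
times handled by the standard hypergeometric variance. Fisher's exact test
(two-sided) serves categorical contrasts such as mutation-label vs stratum;
a zero margin returns p = 1 by convention. Metagene region comparisons use
Student's t-test, paired across genes to match the matched-pair design;
identical vectors return (t = 0, p = 1), a nonzero constant difference has
undefined variance and is flagged as NaN.

## Metagene profiles

Gene bodies are scaled to 60 equal bins (remainder bases joining the 3'-most
bin, assigned in transcription orientation so '+' and '-' genes mirror
exactly); ±4-kb flanks are averaged in 100-bp windows; all values are RPKM
per bin, log2-transformed with the pseudocount for matrix output. Profiles of
'-' genes are reversed so the TSS is always on the left. Heatmap matrices
order genes by descending read-through length.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with machine-
readable ground truth:

* **Annotation**: chains of genes per chromosome, log-normal gene lengths
  (median 10 kb, σ=0.4, min 2 kb), 2–10 exons per gene, log-normal intergenic
  gaps (median 8 kb), strand switching between consecutive genes with
  probability 0.2 (chains of co-directional genes), and a configurable
  fraction of genes (default 25%) placed with a < 5-kb downstream gap to
  exercise the clear-zone filter.
* **Coverage**: per-base Poisson counts around per-gene log-normal depths
  (median 50 reads/base, σ=0.6) over a near-zero intergenic background.
  The background default is 5×10⁻⁴ expected reads per base (≈ 0.05 per 100-bp
  window). This choice matters: intergenic RNA-seq coverage is effectively
  zero in real libraries, and with a substantially higher background the
  symmetric Poisson noise of paired null windows would cross the 1.5-fold
  threshold often enough to void the caller's specificity. At the default,
  the per-gene null call rate is well below 1%. Coverage is emitted as depth
  (bedGraph, one file per strand); the library size is defined as total depth
  bases divided by a nominal 100-bp read length, keeping RPKM well defined
  without BAM machinery.
* **Read-through tails**: planted on a fraction of eligible genes (default
  10%) that are deep enough to be detectable (depth ≥ 30) and safely above
  the activity percentile (5% margin — gene-body RPKM is proportional to
  depth, so genes at the activity boundary would be filtered, not missed).
  The tail adds ρ·depth·exp(−x/L_decay) to the test mean from the TTS
  (ρ = 0.8, L_decay = 2 kb), hard-truncated at a drawn tail length (uniform
  on 1–4 kb in 100-bp steps) so the ground-truth length is well defined.
  Gene-body means are untouched: planted calls are attributable to
  termination failure, not up-regulation, and the upstream region shows no
  difference by construction.
* **Invasion**: a subset of planted genes with a tandem pair (default 20%)
  get their tail extended across the whole intergenic gap (decaying but
  floored) and a constant elevation of (fc−1)·depth over the first
  `invaded_fraction_target` of the downstream gene (default 20% at 3-fold).
  Note that an invaded downstream gene which is itself planted will be
  excluded by the overall-increase filter — by design, and visible in the
  truth bookkeeping.
* **Chimeras**: each invaded pair emits Poisson(λ=3) junction reads at exon
  boundaries, with ranks drawn with 80% mass on (second-last exon → second
  exon) and uniform otherwise.
* **Survival**: exponential times (scale 1,000 days) with the hazard
  multiplied by 3 for samples whose true burden exceeds the stratification
  cutoff, administratively censored at 1,500 days. Sample-sheet mutation
  labels are drawn with P(mutant)=0.8/0.2 in the high/low strata, so Fisher
  contrasts have signal.

A single seed drives everything through per-sample `SeedSequence` substreams;
fixed seed gives byte-identical files.

### What the simulations do not show

The generator draws uniform coverage over whole gene bodies (no exonic
structure in coverage, no 3' bias, no mappability or GC structure), emits
depth rather than reads, uses independent controls rather than correlated
matched tissue, and plants clean exponential tails. Passing recovery tests
therefore validates the *logic and calibration* of the pipeline — thresholds,
orientation handling, normalisation, multiple-testing and survival machinery
— not its robustness to alignment artifacts, annotation errors, or biological
covariates in real libraries.

## Problem sizes and numerics

Validation runs use desk-scale problem sizes chosen to keep the full suite
fast while leaving the statistics well powered: a 1,000-gene genome with 100
planted tails for caller recovery; 2,000 replicates for log-rank null
calibration and 300 for power; 500 tandem pairs (50 coupled, 50 sample
pairs) for the screen; ≥ 50 measured pairs per planted fraction for invasion
recovery. Oracle-equivalence tests compare each primitive (interval union,
window counting, metagene binning, BH, Fisher, Kaplan–Meier) against an
independent brute-force implementation on 100 random small instances at
1e-9 tolerance. Floating-point boundary cases in threshold tests use a zero
pseudocount, since any positive pseudocount shifts an exact-ratio input off
the boundary.
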