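# rtscan

Detection and quantification of **transcription read-through** from paired
RNA-seq coverage.

Failure of RNA polymerase II to terminate at a gene's transcription
termination site (TTS) produces downstream-of-gene (DoG) transcripts that can
run across the intergenic region, invade the next gene of a tandem pair,
alter its expression, and generate read-through RNA chimeras by intergenic
splicing — all without any DNA rearrangement. `rtscan` implements a complete
desk-scale analysis of this phenomenon for cohorts of matched test/control
sample pairs (e.g. tumor and matched normal tissue), together with a
synthetic-data generator that plants known read-through signal so every stage
can be validated against ground truth.

## The core statistic

For each gene with a clear zone (no annotated gene on either strand within
5 kb downstream of the TTS), coverage in the 4-kb region past the TTS is
counted in 100-bp windows and normalised to RPKM
(reads per kilobase per million mapped reads):

```
RPKM = count / (L / 10^3) / (N / 10^6)
```

with `L` the window length and `N` the sample's total mapped reads. The
per-window fold change against the matched control is

```
fc_i = (RPKM_test,i + c) / (RPKM_ctrl,i + c),        c = 0.1 (pseudocount)
```

and a gene is called as showing transcription read-through when **more than
six** windows have `fc_i >= 1.5`. Calling is restricted to transcriptionally
active genes (control gene-body RPKM above the cohort's 25th percentile) and
genes *without* an overall gene-body expression increase, so that calls
reflect termination failure rather than up-regulation. The read-through
*length* is the contiguous run of passing windows nearest the TTS.

On top of the caller, the package provides:

* **Invasion quantification** — the fraction of the downstream tandem gene
  covered by a fold-change elevation continuous with its 5' end, plus
  intergenic and gene-body fold changes.
* **Correlation screen** — per tandem pair, Spearman correlation across
  sample pairs between the upstream gene's read-through level (log2 fold
  change over the 4-kb downstream zone) and the downstream gene's expression
  change, with Benjamini–Hochberg control at q < 0.05.
* **Chimera calling** — read-through RNA chimeras from split-read junction
  records: donor at an upstream exon 3' boundary, acceptor at a downstream
  exon 5' boundary of the same tandem pair, span ≥ 100 bp, at least two
  distinct supporting reads; events are classified by exon-pair pattern
  (e.g. `E[last-1]->E2`, the second-last exon spliced to the second exon).
* **Cohort statistics** — stratification into high/low read-through burden
  (default cutoff: more than 200 genes called), Kaplan–Meier curves and the
  log-rank test for survival, Fisher's exact test for categorical contrasts,
  and paired t-tests for metagene region comparisons.
* **Metagene profiles and heatmap matrices** — gene bodies scaled to 60 equal
  bins with ±4-kb flanks averaged in 100-bp windows, genes ordered by
  read-through length.

## Worked example

```python
from rtscan import (SimConfig, simulate_annotation, simulate_sample_pair,
                    profile_sample)

config = SimConfig(n_genes=200, readthrough_fraction=0.1, seed=11)
annotation = simulate_annotation(config, seed=11)
pair = simulate_sample_pair(annotation, config, seed=12,
                            sample_id="T01", control_id="N01")
profile = profile_sample(pair.test, pair.control, annotation)
print(f"genes annotated:        {len(annotation)}")
print(f"planted read-through:   {pair.truth.n_true_readthrough}")
print(f"called read-through:    {profile.n_readthrough_genes}")
call = profile.calls[sorted(profile.readthrough_gene_ids)[0]]
print(f"example call:           {call.gene_id}: {call.n_windows_above} windows above "
      f"1.5-fold, length {call.readthrough_length_bp} bp")
```

prints

```
genes annotated:        200
planted read-through:   11
called read-through:    11
example call:           G00003: 37 windows above 1.5-fold, length 3700 bp
```

All 11 planted tails are recovered and nothing else is called: the planted
tail of `G00003` decays exponentially from 0.8× the gene's depth over ~3.7 kb,
so 37 consecutive windows clear the 1.5-fold threshold and the estimated
read-through length matches the planted one.

The same analysis is available from the shell:

```sh
rtscan simulate --out cohort/ --seed 17 --n-samples 10
rtscan cohort --dir cohort/ --out results/ --cutoff 200
```

which writes per-sample call/invasion/chimera tables plus the cohort
aggregates (burden table, stratification, log-rank comparison, correlation
screen, chimera pattern histogram) under `results/`.

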