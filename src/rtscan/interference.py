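"""Transcriptional interference: downstream-gene invasion and the cohort correlation screen.

Read-through polymerases that cross the intergenic region can invade the gene
located immediately downstream (transcriptional interference). Two analyses
quantify this:

* per sample pair, the fraction of the downstream gene body covered by a
  contiguous fold-change elevation continuous with the gene's 5' end; and
* across a cohort of paired samples, a per-tandem-pair correlation between the
  upstream gene's read-through level (log2 fold change of coverage in the 4-kb
  zone past its TTS) and the downstream gene's expression change, with
  Benjamini-Hochberg control at q < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GenomeAnnotation, TandemPair
from .caller import CallerParams
from .coverage import (CoverageTrack, downstream_window_vector, fold_change_vector,
                       gene_body_expression, region_count, rpkm, window_counts)


@dataclass
class InvasionResult:
    pair: TandemPair
    intergenic_fc: float | None  # None when the intergenic interval is empty
    downstream_invaded_fraction: float
    downstream_body_fc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.downstream_invaded_fraction <= 1.0:
            raise ValueError("invaded fraction outside [0, 1]")


def _region_fc(test: CoverageTrack, control: CoverageTrack, chrom: str,
               start: int, end: int, strand: str, pseudocount: float) -> float:
    length = end - start
    t = rpkm(region_count(test, chrom, start, end, strand), length, test.total_mapped_reads)
    c = rpkm(region_count(control, chrom, start, end, strand), length, control.total_mapped_reads)
    return float((t + pseudocount) / (c + pseudocount))


def invasion_fraction(test: CoverageTrack, control: CoverageTrack, pair: TandemPair,
                      annotation: GenomeAnnotation, params: CallerParams | None = None) -> InvasionResult:
    """Quantify how far a read-through tail invades the downstream gene.

    The downstream gene body is partitioned into fixed windows from its 5' end;
    the invaded fraction is the length of the contiguous run of windows at or
    above the fold-change threshold *starting at the first window*, divided by
    the gene length. Elevation that does not begin at the gene's 5' end is not
    counted as invasion, since invasion is physically continuous with the
    intergenic tail.
    """
    if params is None:
        params = CallerParams()
    down = annotation.genes[pair.downstream_id]
    counts_t = window_counts(test, down.chrom, down.start, down.end, down.strand, params.window_bp)
    counts_c = window_counts(control, down.chrom, down.start, down.end, down.strand, params.window_bp)
    fc = ((rpkm(counts_t, params.window_bp, test.total_mapped_reads) + params.pseudocount)
          / (rpkm(counts_c, params.window_bp, control.total_mapped_reads) + params.pseudocount)
          ) if counts_t.size else np.zeros(0)
    run = 0
    while run < len(fc) and fc[run] >= params.fc_threshold:
        run += 1
    frac = min(1.0, run * params.window_bp / down.length) if down.length else 0.0

    ig_start, ig_end = pair.intergenic
    intergenic_fc = (_region_fc(test, control, pair.chrom, ig_start, ig_end,
                                pair.strand, params.pseudocount)
                     if ig_end > ig_start else None)
    body_fc = _region_fc(test, control, down.chrom, down.start, down.end,
                         down.strand, params.pseudocount)
    return InvasionResult(pair, intergenic_fc, frac, body_fc)


def readthrough_level(test: CoverageTrack, control: CoverageTrack, gene: GeneModel,
                      params: CallerParams | None = None) -> float:
    """log2 fold change of RPKM summed over the 4-kb zone downstream of the TTS."""
    if params is None:
        params = CallerParams()
    t = downstream_window_vector(test, gene, params.downstream_span_bp, params.window_bp)
    c = downstream_window_vector(control, gene, params.downstream_span_bp, params.window_bp)
    return float(np.log2((t.values.mean() + params.pseudocount)
                         / (c.values.mean() + params.pseudocount)))


def downstream_expression_change(test: CoverageTrack, control: CoverageTrack,
                                 gene: GeneModel, pseudocount: float = 0.1) -> float:
    """log2 gene-body RPKM fold change of the downstream gene."""
    return float(np.log2((gene_body_expression(test, gene) + pseudocount)
                         / (gene_body_expression(control, gene) + pseudocount)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(rt_levels: pd.DataFrame, expr_changes: pd.DataFrame,
                       method: str = "spearman", alpha: float = 0.05,
                       min_samples: int = 10) -> pd.DataFrame:
    """Per-tandem-pair correlation between read-through level and downstream expression.

    Parameters
    ----------
    rt_levels, expr_changes
        Aligned DataFrames (rows = tandem pairs, columns = sample pairs) of the
        upstream gene's read-through level and the downstream gene's expression
        change. NaN marks uninformative samples.
    method
        'spearman' (default, robust to fold-change outliers) or 'pearson'.
    min_samples
        Pairs with fewer informative samples are reported but flagged and
        excluded from the multiple-testing family.

    Returns
    -------
    DataFrame with columns pair, n, r, p, q, significant, direction, tested.
    """
    if not rt_levels.index.equals(expr_changes.index):
        raise ValueError("rt_levels and expr_changes must share the same pair index")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for pair_id in rt_levels.index:
        x = rt_levels.loc[pair_id].to_numpy(dtype=float)
        y = expr_changes.loc[pair_id].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        r = p = math.nan
        tested = False
        if n >= max(3, min_samples):
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                tested = False  # constant vector: correlation undefined
            else:
                res = corr(xs, ys)
                r, p = float(res.statistic), float(res.pvalue)
                tested = np.isfinite(p)
        rows.append({"pair": pair_id, "n": n, "r": r, "p": p, "tested": tested})
    df = pd.DataFrame(rows).set_index("pair")
    df["q"] = math.nan
    tested_mask = df["tested"].to_numpy()
    if tested_mask.any():
        df.loc[tested_mask, "q"] = bh_adjust(df.loc[tested_mask, "p"].to_numpy())
    df["significant"] = (df["q"] < alpha).fillna(False)
    df["direction"] = np.where(df["r"] > 0, "positive",
                               np.where(df["r"] < 0, "negative", "none"))
    return df


def correlate_readthrough_with_downstream_expression(
        sample_pairs: Mapping[str, tuple[CoverageTrack, CoverageTrack]],
        pairs: Sequence[TandemPair], annotation: GenomeAnnotation,
        params: CallerParams | None = None, method: str = "spearman",
        alpha: float = 0.05, min_samples: int = 10) -> pd.DataFrame:
    """Run the correlation screen directly from cohort coverage tracks.

    ``sample_pairs`` maps sample_id to its (test, control) tracks. For every
    tandem pair, the screen correlates the upstream gene's read-through level
    with the downstream gene's expression change across samples.
    """
    if params is None:
        params = CallerParams()
    index = [f"{p.upstream_id}|{p.downstream_id}" for p in pairs]
    samples = list(sample_pairs)
    rt = pd.DataFrame(index=index, columns=samples, dtype=float)
    ex = pd.DataFrame(index=index, columns=samples, dtype=float)
    for sid, (test, control) in sample_pairs.items():
        for p, key in zip(pairs, index):
            rt.loc[key, sid] = readthrough_level(test, control,
                                                 annotation.genes[p.upstream_id], params)
            ex.loc[key, sid] = downstream_expression_change(
                test, control, annotation.genes[p.downstream_id], params.pseudocount)
    return correlation_screen(rt, ex, method=method, alpha=alpha, min_samples=min_samples)
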