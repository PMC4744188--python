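"""Per-gene, per-sample-pair transcription read-through calling.

The call is a deterministic windowed rule on paired coverage: a gene shows
read-through when more than six of the 100-bp windows in the 4-kb zone
downstream of its TTS have an RPKM fold change of at least 1.5 over the
matched control. Before calling, genes are filtered for (i) a clear zone with
no annotated neighbour within 5 kb downstream of the TTS, (ii) transcriptional
activity in the control (gene-body RPKM above the 25th percentile), and
(iii) absence of an overall gene-body expression increase, so that calls
reflect termination failure rather than transcriptional up-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, downstream_interval, eligible_readthrough_genes
from .coverage import (CoverageTrack, WindowVector, downstream_window_vector,
                       fold_change_vector, gene_body_expression)

#: machine-readable reasons a gene was not considered for calling
EXCLUSION_REASONS = ("inactive", "neighbor_within_clear_zone", "overall_increase", "truncated_zone")


@dataclass
class CallerParams:
    """All thresholds of the read-through caller.

    Defaults implement: >6 windows of 100 bp at fold change >=1.5 within 4 kb
    downstream of the TTS, restricted to genes above the 25th expression
    percentile with a 5-kb clear zone and no overall expression increase.
    """

    downstream_span_bp: int = 4000
    window_bp: int = 100
    fc_threshold: float = 1.5
    min_windows_above: int = 7  # "more than six"
    active_percentile: float = 25.0
    clear_zone_bp: int = 5000
    overall_increase_fc: float = 1.5
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        for name in ("downstream_span_bp", "window_bp", "fc_threshold", "min_windows_above",
                     "clear_zone_bp", "overall_increase_fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not 0 <= self.active_percentile <= 100:
            raise ValueError("active_percentile must be in [0, 100]")
        if self.min_windows_above > self.downstream_span_bp // self.window_bp:
            raise ValueError("min_windows_above exceeds the number of windows")

    @property
    def n_windows(self) -> int:
        return self.downstream_span_bp // self.window_bp

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReadThroughCall:
    gene_id: str
    called: bool
    n_windows_above: int = 0
    readthrough_length_bp: int = 0
    mean_downstream_fc: float = float("nan")
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded_reason is not None and self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")
        if self.called and self.excluded_reason is not None:
            raise ValueError("a called gene cannot carry an exclusion reason")


@dataclass
class SampleReadthroughProfile:
    """All per-gene calls for one test/control sample pair."""

    sample_id: str
    control_id: str
    calls: dict[str, ReadThroughCall]

    @property
    def n_readthrough_genes(self) -> int:
        return sum(c.called for c in self.calls.values())

    @property
    def readthrough_gene_ids(self) -> set[str]:
        return {g for g, c in self.calls.items() if c.called}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [asdict(c) for _, c in sorted(self.calls.items())]
        df = pd.DataFrame(rows)
        df.insert(0, "sample_id", self.sample_id)
        df.insert(1, "control_id", self.control_id)
        return df


def active_gene_filter(expression: Mapping[str, float], percentile: float = 25.0) -> set[str]:
    """Genes strictly above the given percentile of the control expression distribution.

    The percentile (linear interpolation) is computed over all annotated genes,
    zeros included, in the control sample.
    """
    if not expression:
        raise ValueError("empty expression map")
    cutoff = float(np.percentile(np.fromiter(expression.values(), dtype=float), percentile))
    return {g for g, v in expression.items() if v > cutoff}


def readthrough_length(fc_vector: np.ndarray, params: CallerParams) -> int:
    """Length in bp of the contiguous passing run nearest the TTS.

    The run starts at the TTS-proximal-most window with fold change at or above
    the threshold and extends while consecutive windows keep passing; 0 when no
    window passes.
    """
    above = np.asarray(fc_vector) >= params.fc_threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0
    run = 1
    first = idx[0]
    while first + run < len(above) and above[first + run]:
        run += 1
    return run * params.window_bp


def call_gene_readthrough(test_wv: WindowVector, control_wv: WindowVector,
                          params: CallerParams) -> ReadThroughCall:
    """Apply the windowed fold-change rule to one gene's downstream zone."""
    fc = fold_change_vector(test_wv, control_wv, params.pseudocount)
    n_above = int(np.count_nonzero(fc >= params.fc_threshold))
    return ReadThroughCall(
        gene_id=test_wv.gene_id,
        called=n_above >= params.min_windows_above,
        n_windows_above=n_above,
        readthrough_length_bp=readthrough_length(fc, params),
        mean_downstream_fc=float(fc.mean()) if fc.size else float("nan"),
    )


def overall_increase_filter(test_expr: float, control_expr: float, params: CallerParams) -> bool:
    """True when the gene body shows an overall expression increase (gene excluded)."""
    fc = (test_expr + params.pseudocount) / (control_expr + params.pseudocount)
    return fc >= params.overall_increase_fc


def profile_sample(test: CoverageTrack, control: CoverageTrack,
                   annotation: GenomeAnnotation, params: CallerParams | None = None,
                   sample_id: str = "test", control_id: str = "control") -> SampleReadthroughProfile:
    """Call read-through for every annotated gene of one test/control pair.

    Filters are applied in order — clear-zone eligibility, activity in the
    control, truncated downstream zone, overall expression increase — and each
    excluded gene records the first reason that applied.
    """
    if params is None:
        params = CallerParams()
    eligible = eligible_readthrough_genes(annotation, params.clear_zone_bp)
    control_expr = {g.gene_id: gene_body_expression(control, g) for g in annotation}
    active = active_gene_filter(control_expr, params.active_percentile)

    calls: dict[str, ReadThroughCall] = {}
    for gene in annotation:
        gid = gene.gene_id
        if gid not in eligible:
            calls[gid] = ReadThroughCall(gid, False, excluded_reason="neighbor_within_clear_zone")
            continue
        if gid not in active:
            calls[gid] = ReadThroughCall(gid, False, excluded_reason="inactive")
            continue
        s, e, truncated = downstream_interval(gene, params.downstream_span_bp, annotation.chrom_sizes)
        if truncated and (e - s) // params.window_bp < params.min_windows_above:
            calls[gid] = ReadThroughCall(gid, False, excluded_reason="truncated_zone")
            continue
        if overall_increase_filter(gene_body_expression(test, gene), control_expr[gid], params):
            calls[gid] = ReadThroughCall(gid, False, excluded_reason="overall_increase")
            continue
        twv = downstream_window_vector(test, gene, params.downstream_span_bp, params.window_bp)
        cwv = downstream_window_vector(control, gene, params.downstream_span_bp, params.window_bp)
        calls[gid] = call_gene_readthrough(twv, cwv, params)
    return SampleReadthroughProfile(sample_id, control_id, calls)
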