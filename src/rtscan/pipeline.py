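"""End-to-end orchestration: per-pair stages and cohort aggregation.

All outputs are pure functions of (inputs, parameters): no timestamps or
hostnames enter the files, so a rerun on identical inputs is byte-identical.
Per-sample failures in a cohort run are isolated (skipped and reported in the
run summary) rather than aborting the whole cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import (GenomeAnnotation, TandemPair, build_tandem_pairs, pairs_to_tsv,
                     read_chrom_sizes)
from .coverage import CoverageTrack, cohort_matrix, metagene_profile
from .caller import CallerParams, SampleReadthroughProfile, profile_sample
from .interference import (correlation_screen, downstream_expression_change,
                           invasion_fraction, readthrough_level)
from .chimeras import (JunctionRecord, call_chimeras, calls_to_dataframe,
                       chimera_readthrough_association, pattern_histogram, read_junctions)
from .stats import logrank_test, read_survival, stratify_by_readthrough, survival_by_stratum

log = logging.getLogger(__name__)

ALL_STAGES = ("call", "interference", "chimera")


class DataError(RuntimeError):
    """Malformed or missing input data (CLI exit code 3)."""


def _manifest(path: Path, params: CallerParams, extra: dict) -> None:
    payload = {"rtscan_version": __version__, "params": params.to_dict(), **extra}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def run_pair(annotation: GenomeAnnotation, test: CoverageTrack, control: CoverageTrack,
             outdir: str | Path, sample_id: str = "test", control_id: str = "control",
             params: CallerParams | None = None,
             junctions: Sequence[JunctionRecord] | None = None,
             pairs: Sequence[TandemPair] | None = None,
             stages: Sequence[str] = ALL_STAGES,
             write_heatmap: bool = True) -> dict:
    """Run the per-sample stages for one test/control pair and write TSV outputs.

    Returns a dict with the in-memory results (profile, invasion table,
    chimera calls) for downstream aggregation.
    """
    params = params or CallerParams()
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if pairs is None:
        pairs = build_tandem_pairs(annotation)
    results: dict = {"sample_id": sample_id}

    profile: SampleReadthroughProfile | None = None
    if "call" in stages:
        profile = profile_sample(test, control, annotation, params, sample_id, control_id)
        profile.to_dataframe().to_csv(out / f"{sample_id}.calls.tsv", sep="\t", index=False)
        results["profile"] = profile
        if write_heatmap:
            entries = []
            for gid in sorted(profile.readthrough_gene_ids):
                call = profile.calls[gid]
                gene = annotation.genes[gid]
                if gene.length < 60:
                    continue
                entries.append((gid, metagene_profile(control, gene),
                                metagene_profile(test, gene), call.readthrough_length_bp))
            if entries:
                ctrl_m, fc_m = cohort_matrix(entries, params.pseudocount)
                ctrl_m.to_csv(out / f"{sample_id}.heatmap_control_log2rpkm.tsv", sep="\t")
                fc_m.to_csv(out / f"{sample_id}.heatmap_log2fc.tsv", sep="\t")

    if "interference" in stages:
        if profile is None:
            raise DataError("interference stage requires the call stage")
        rows = []
        called = profile.readthrough_gene_ids
        for pair in pairs:
            if pair.upstream_id not in called:
                continue
            inv = invasion_fraction(test, control, pair, annotation, params)
            rows.append({"upstream_id": pair.upstream_id, "downstream_id": pair.downstream_id,
                         "gap_bp": pair.gap_bp,
                         "intergenic_fc": inv.intergenic_fc,
                         "downstream_invaded_fraction": inv.downstream_invaded_fraction,
                         "downstream_body_fc": inv.downstream_body_fc})
        inv_df = pd.DataFrame(rows, columns=["upstream_id", "downstream_id", "gap_bp",
                                             "intergenic_fc", "downstream_invaded_fraction",
                                             "downstream_body_fc"])
        inv_df.to_csv(out / f"{sample_id}.invasion.tsv", sep="\t", index=False)
        results["invasion"] = inv_df

    if "chimera" in stages:
        calls, n_unassigned = call_chimeras(junctions or [], annotation, pairs,
                                            sample_id=sample_id)
        df = calls_to_dataframe(calls)
        df.to_csv(out / f"{sample_id}.chimeras.tsv", sep="\t", index=False)
        results["chimeras"] = calls
        results["n_unassigned_junctions"] = n_unassigned

    _manifest(out / f"{sample_id}.run.json", params,
              {"sample_id": sample_id, "control_id": control_id, "stages": sorted(stages)})
    return results


def _load_track(directory: Path, sid: str, total: float,
                chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    plus = directory / f"{sid}.plus.bedgraph"
    minus = directory / f"{sid}.minus.bedgraph"
    single = directory / f"{sid}.bedgraph"
    if plus.exists():
        return CoverageTrack.from_bedgraph(chrom_sizes, total, plus=plus,
                                           minus=minus if minus.exists() else None)
    if single.exists():
        return CoverageTrack.from_bedgraph(chrom_sizes, total, unstranded=single)
    raise DataError(f"no coverage track found for sample {sid!r} in {directory}")


def run_cohort(cohort_dir: str | Path, outdir: str | Path,
               params: CallerParams | None = None,
               cutoff_genes: int = 200, min_samples: int = 10,
               stages: Sequence[str] = ALL_STAGES,
               write_heatmap: bool = True) -> dict:
    """Run the full analysis over a simulated/real cohort directory.

    Expects ``genes.gtf``, ``chrom.sizes``, ``samples.tsv`` (sample_id,
    control_id, totals), optional per-sample junction files and an optional
    ``survival.tsv``. Writes per-sample outputs plus the cohort aggregates:
    burden table, stratification, log-rank comparison, correlation screen,
    chimera pattern histogram, and chimera/read-through association.
    """
    params = params or CallerParams()
    cdir, out = Path(cohort_dir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not (cdir / "samples.tsv").exists():
        raise DataError(f"missing sample sheet {cdir / 'samples.tsv'}")
    sheet = pd.read_csv(cdir / "samples.tsv", sep="\t")
    chrom_sizes = read_chrom_sizes(cdir / "chrom.sizes") if (cdir / "chrom.sizes").exists() else None
    annotation = GenomeAnnotation.from_gtf(cdir / "genes.gtf", chrom_sizes)
    pairs = build_tandem_pairs(annotation)
    pairs_to_tsv(pairs, out / "tandem_pairs.tsv")

    burdens: dict[str, int] = {}
    chim_counts: dict[str, int] = {}
    all_chimeras = []
    pair_index = [f"{p.upstream_id}|{p.downstream_id}" for p in pairs]
    rt_levels = pd.DataFrame(index=pair_index, dtype=float)
    expr_changes = pd.DataFrame(index=pair_index, dtype=float)
    failures: dict[str, str] = {}

    for row in sheet.itertuples(index=False):
        sid, cid = str(row.sample_id), str(row.control_id)
        try:
            test = _load_track(cdir, sid, float(row.test_total_mapped_reads), annotation.chrom_sizes)
            control = _load_track(cdir, cid, float(row.control_total_mapped_reads),
                                  annotation.chrom_sizes)
            jpath = cdir / f"{sid}.junctions.tsv"
            junctions = read_junctions(jpath) if jpath.exists() else []
            res = run_pair(annotation, test, control, out / "samples" / sid,
                           sample_id=sid, control_id=cid, params=params,
                           junctions=junctions, pairs=pairs, stages=stages,
                           write_heatmap=write_heatmap)
        except (OSError, ValueError, KeyError, DataError) as exc:  # isolate per sample
            log.error("sample %s failed: %s", sid, exc)
            failures[sid] = str(exc)
            continue
        if "profile" in res:
            profile = res["profile"]
            burdens[sid] = profile.n_readthrough_genes
            called = profile.readthrough_gene_ids
            rt_col, ex_col = [], []
            for p in pairs:
                if p.upstream_id in called:
                    rt_col.append(readthrough_level(test, control,
                                                    annotation.genes[p.upstream_id], params))
                    ex_col.append(downstream_expression_change(
                        test, control, annotation.genes[p.downstream_id], params.pseudocount))
                else:
                    rt_col.append(np.nan)
                    ex_col.append(np.nan)
            rt_levels[sid] = rt_col
            expr_changes[sid] = ex_col
        if "chimeras" in res:
            chim_counts[sid] = len(res["chimeras"])
            all_chimeras.extend(res["chimeras"])

    summary: dict = {"n_samples": int(len(sheet)), "n_failed": len(failures),
                     "failures": failures, "stages": sorted(stages)}

    if burdens:
        strat = stratify_by_readthrough(burdens, cutoff_genes)
        pd.DataFrame(sorted(burdens.items()), columns=["sample_id", "n_readthrough_genes"]) \
            .to_csv(out / "burden.tsv", sep="\t", index=False)
        strat.to_dataframe().to_csv(out / "stratification.tsv", sep="\t", index=False)
        if (cdir / "survival.tsv").exists():
            survival = read_survival(cdir / "survival.tsv")
            high, low = survival_by_stratum(survival, strat)
            try:
                stat, p = logrank_test(high[["time_days", "event"]].to_numpy(),
                                       low[["time_days", "event"]].to_numpy())
                summary["logrank"] = {"statistic": stat, "p": p,
                                      "n_high": int(len(high)), "n_low": int(len(low))}
            except ValueError as exc:
                summary["logrank"] = {"error": str(exc)}
        screen = correlation_screen(rt_levels, expr_changes, min_samples=min_samples)
        screen.to_csv(out / "correlation_screen.tsv", sep="\t")
        summary["n_significant_pairs"] = int(screen["significant"].sum())
        summary["n_tested_pairs"] = int(screen["tested"].sum())

    if chim_counts:
        hist = pattern_histogram(all_chimeras)
        hist.rename_axis("pattern").rename("n_events") \
            .to_csv(out / "chimera_patterns.tsv", sep="\t")
        if burdens:
            strat = stratify_by_readthrough(burdens, cutoff_genes)
            try:
                assoc = chimera_readthrough_association(burdens, chim_counts,
                                                        strat.assignments)
                summary["chimera_readthrough_association"] = {
                    "r": assoc.r, "p": assoc.p, "n_samples": assoc.n_samples,
                    "high_mean": assoc.high_mean, "low_mean": assoc.low_mean}
            except ValueError as exc:
                summary["chimera_readthrough_association"] = {"error": str(exc)}

    (out / "cohort_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float) + "\n")
    return summary
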