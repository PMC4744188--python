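"""Synthetic paired RNA-seq cohorts with planted read-through ground truth.

The generator emulates the statistical structure the analysis assumes:

* a gene annotation laid out as chains of mostly co-directional genes with
  log-normal gene lengths (median 10 kb) and intergenic gaps (median 8 kb),
  including a configurable fraction of genes with a neighbour closer than
  5 kb (to exercise the clear-zone filter);
* paired coverage tracks: the control is per-base Poisson noise around
  log-normal gene-body depths over a near-zero intergenic background; the
  test track shares the gene-body means (so the overall-increase filter is
  not triggered) and adds, for planted genes, an exponentially decaying
  read-through tail from the TTS (initial depth rho x gene depth,
  characteristic length L_decay, hard-truncated at a drawn tail length);
* downstream-gene invasion: for a subset of planted genes with a tandem
  pair, elevated coverage bridges the intergenic gap and covers a target
  fraction of the downstream gene body at a fixed fold change;
* chimeric junction reads for invaded pairs, with exon ranks drawn with 80%
  mass on the (second-last exon -> second exon) pattern;
* survival times, exponential with a hazard multiplier for samples whose
  true read-through burden exceeds the stratification cutoff.

Everything is driven by one integer seed; fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (GeneModel, GenomeAnnotation, TandemPair, build_tandem_pairs,
                     downstream_interval, eligible_readthrough_genes, write_chrom_sizes)
from .coverage import CoverageTrack
from .chimeras import JunctionRecord, write_junctions


@dataclass
class SimConfig:
    """Study conditions for the simulated cohorts (all lengths in bp, depths in reads/base)."""

    # annotation layout
    n_chroms: int = 2
    chrom_len_bp: int | None = None  # None: sized to fit the placed genes
    n_genes: int = 200
    gene_len_median: int = 10_000
    gene_len_sigma: float = 0.4
    gene_len_min: int = 2_000
    exon_count_range: tuple[int, int] = (2, 10)
    gap_median: int = 8_000
    gap_sigma: float = 0.5
    gap_min: int = 1_000
    close_gap_fraction: float = 0.25   # genes placed with a <5 kb downstream gap
    close_gap_range: tuple[int, int] = (1_000, 4_500)
    far_gap_min: int = 5_500
    strand_switch_prob: float = 0.2    # chains of co-directional genes
    edge_margin_bp: int = 10_000

    # expression and noise
    depth_median: float = 50.0
    depth_sigma: float = 0.6
    background_depth: float = 5e-4     # intergenic per-base mean (near-zero)
    read_len: int = 100                # total_mapped_reads = depth-bases / read_len
    poisson_noise: bool = True         # False: emit the noise-free mean depth directly

    # planted read-through
    readthrough_fraction: float = 0.10  # of eligible genes, per tumor sample
    rho: float = 0.8                    # initial tail depth = rho x gene depth
    l_decay: float = 2_000.0
    tail_len_range: tuple[int, int] = (1_000, 4_000)  # multiples of window below
    tail_len_step: int = 100
    min_plant_depth: float = 30.0

    # invasion of the downstream gene
    invasion_fraction_of_rt: float = 0.2
    invaded_fraction_target: float = 0.2
    invasion_fc: float = 3.0

    # chimeric junctions
    chimera_lambda: float = 3.0
    chimera_modal_mass: float = 0.8    # P(second-last exon -> second exon)
    chimera_min_dist_bp: int = 100

    # survival
    survival_scale_days: float = 1_000.0
    hazard_multiplier: float = 3.0
    censor_time_days: float = 1_500.0
    burden_cutoff: int = 200
    burden_range: tuple[int, int] | None = None  # None: spans the cutoff
    mutant_fraction_high: float = 0.8   # P(SETD2-mutant label | high burden)
    mutant_fraction_low: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("close_gap_fraction", "readthrough_fraction",
                     "invasion_fraction_of_rt", "invaded_fraction_target",
                     "chimera_modal_mass", "mutant_fraction_high", "mutant_fraction_low"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.rho < 0 or self.l_decay <= 0 or self.chimera_lambda < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SampleTruth:
    """Planted ground truth for one simulated tumor/control pair."""

    sample_id: str
    readthrough_tails: dict[str, int]          # gene_id -> planted tail length (bp)
    invaded: dict[str, float]                  # "up|down" -> planted invaded fraction
    chimeras: list[dict]                       # upstream/downstream/ranks/n_reads
    n_true_readthrough: int = 0

    def __post_init__(self) -> None:
        self.n_true_readthrough = len(self.readthrough_tails)


@dataclass
class SamplePairSim:
    sample_id: str
    control_id: str
    control: CoverageTrack
    test: CoverageTrack
    junctions: list[JunctionRecord]
    truth: SampleTruth


@dataclass
class CohortSim:
    annotation: GenomeAnnotation
    samples: list[SamplePairSim]
    survival: pd.DataFrame
    sample_sheet: pd.DataFrame
    config: SimConfig


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# --------------------------------------------------------------------- annotation

def _partition_gene(rng: np.random.Generator, length: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    """Split a gene of ``length`` into alternating exon/intron segments (first/last exon)."""
    n_seg = 2 * n_exons - 1
    min_seg = 30
    if length < n_seg * min_seg:
        n_exons = max(1, length // (2 * min_seg))
        n_seg = max(1, 2 * n_exons - 1)
    w = rng.dirichlet(np.ones(n_seg))
    free = length - n_seg * min_seg
    sizes = (min_seg + np.floor(w * free)).astype(int)
    sizes[-1] += length - sizes.sum()
    exons, pos = [], 0
    for i, s in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(s)))
        pos += int(s)
    return tuple(exons)


def simulate_annotation(config: SimConfig, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Place chains of genes on ``n_chroms`` chromosomes per the configured layout."""
    rng = _rng(config.seed if seed is None else seed, rng)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: dict[str, GeneModel] = {}
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = config.edge_margin_bp
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(n_here):
            gid += 1
            length = int(max(config.gene_len_min,
                             rng.lognormal(math.log(config.gene_len_median), config.gene_len_sigma)))
            n_ex = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
            exons = tuple((pos + a, pos + b) for a, b in _partition_gene(rng, length, n_ex))
            genes[f"G{gid:05d}"] = GeneModel(f"G{gid:05d}", chrom, strand, exons)
            if rng.random() < config.close_gap_fraction:
                gap = int(rng.integers(config.close_gap_range[0], config.close_gap_range[1] + 1))
            else:
                gap = int(max(config.far_gap_min,
                              rng.lognormal(math.log(config.gap_median), config.gap_sigma)))
            gap = max(gap, config.gap_min)
            pos += length + gap
            if rng.random() < config.strand_switch_prob:
                strand = "-" if strand == "+" else "+"
        chrom_sizes[chrom] = pos + config.edge_margin_bp
        if config.chrom_len_bp is not None:
            if pos + config.edge_margin_bp > config.chrom_len_bp:
                raise ValueError(
                    f"infeasible packing: {n_here} genes need {pos + config.edge_margin_bp} bp "
                    f"on {chrom}, chrom_len_bp is {config.chrom_len_bp}")
            chrom_sizes[chrom] = config.chrom_len_bp
    return GenomeAnnotation(genes, chrom_sizes)


# --------------------------------------------------------------------- sample pair

def plantable_genes(annotation: GenomeAnnotation, config: SimConfig,
                    depths: Mapping[str, float],
                    eligible: set[str] | None = None) -> list[str]:
    """Eligible genes deep enough to carry a detectable planted tail.

    Besides the clear-zone eligibility and a minimum depth, planted genes must
    sit safely above the 25th-percentile activity cutoff of the cohort's depth
    distribution (5% margin), since gene-body RPKM is proportional to depth and
    the analysis only calls transcriptionally active genes.
    """
    if eligible is None:
        eligible = eligible_readthrough_genes(annotation)
    active_floor = 1.05 * float(np.percentile(list(depths.values()), 25.0))
    out = []
    for gid in sorted(eligible):
        g = annotation.genes[gid]
        _, _, truncated = downstream_interval(g, config.tail_len_range[1], annotation.chrom_sizes)
        if (not truncated and depths[gid] >= config.min_plant_depth
                and depths[gid] > active_floor):
            out.append(gid)
    return out


def _add_oriented(arr: np.ndarray, tts: int, strand: str, profile: np.ndarray) -> None:
    """Add a TTS-anchored profile (index 0 = base adjacent to the TTS) in strand orientation."""
    n = len(profile)
    if strand == "+":
        end = min(len(arr), tts + n)
        arr[tts:end] += profile[: end - tts]
    else:
        start = max(0, tts - n)
        arr[start:tts] += profile[: tts - start][::-1]


def simulate_sample_pair(annotation: GenomeAnnotation, config: SimConfig,
                         seed: int | None = None, rng: np.random.Generator | None = None,
                         sample_id: str = "tumor", control_id: str = "normal",
                         n_readthrough: int | None = None,
                         invaded_fraction: float | None = None,
                         pairs: Sequence[TandemPair] | None = None,
                         eligible: set[str] | None = None) -> SamplePairSim:
    """Simulate one matched tumor/control coverage pair with planted truth.

    The control track draws per-base Poisson counts around gene-body means;
    the test track shares those means and adds planted read-through tails,
    intergenic bridges plus downstream-gene elevation for invaded pairs, and
    emits junction reads for planted chimeras.
    """
    rng = _rng(config.seed if seed is None else seed, rng)
    gene_ids = sorted(annotation.genes)
    depths = {gid: float(rng.lognormal(math.log(config.depth_median), config.depth_sigma))
              for gid in gene_ids}

    mean_ctrl: dict[tuple[str, str], np.ndarray] = {}
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        for strand in "+-":
            mean_ctrl[(chrom, strand)] = np.full(size, config.background_depth, dtype=np.float32)
    for gid in gene_ids:
        g = annotation.genes[gid]
        mean_ctrl[(g.chrom, g.strand)][g.start:g.end] += depths[gid]
    mean_test = {k: v.copy() for k, v in mean_ctrl.items()}

    # --- plant read-through tails
    candidates = plantable_genes(annotation, config, depths, eligible)
    if n_readthrough is None:
        n_rt = int(round(config.readthrough_fraction * len(candidates)))
    else:
        n_rt = min(n_readthrough, len(candidates))
    planted = sorted(str(g) for g in rng.choice(candidates, size=n_rt, replace=False)) if n_rt else []

    lo, hi = config.tail_len_range
    steps = np.arange(lo, hi + 1, config.tail_len_step)
    tails: dict[str, int] = {}
    for gid in planted:
        tails[gid] = int(rng.choice(steps))

    # --- choose invaded tandem pairs among planted upstream genes
    if pairs is None:
        pairs = build_tandem_pairs(annotation)
    pair_by_up = {p.upstream_id: p for p in pairs}
    invadable = [g for g in planted if g in pair_by_up]
    n_inv = int(round(config.invasion_fraction_of_rt * len(invadable)))
    invaded_up = sorted(str(g) for g in rng.choice(invadable, size=n_inv, replace=False)) if n_inv else []
    f_target = config.invaded_fraction_target if invaded_fraction is None else invaded_fraction

    for gid in planted:
        g = annotation.genes[gid]
        tail_len = tails[gid]
        if gid in invaded_up:
            tail_len = tails[gid] = hi  # invading tails span the whole measured zone
        x = np.arange(tail_len, dtype=np.float32)
        profile = np.float32(config.rho * depths[gid]) * np.exp(-x / np.float32(config.l_decay))
        _add_oriented(mean_test[(g.chrom, g.strand)], g.tts, g.strand, profile)

    invaded: dict[str, float] = {}
    junctions: list[JunctionRecord] = []
    chim_truth: list[dict] = []
    for gid in invaded_up:
        pair = pair_by_up[gid]
        up, down = annotation.genes[gid], annotation.genes[pair.downstream_id]
        gap = pair.gap_bp
        arr = mean_test[(up.chrom, up.strand)]
        # intergenic bridge beyond the planted 4-kb tail, decaying but floored
        floor = np.float32(0.5 * (config.invasion_fc - 1.0) * depths[pair.downstream_id])
        x = np.arange(tails[gid], gap, dtype=np.float32)
        if x.size:
            bridge = np.maximum(
                np.float32(config.rho * depths[gid]) * np.exp(-x / np.float32(config.l_decay)),
                floor)
            _add_oriented(arr, up.tts, up.strand, np.concatenate(
                [np.zeros(tails[gid], dtype=np.float32), bridge]))
        inv_len = int(round(f_target * down.length))
        if inv_len:
            elev = np.full(inv_len, (config.invasion_fc - 1.0) * depths[pair.downstream_id],
                           dtype=np.float32)
            if down.strand == "+":
                arr[down.start: down.start + inv_len] += elev
            else:
                arr[down.end - inv_len: down.end] += elev[::-1]
        invaded[f"{gid}|{pair.downstream_id}"] = inv_len / down.length

        # --- chimeric junction reads for this invaded pair
        k = int(rng.poisson(config.chimera_lambda))
        if k > 0:
            up_tx = up.exons_in_transcription_order()
            down_tx = down.exons_in_transcription_order()
            if (rng.random() < config.chimera_modal_mass
                    and len(up_tx) >= 2 and len(down_tx) >= 2):
                drank, arank = 2, 2
            else:
                drank = int(rng.integers(1, len(up_tx) + 1))
                arank = int(rng.integers(1, len(down_tx) + 1))
            donor_exon = up_tx[-drank]
            acceptor_exon = down_tx[arank - 1]
            donor_pos = donor_exon[1] if up.strand == "+" else donor_exon[0]
            acceptor_pos = acceptor_exon[0] if down.strand == "+" else acceptor_exon[1]
            if abs(acceptor_pos - donor_pos) >= config.chimera_min_dist_bp:
                for i in range(k):
                    junctions.append(JunctionRecord(
                        up.chrom, donor_pos, acceptor_pos, up.strand,
                        f"{sample_id}:{gid}:{pair.downstream_id}:{i + 1}"))
                chim_truth.append({"upstream_id": gid, "downstream_id": pair.downstream_id,
                                   "donor_exon_rank_from_end": drank,
                                   "acceptor_exon_rank": arank, "n_reads": k})

    # --- draw Poisson coverage and package tracks
    def draw(means: dict[tuple[str, str], np.ndarray]) -> CoverageTrack:
        if config.poisson_noise:
            data = {k: rng.poisson(v).astype(np.float32) for k, v in sorted(means.items())}
        else:
            data = {k: v.copy() for k, v in sorted(means.items())}
        total = max(1.0, sum(float(a.sum()) for a in data.values()) / config.read_len)
        return CoverageTrack(dict(annotation.chrom_sizes), total, data)

    control = draw(mean_ctrl)
    test = draw(mean_test)
    truth = SampleTruth(sample_id, tails, invaded, chim_truth)
    return SamplePairSim(sample_id, control_id, control, test, junctions, truth)


# --------------------------------------------------------------------- cohort

def simulate_survival(strata: Sequence[str], config: SimConfig,
                      rng: np.random.Generator,
                      sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Exponential survival times with a hazard multiplier for 'high' strata."""
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(strata))]
    rows = []
    for sid, stratum in zip(sample_ids, strata):
        scale = config.survival_scale_days
        if stratum == "high":
            scale /= config.hazard_multiplier
        t = float(rng.exponential(scale))
        event = t <= config.censor_time_days
        rows.append((sid, min(t, config.censor_time_days), int(event)))
    return pd.DataFrame(rows, columns=["sample_id", "time_days", "event"])


def simulate_coupled_screen(n_pairs: int, n_coupled: int, n_samples: int,
                            slope: float = 1.0, noise_sd: float = 0.2,
                            rt_mean: float = 1.0, rt_sd: float = 1.0,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Read-through/expression matrices for the correlation screen, with planted coupling.

    Every tandem pair gets a per-sample read-through level ~ N(rt_mean, rt_sd).
    For the first ``n_coupled`` pairs the downstream expression change is
    ``slope x level + N(0, noise_sd)``; for the rest it is independent noise of
    the same marginal scale. Returns (rt_levels, expr_changes, coupled_ids).
    """
    rng = _rng(seed, rng)
    index = [f"P{i + 1:04d}" for i in range(n_pairs)]
    cols = [f"S{j + 1:03d}" for j in range(n_samples)]
    rt = rng.normal(rt_mean, rt_sd, size=(n_pairs, n_samples))
    expr = np.empty_like(rt)
    expr[:n_coupled] = slope * rt[:n_coupled] + rng.normal(0, noise_sd, size=(n_coupled, n_samples))
    expr[n_coupled:] = rng.normal(0, math.hypot(slope * rt_sd, noise_sd),
                                  size=(n_pairs - n_coupled, n_samples))
    return (pd.DataFrame(rt, index=index, columns=cols),
            pd.DataFrame(expr, index=index, columns=cols), index[:n_coupled])


def simulate_cohort(annotation: GenomeAnnotation, config: SimConfig, n_samples: int,
                    seed: int | None = None, outdir: str | Path | None = None) -> CohortSim:
    """Simulate a cohort of matched pairs with burden-linked survival.

    Per-sample read-through burdens are drawn uniformly over a range spanning
    the stratification cutoff (clipped to the number of plantable genes);
    samples whose true burden exceeds the cutoff get the configured hazard
    multiplier. With ``outdir`` set, all artifacts (GTF, bedGraphs, junction
    files, sample sheet, survival table, truth JSON) are written to disk.
    """
    if n_samples < 2:
        raise ValueError("a cohort needs at least 2 sample pairs")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    children = ss.spawn(n_samples + 1)
    main = np.random.default_rng(children[0])

    eligible = eligible_readthrough_genes(annotation)
    pairs = build_tandem_pairs(annotation)
    # burden range: probe plantable count with median depth assumption
    n_plantable_max = len(eligible)
    if config.burden_range is not None:
        blo, bhi = config.burden_range
    else:
        blo = max(1, round(0.25 * config.burden_cutoff))
        bhi = max(blo + 1, round(1.75 * config.burden_cutoff))
    bhi = min(bhi, n_plantable_max)
    blo = min(blo, bhi)

    samples: list[SamplePairSim] = []
    for i in range(n_samples):
        n_rt = int(main.integers(blo, bhi + 1))
        sim = simulate_sample_pair(
            annotation, config, rng=np.random.default_rng(children[i + 1]),
            sample_id=f"S{i + 1:03d}", control_id=f"N{i + 1:03d}",
            n_readthrough=n_rt, pairs=pairs, eligible=eligible)
        samples.append(sim)

    strata = ["high" if s.truth.n_true_readthrough > config.burden_cutoff else "low"
              for s in samples]
    survival = simulate_survival(strata, config, main, [s.sample_id for s in samples])
    labels = []
    for s, st in zip(samples, strata):
        p = config.mutant_fraction_high if st == "high" else config.mutant_fraction_low
        labels.append("mutant" if main.random() < p else "wt")
    sheet = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "control_id": [s.control_id for s in samples],
        "test_total_mapped_reads": [s.test.total_mapped_reads for s in samples],
        "control_total_mapped_reads": [s.control.total_mapped_reads for s in samples],
        "setd2_status": labels,
    })
    cohort = CohortSim(annotation, samples, survival, sheet, config)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: CohortSim, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.annotation.to_gtf(out / "genes.gtf")
    write_chrom_sizes(cohort.annotation.chrom_sizes, out / "chrom.sizes")
    for sim in cohort.samples:
        for track, sid in ((sim.test, sim.sample_id), (sim.control, sim.control_id)):
            track.to_bedgraph("+", out / f"{sid}.plus.bedgraph")
            track.to_bedgraph("-", out / f"{sid}.minus.bedgraph")
        write_junctions(sim.junctions, out / f"{sim.sample_id}.junctions.tsv")
    cohort.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    cohort.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    truth = {
        "burden_cutoff": cohort.config.burden_cutoff,
        "hazard_multiplier": cohort.config.hazard_multiplier,
        "samples": {s.sample_id: {
            "readthrough_tails": s.truth.readthrough_tails,
            "invaded": s.truth.invaded,
            "chimeras": s.truth.chimeras,
            "n_true_readthrough": s.truth.n_true_readthrough,
        } for s in cohort.samples},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
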