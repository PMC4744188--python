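"""Synthetic-data generator: layout, planted signal, bookkeeping, determinism."""

import json
import math
from pathlib import Path

import numpy as np
import pytest

from rtscan.caller import CallerParams, profile_sample
from rtscan.genome import build_tandem_pairs, eligible_readthrough_genes
from rtscan.coverage import downstream_window_vector, fold_change_vector
from rtscan.simulate import (SimConfig, simulate_annotation, simulate_cohort,
                             simulate_coupled_screen, simulate_sample_pair,
                             simulate_survival)


class TestAnnotationLayout:
    def test_single_gene_no_pairs(self):
        cfg = SimConfig(n_genes=1, n_chroms=1)
        ann = simulate_annotation(cfg, seed=1)
        assert len(ann) == 1 and build_tandem_pairs(ann) == []

    def test_fixed_seed_identical_gtf(self, tmp_path):
        cfg = SimConfig(n_genes=30)
        for d in ("a", "b"):
            simulate_annotation(cfg, seed=9).to_gtf(tmp_path / f"{d}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_close_gap_fraction_realized(self):
        cfg = SimConfig(n_genes=1000, n_chroms=2, close_gap_fraction=0.30)
        ann = simulate_annotation(cfg, seed=3)
        gaps = []
        for chrom in ann.chrom_sizes:
            genes = ann.genes_on(chrom)
            gaps += [b.start - a.end for a, b in zip(genes, genes[1:])]
        frac = np.mean([g < 5000 for g in gaps])
        assert abs(frac - 0.30) <= 0.05

    def test_genes_disjoint_and_within_bounds(self):
        ann = simulate_annotation(SimConfig(n_genes=200), seed=4)
        for chrom in ann.chrom_sizes:
            genes = ann.genes_on(chrom)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start
            for g in genes:
                assert 0 <= g.start and g.end <= ann.chrom_sizes[chrom]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_annotation(SimConfig(n_genes=100, n_chroms=1, chrom_len_bp=100_000), seed=1)


class TestSamplePair:
    def test_planted_tail_fold_change_matches_decay_model(self):
        """Noise-free: fc of the first 10 windows follows rho*e^{-x/L} / background."""
        cfg = SimConfig(n_genes=40, poisson_noise=False)
        ann = simulate_annotation(cfg, seed=5)
        sim = simulate_sample_pair(ann, cfg, seed=6, n_readthrough=5)
        params = CallerParams()
        for gid, tail in sim.truth.readthrough_tails.items():
            gene = ann.genes[gid]
            t = downstream_window_vector(sim.test, gene)
            c = downstream_window_vector(sim.control, gene)
            fc = fold_change_vector(t, c, params.pseudocount)
            n_win = min(10, tail // 100)
            assert np.all(fc[:n_win] >= 1.5)

    def test_zero_readthrough_fraction_yields_near_zero_calls(self):
        cfg = SimConfig(n_genes=100, readthrough_fraction=0.0)
        ann = simulate_annotation(cfg, seed=7)
        sim = simulate_sample_pair(ann, cfg, seed=8)
        prof = profile_sample(sim.test, sim.control, ann)
        assert prof.n_readthrough_genes <= 1  # < 1% of ~100 genes

    def test_gene_body_means_unchanged_for_planted_genes(self):
        cfg = SimConfig(n_genes=40, poisson_noise=False)
        ann = simulate_annotation(cfg, seed=15)
        sim = simulate_sample_pair(ann, cfg, seed=16, n_readthrough=5)
        for gid in sim.truth.readthrough_tails:
            g = ann.genes[gid]
            t = sim.test.depth(g.chrom, g.strand)[g.start:g.end]
            c = sim.control.depth(g.chrom, g.strand)[g.start:g.end]
            np.testing.assert_allclose(t, c, rtol=1e-5)

    def test_junction_lines_match_truth_counts(self):
        cfg = SimConfig(n_genes=60, readthrough_fraction=0.4, invasion_fraction_of_rt=0.8,
                        chimera_lambda=4.0)
        ann = simulate_annotation(cfg, seed=9)
        sim = simulate_sample_pair(ann, cfg, seed=10)
        assert sim.truth.chimeras  # the configuration plants some
        for ev in sim.truth.chimeras:
            matching = [j for j in sim.junctions
                        if f":{ev['upstream_id']}:{ev['downstream_id']}:" in j.read_id]
            assert len(matching) == ev["n_reads"]

    def test_total_mapped_reads_equals_depth_bases_over_read_len(self):
        cfg = SimConfig(n_genes=20)
        ann = simulate_annotation(cfg, seed=11)
        sim = simulate_sample_pair(ann, cfg, seed=12)
        depth_bases = sum(float(a.sum()) for a in sim.control.data.values())
        assert sim.control.total_mapped_reads == pytest.approx(depth_bases / cfg.read_len)

    def test_planted_genes_are_eligible(self):
        cfg = SimConfig(n_genes=80)
        ann = simulate_annotation(cfg, seed=13)
        sim = simulate_sample_pair(ann, cfg, seed=14, n_readthrough=10)
        eligible = eligible_readthrough_genes(ann)
        assert set(sim.truth.readthrough_tails) <= eligible


class TestCohort:
    def _small_cfg(self, **kw):
        base = dict(n_genes=40, gene_len_median=4000, gene_len_min=1500,
                    burden_cutoff=8, burden_range=(2, 14), readthrough_fraction=0.3)
        base.update(kw)
        return SimConfig(**base)

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        cfg = self._small_cfg()
        for d in ("a", "b"):
            ann = simulate_annotation(cfg, seed=17)
            simulate_cohort(ann, cfg, n_samples=3, seed=18, outdir=tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_truth_json_consistent_with_emitted_files(self, tmp_path):
        cfg = self._small_cfg(invasion_fraction_of_rt=0.5, chimera_lambda=4.0)
        ann = simulate_annotation(cfg, seed=19)
        cohort = simulate_cohort(ann, cfg, n_samples=3, seed=20, outdir=tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        for sim in cohort.samples:
            entry = truth["samples"][sim.sample_id]
            assert entry["n_true_readthrough"] == len(entry["readthrough_tails"])
            n_lines = sum(1 for _ in open(tmp_path / f"{sim.sample_id}.junctions.tsv")) \
                if (tmp_path / f"{sim.sample_id}.junctions.tsv").stat().st_size else 0
            assert n_lines == sum(ev["n_reads"] for ev in entry["chimeras"])

    def test_burden_recovery_correlates_with_truth(self):
        """End-to-end: caller-estimated burden tracks the planted burden almost perfectly."""
        cfg = self._small_cfg(n_genes=80, burden_range=(3, 25), burden_cutoff=12,
                              gene_len_median=6000)
        ann = simulate_annotation(cfg, seed=23)
        cohort = simulate_cohort(ann, cfg, n_samples=8, seed=24)
        true_b, est_b = [], []
        for sim in cohort.samples:
            prof = profile_sample(sim.test, sim.control, ann)
            true_b.append(sim.truth.n_true_readthrough)
            est_b.append(prof.n_readthrough_genes)
        r = np.corrcoef(true_b, est_b)[0, 1]
        assert r >= 0.95


class TestSurvivalGenerator:
    def test_deterministic_given_rng_state(self):
        cfg = SimConfig()
        a = simulate_survival(["high", "low"] * 10, cfg, np.random.default_rng(3))
        b = simulate_survival(["high", "low"] * 10, cfg, np.random.default_rng(3))
        assert a.equals(b)

    def test_high_stratum_dies_earlier_on_average(self):
        cfg = SimConfig(hazard_multiplier=3.0)
        rng = np.random.default_rng(4)
        df = simulate_survival(["high"] * 300 + ["low"] * 300, cfg, rng)
        high = df.iloc[:300]["time_days"].mean()
        low = df.iloc[300:]["time_days"].mean()
        assert high < low

    def test_administrative_censoring(self):
        cfg = SimConfig(censor_time_days=100.0)
        df = simulate_survival(["low"] * 50, cfg, np.random.default_rng(5))
        assert df["time_days"].max() <= 100.0
        assert (~df["event"].astype(bool)).sum() > 0


class TestCoupledScreenGenerator:
    def test_shapes_and_coupling(self):
        rt, expr, coupled = simulate_coupled_screen(50, 5, 30, seed=6)
        assert rt.shape == expr.shape == (50, 30)
        assert len(coupled) == 5
        for pid in coupled:
            r = np.corrcoef(rt.loc[pid], expr.loc[pid])[0, 1]
            assert r > 0.9
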