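"""Window counting, RPKM normalisation, fold changes, and metagene binning."""

import numpy as np
import pytest

from rtscan.coverage import (CoverageTrack, WindowVector, cohort_matrix,
                             fold_change_vector, gene_body_expression,
                             metagene_profile, region_count, rpkm, window_counts)
from rtscan.genome import GeneModel

from conftest import make_gene, make_track


def oracle_window_counts(arr, start, end, orientation, width):
    """Naive per-base loop, proximal-to-distal along the orientation."""
    seg = list(arr[start:end])
    if orientation == "-":
        seg = seg[::-1]
    out = []
    for i in range(len(seg) // width):
        out.append(sum(seg[i * width:(i + 1) * width]))
    return np.array(out, dtype=float)


class TestWindowCounts:
    def test_uniform_coverage(self):
        track = make_track({"chr1": 400}, {("chr1", "+"): np.full(400, 2.0)})
        assert window_counts(track, "chr1", 0, 400, "+", 100).tolist() == [200, 200, 200, 200]

    def test_zero_track_and_empty_interval(self):
        track = make_track({"chr1": 400}, {("chr1", "+"): np.zeros(400)})
        assert window_counts(track, "chr1", 0, 400, "+", 100).tolist() == [0, 0, 0, 0]
        assert window_counts(track, "chr1", 100, 100, "+", 100).size == 0

    @pytest.mark.parametrize("orientation", ["+", "-"])
    def test_random_sparse_track_matches_per_base_oracle(self, rng, orientation):
        for _ in range(50):
            size = int(rng.integers(50, 600))
            arr = rng.poisson(0.3, size).astype(float)
            track = make_track({"chr1": size}, {("chr1", orientation): arr})
            start = int(rng.integers(0, size // 2))
            end = int(rng.integers(start, size))
            width = int(rng.integers(1, 40))
            got = window_counts(track, "chr1", start, end, orientation, width)
            np.testing.assert_allclose(
                got, oracle_window_counts(arr, start, end, orientation, width), atol=1e-9)

    def test_partition_conservation(self, rng):
        arr = rng.poisson(2.0, 1000).astype(float)
        track = make_track({"chr1": 1000}, {("chr1", "+"): arr})
        windows = window_counts(track, "chr1", 0, 1000, "+", 50)
        assert windows.sum() == pytest.approx(region_count(track, "chr1", 0, 1000, "+"))


class TestRpkm:
    def test_formula(self):
        assert rpkm(100, 100, 10_000_000) == pytest.approx(100.0)
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert rpkm(30, 250, 2_000_000) == pytest.approx(rpkm(30, 250, 1_000_000) / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestFoldChange:
    def test_identity(self):
        wv = WindowVector("g", 100, np.full(40, 3.0))
        assert np.allclose(fold_change_vector(wv, wv, 0.1), 1.0)

    def test_plain_ratio_and_pseudocount(self):
        t = WindowVector("g", 100, [3.0])
        c = WindowVector("g", 100, [2.0])
        assert fold_change_vector(t, c, 0.0)[0] == pytest.approx(1.5)
        t2 = WindowVector("g", 100, [5.0])
        c2 = WindowVector("g", 100, [0.0])
        assert fold_change_vector(t2, c2, 0.1)[0] == pytest.approx(51.0)

    def test_mismatched_grids_rejected(self):
        a = WindowVector("g", 100, np.ones(40))
        b = WindowVector("g", 100, np.ones(30))
        with pytest.raises(ValueError):
            fold_change_vector(a, b)
        with pytest.raises(ValueError):
            fold_change_vector(a, WindowVector("other", 100, np.ones(40)))


def oracle_metagene(arr, gene, total, flank_bp=4000, width=100, n_bins=60):
    """Brute-force per-base means/RPKM for the 40/60/40 profile."""
    size = len(arr)

    def win_rpkm(lo, hi):
        c = arr[max(0, lo):min(size, hi)].sum()
        return c / (width / 1e3) / (total / 1e6)

    L = gene.end - gene.start
    bin_len = L // n_bins
    seg = list(arr[gene.start:gene.end])
    if gene.strand == "-":
        seg = seg[::-1]  # transcription orientation; remainder goes to the 3'-most bin
    body = []
    for j in range(n_bins):
        lo = j * bin_len
        hi = (j + 1) * bin_len if j < n_bins - 1 else L
        body.append(sum(seg[lo:hi]) / ((hi - lo) / 1e3) / (total / 1e6))
    up = [win_rpkm(gene.start - flank_bp + i * width, gene.start - flank_bp + (i + 1) * width)
          for i in range(flank_bp // width)]
    down = [win_rpkm(gene.end + i * width, gene.end + (i + 1) * width)
            for i in range(flank_bp // width)]
    if gene.strand == "-":
        up, down = down[::-1], up[::-1]
    return np.array(up), np.array(body), np.array(down)


class TestMetagene:
    def _gene(self, strand="+", start=5000, end=12345):
        return make_gene("g", "chr1", strand, [(start, end)])

    def test_uniform_coverage_gives_flat_body(self):
        arr = np.full(20000, 3.0)
        track = make_track({"chr1": 20000}, {("chr1", "+"): arr})
        prof = metagene_profile(track, self._gene())
        assert np.allclose(prof.body, prof.body[0])
        assert np.allclose(prof.upstream_flank, prof.downstream_flank)

    def test_signal_only_downstream_of_tts(self):
        arr = np.zeros(20000)
        arr[12345:16345] = 5.0
        track = make_track({"chr1": 20000}, {("chr1", "+"): arr})
        prof = metagene_profile(track, self._gene())
        assert np.all(prof.body == 0) and np.all(prof.upstream_flank == 0)
        assert np.all(prof.downstream_flank > 0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_track_matches_per_base_oracle(self, rng, strand):
        for _ in range(30):
            size = 20000
            arr = rng.poisson(1.0, size).astype(float)
            track = make_track({"chr1": size}, {("chr1", strand): arr}, total=2_000_000)
            start = int(rng.integers(4000, 6000))
            end = start + int(rng.integers(61, 9000))
            gene = make_gene("g", "chr1", strand, [(start, end)])
            prof = metagene_profile(track, gene)
            up, body, down = oracle_metagene(arr, gene, 2_000_000)
            np.testing.assert_allclose(prof.upstream_flank, up, atol=1e-9)
            np.testing.assert_allclose(prof.body, body, atol=1e-9)
            np.testing.assert_allclose(prof.downstream_flank, down, atol=1e-9)

    def test_minus_strand_mirrors_plus(self, rng):
        """A '-' gene on mirrored coverage gives the same profile as its '+' twin."""
        size = 20000
        arr = rng.poisson(2.0, size).astype(float)
        plus_track = make_track({"chr1": size}, {("chr1", "+"): arr})
        minus_track = make_track({"chr1": size}, {("chr1", "-"): arr[::-1].copy()})
        gplus = make_gene("g", "chr1", "+", [(5000, 9000)])
        gminus = make_gene("g", "chr1", "-", [(size - 9000, size - 5000)])
        p = metagene_profile(plus_track, gplus)
        m = metagene_profile(minus_track, gminus)
        np.testing.assert_allclose(p.concat(), m.concat(), atol=1e-9)

    def test_short_body_rejected(self):
        track = make_track({"chr1": 20000}, {("chr1", "+"): np.zeros(20000)})
        with pytest.raises(ValueError, match="shorter"):
            metagene_profile(track, self._gene(end=5030))


class TestGeneBodyExpression:
    def test_zero_coverage(self):
        track = make_track({"chr1": 5000}, {("chr1", "+"): np.zeros(5000)})
        assert gene_body_expression(track, make_gene("g", "chr1", "+", [(0, 1000)])) == 0.0

    def test_composes_with_rpkm_of_summed_counts(self, rng):
        arr = rng.poisson(3.0, 5000).astype(float)
        track = make_track({"chr1": 5000}, {("chr1", "+"): arr}, total=3_000_000)
        gene = make_gene("g", "chr1", "+", [(1000, 3500)])
        expect = rpkm(arr[1000:3500].sum(), 2500, 3_000_000)
        assert gene_body_expression(track, gene) == pytest.approx(float(expect))


class TestCohortMatrix:
    def _profile(self, gid, level):
        from rtscan.coverage import MetageneProfile
        return MetageneProfile(gid, np.full(40, level), np.full(60, level), np.full(40, level))

    def test_single_gene_row_shape(self):
        ctrl, fc = cohort_matrix([("g1", self._profile("g1", 2.0), self._profile("g1", 4.0), 500)])
        assert ctrl.shape == (1, 140) and fc.shape == (1, 140)
        assert np.allclose(fc.iloc[0], np.log2(4.1 / 2.1))

    def test_rows_ordered_by_descending_readthrough_length(self):
        entries = [("short", self._profile("short", 1), self._profile("short", 1), 500),
                   ("long", self._profile("long", 1), self._profile("long", 1), 2000)]
        ctrl, _ = cohort_matrix(entries)
        assert list(ctrl.index) == ["long", "short"]
        ctrl2, _ = cohort_matrix(entries[::-1])
        assert list(ctrl2.index) == ["long", "short"]


class TestBedgraphIO:
    def test_roundtrip_preserves_depth(self, rng, tmp_path):
        size = 3000
        arr_p = rng.poisson(1.5, size).astype(np.float32)
        arr_m = rng.poisson(0.5, size).astype(np.float32)
        track = make_track({"chr1": size}, {("chr1", "+"): arr_p, ("chr1", "-"): arr_m})
        track.to_bedgraph("+", tmp_path / "p.bg")
        track.to_bedgraph("-", tmp_path / "m.bg")
        back = CoverageTrack.from_bedgraph({"chr1": size}, track.total_mapped_reads,
                                           plus=tmp_path / "p.bg", minus=tmp_path / "m.bg")
        np.testing.assert_allclose(back.depth("chr1", "+"), arr_p, atol=1e-5)
        np.testing.assert_allclose(back.depth("chr1", "-"), arr_m, atol=1e-5)
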