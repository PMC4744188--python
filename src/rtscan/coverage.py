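"""Windowed coverage quantification: raw counts, RPKM, fold changes, metagene profiles.

Coverage is consumed as per-base read depth (bedGraph tracks, one file per
strand), normalised to RPKM using the sample's total mapped read count.
Windowed vectors are always ordered along the direction of transcription
(TTS-proximal window first for downstream zones), so '-' strand genes mirror
'+' strand genes automatically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, downstream_interval

log = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample, optionally strand-resolved.

    ``data`` maps ``(chrom, strand)`` to a per-base depth array; strand is
    '+'/'-' for stranded tracks or '.' for unstranded. ``total_mapped_reads``
    is the library size used for RPKM normalisation.
    """

    chrom_sizes: dict[str, int]
    total_mapped_reads: float
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        self._warned_unstranded = False

    @property
    def stranded(self) -> bool:
        return not any(s == "." for _, s in self.data)

    def depth(self, chrom: str, strand: str) -> np.ndarray:
        """Depth array for a chromosome on the requested strand.

        Falls back to the unstranded track (with a one-time warning) when no
        strand-resolved track exists; missing chromosomes are all-zero.
        """
        if (chrom, strand) in self.data:
            return self.data[(chrom, strand)]
        if (chrom, ".") in self.data:
            if strand in "+-" and not self._warned_unstranded:
                log.warning("unstranded coverage used for strand-specific query")
                self._warned_unstranded = True
            return self.data[(chrom, ".")]
        return np.zeros(self.chrom_sizes[chrom], dtype=np.float32)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_bedgraph(cls, chrom_sizes: Mapping[str, int], total_mapped_reads: float,
                      plus: str | Path | None = None, minus: str | Path | None = None,
                      unstranded: str | Path | None = None) -> "CoverageTrack":
        track = cls(dict(chrom_sizes), total_mapped_reads)
        for strand, path in (("+", plus), ("-", minus), (".", unstranded)):
            if path is None:
                continue
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "value"], comment="t",
                             dtype={"chrom": str})
            for chrom, sub in df.groupby("chrom", sort=False):
                size = track.chrom_sizes[chrom]
                # accumulate disjoint-interval values via a difference array
                delta = np.zeros(size + 1)
                np.add.at(delta, sub["start"].to_numpy(int), sub["value"].to_numpy(float))
                np.add.at(delta, sub["end"].to_numpy(int), -sub["value"].to_numpy(float))
                arr = track.data.setdefault(
                    (chrom, strand), np.zeros(size, dtype=np.float32))
                arr += np.cumsum(delta[:-1]).astype(np.float32)
        return track

    def to_bedgraph(self, strand: str, path: str | Path) -> None:
        """Write one strand as a run-length-encoded 4-column bedGraph (zeros omitted)."""
        frames = []
        for chrom in sorted(self.chrom_sizes):
            arr = self.data.get((chrom, strand))
            if arr is None:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            vals = arr[starts]
            keep = vals != 0
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts[keep],
                                        "end": ends[keep], "value": vals[keep]}))
        df = pd.concat(frames) if frames else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        # integer depths print without a decimal point for compact files
        df["value"] = df["value"].map(lambda v: f"{v:g}")
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class WindowVector:
    """RPKM per fixed-width window over a strand-oriented interval, proximal first."""

    gene_id: str
    window_bp: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError(f"{self.gene_id}: negative RPKM values")

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass
class MetageneProfile:
    """40-bin upstream flank / 60-bin scaled body / 40-bin downstream flank profile."""

    gene_id: str
    upstream_flank: np.ndarray  # 100-bp windows, -4 kb .. TSS
    body: np.ndarray            # 60 equal bins, TSS .. TTS
    downstream_flank: np.ndarray  # 100-bp windows, TTS .. +4 kb
    log2: bool = False

    def concat(self) -> np.ndarray:
        return np.concatenate([self.upstream_flank, self.body, self.downstream_flank])


def window_counts(track: CoverageTrack, chrom: str, start: int, end: int,
                  orientation: str, width_bp: int) -> np.ndarray:
    """Sum per-base depth in consecutive windows of ``width_bp`` over [start, end).

    Windows are ordered proximal-to-distal along ``orientation`` ('+' walks
    left-to-right, '-' right-to-left). A trailing partial window (distal side)
    is dropped with a debug notice. An empty interval yields an empty vector.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    size = track.chrom_sizes[chrom]
    start, end = max(0, start), min(size, end)
    if end <= start:
        return np.zeros(0)
    arr = track.depth(chrom, orientation if orientation in "+-" else ".")
    seg = arr[start:end].astype(float)
    if orientation == "-":
        seg = seg[::-1]
    n = len(seg) // width_bp
    if len(seg) % width_bp:
        log.debug("dropping trailing partial window (%d bp)", len(seg) % width_bp)
    if n == 0:
        return np.zeros(0)
    return seg[: n * width_bp].reshape(n, width_bp).sum(axis=1)


def rpkm(raw_count, region_len_bp, total_mapped_reads: float):
    """Reads per kilobase of region per million mapped reads."""
    region_len_bp = np.asarray(region_len_bp, dtype=float)
    if np.any(region_len_bp <= 0):
        raise ValueError("region_len_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return np.asarray(raw_count, dtype=float) / (region_len_bp / 1e3) / (total_mapped_reads / 1e6)


def downstream_window_vector(track: CoverageTrack, gene: GeneModel,
                             span_bp: int = 4000, width_bp: int = 100) -> WindowVector:
    """RPKM in ``width_bp`` windows over the ``span_bp`` zone downstream of the TTS."""
    s, e, _ = downstream_interval(gene, span_bp, track.chrom_sizes)
    counts = window_counts(track, gene.chrom, s, e, gene.strand, width_bp)
    return WindowVector(gene.gene_id, width_bp, rpkm(counts, width_bp, track.total_mapped_reads))


def fold_change_vector(test: WindowVector, control: WindowVector, pseudocount: float = 0.1) -> np.ndarray:
    """Per-window (test + pc) / (control + pc) RPKM ratio on a matching grid."""
    if (test.gene_id != control.gene_id or test.window_bp != control.window_bp
            or test.n_windows != control.n_windows):
        raise ValueError(
            f"window grids do not match: {test.gene_id}/{control.gene_id}")
    return (test.values + pseudocount) / (control.values + pseudocount)


def region_count(track: CoverageTrack, chrom: str, start: int, end: int, strand: str) -> float:
    """Total depth over a genomic interval on one strand."""
    size = track.chrom_sizes[chrom]
    start, end = max(0, start), min(size, end)
    if end <= start:
        return 0.0
    return float(track.depth(chrom, strand)[start:end].sum())


def gene_body_expression(track: CoverageTrack, gene: GeneModel) -> float:
    """RPKM over the whole gene body [start, end)."""
    c = region_count(track, gene.chrom, gene.start, gene.end, gene.strand)
    return float(rpkm(c, gene.length, track.total_mapped_reads))


def metagene_profile(track: CoverageTrack, gene: GeneModel,
                     flank_bp: int = 4000, flank_window_bp: int = 100,
                     n_body_bins: int = 60) -> MetageneProfile:
    """Metagene profile: fixed flank windows plus a gene body scaled to equal bins.

    The body is divided into ``n_body_bins`` equal spans (remainder bases go to
    the last bin); flanks use fixed ``flank_window_bp`` windows, truncated
    regions padded with zero coverage. All values are RPKM per bin. Profiles of
    '-' strand genes are reversed so the TSS is always on the left.

    Raises
    ------
    ValueError
        If the gene body is shorter than ``n_body_bins`` bases.
    """
    if gene.length < n_body_bins:
        raise ValueError(f"{gene.gene_id}: body shorter than {n_body_bins} bp, skipped")
    size = track.chrom_sizes[gene.chrom]
    arr = track.depth(gene.chrom, gene.strand)
    n_flank = flank_bp // flank_window_bp
    total = track.total_mapped_reads

    def flank(start: int, end: int) -> np.ndarray:
        seg = np.zeros(flank_bp)
        cs, ce = max(0, start), min(size, end)
        if ce > cs:
            seg[cs - start: ce - start] = arr[cs:ce]
        return rpkm(seg.reshape(n_flank, flank_window_bp).sum(axis=1), flank_window_bp, total)

    body_seg = arr[gene.start: gene.end].astype(float)
    if gene.strand == "-":
        body_seg = body_seg[::-1]  # bin in transcription orientation
    bin_len = gene.length // n_body_bins
    edges = np.arange(0, n_body_bins * bin_len, bin_len)
    counts = np.add.reduceat(body_seg, edges)  # last bin absorbs the remainder
    lengths = np.full(n_body_bins, bin_len, dtype=float)
    lengths[-1] = gene.length - (n_body_bins - 1) * bin_len
    body = rpkm(counts, lengths, total)

    if gene.strand == "+":
        up = flank(gene.start - flank_bp, gene.start)
        down = flank(gene.end, gene.end + flank_bp)
    else:
        up = flank(gene.end, gene.end + flank_bp)[::-1]
        down = flank(gene.start - flank_bp, gene.start)[::-1]
    return MetageneProfile(gene.gene_id, up, body, down)


def average_profiles(profiles: Sequence[MetageneProfile]) -> MetageneProfile:
    """Element-wise mean profile across genes (for metagene plots)."""
    if not profiles:
        raise ValueError("no profiles to average")
    mats = np.stack([p.concat() for p in profiles])
    nf, nb = len(profiles[0].upstream_flank), len(profiles[0].body)
    m = mats.mean(axis=0)
    return MetageneProfile("metagene", m[:nf], m[nf:nf + nb], m[nf + nb:],
                           log2=profiles[0].log2)


def cohort_matrix(entries: Sequence[tuple[str, MetageneProfile, MetageneProfile, int]],
                  pseudocount: float = 0.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap matrices for a set of genes with read-through.

    ``entries`` holds ``(gene_id, control_profile, test_profile,
    readthrough_length_bp)``. Returns two aligned DataFrames (one row per gene,
    140 columns: 40 upstream / 60 body / 40 downstream): log2 control RPKM, and
    log2 test/control fold change. Rows are ordered by descending read-through
    length (gene_id breaks ties), matching the convention of ordering
    read-through heatmaps by tail length.
    """
    order = sorted(entries, key=lambda e: (-e[3], e[0]))
    nf = 40 if not order else len(order[0][1].upstream_flank)
    nb = 60 if not order else len(order[0][1].body)
    nd = 40 if not order else len(order[0][1].downstream_flank)
    cols = ([f"up{i + 1}" for i in range(nf)] + [f"body{i + 1}" for i in range(nb)]
            + [f"down{i + 1}" for i in range(nd)])
    ctrl_rows, fc_rows, index = [], [], []
    for gid, ctrl, test, _ in order:
        c, t = ctrl.concat(), test.concat()
        ctrl_rows.append(np.log2(c + pseudocount))
        fc_rows.append(np.log2((t + pseudocount) / (c + pseudocount)))
        index.append(gid)
    return (pd.DataFrame(ctrl_rows, index=index, columns=cols),
            pd.DataFrame(fc_rows, index=index, columns=cols))
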