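"""Gene models, annotation containers, and the gene sets the read-through analysis operates on.

All coordinates are 0-based half-open internally. GTF input (1-based inclusive)
is converted at the boundary by the reader; BED12 is used as-is.

A *gene model* here is a single merged transcript per gene: the interval union
of all annotated exons, as produced by merging UCSC-style transcript tables.
The analysis then derives two gene sets from the annotation:

* genes eligible for read-through calling — genes with a clear zone (no other
  annotated gene on either strand) downstream of their transcription
  termination site (TTS);
* tandem pairs — consecutive same-strand genes, where read-through from the
  upstream gene can invade the downstream one.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

Interval = tuple[int, int]


def union_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Merge possibly overlapping/adjacent intervals into a sorted disjoint union."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class GeneModel:
    """Merged single-transcript model of one gene.

    ``tss``/``tts`` are derived from strand: the TSS is the 5' end of the gene
    (``start`` on '+', ``end`` on '-') and the TTS the 3' end.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty exon interval [{a},{b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: exons not sorted/disjoint")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_transcription_order(self) -> tuple[Interval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class TandemPair:
    """Consecutive same-strand gene pair (upstream TTS -> downstream TSS)."""

    upstream_id: str
    downstream_id: str
    chrom: str
    strand: str
    intergenic: Interval  # genomic interval between upstream TTS and downstream TSS

    @property
    def gap_bp(self) -> int:
        return self.intergenic[1] - self.intergenic[0]


@dataclass
class GenomeAnnotation:
    """Collection of merged gene models plus chromosome sizes."""

    genes: dict[str, GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > size:
                raise ValueError(f"{g.gene_id}: [{g.start},{g.end}) outside {g.chrom} (size {size})")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def genes_on(self, chrom: str, strand: str | None = None) -> list[GeneModel]:
        out = [g for g in self.genes.values() if g.chrom == chrom]
        if strand is not None:
            out = [g for g in out if g.strand == strand]
        return sorted(out, key=lambda g: (g.start, g.end, g.gene_id))

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_gtf(cls, path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> "GenomeAnnotation":
        """Read a GTF and merge all exon records per gene_id into one model."""
        import pyranges as pr

        df = pr.read_gtf(str(path)).df
        if "Feature" in df.columns and (df["Feature"] == "exon").any():
            df = df[df["Feature"] == "exon"]
        genes: dict[str, GeneModel] = {}
        for gid, sub in df.groupby("gene_id", sort=True):
            genes[gid] = merge_transcripts(
                gid,
                [
                    (str(sub["Chromosome"].iloc[0]), str(sub["Strand"].iloc[0]),
                     list(zip(sub["Start"], sub["End"])))
                ]
                if sub["Chromosome"].nunique() == 1 and sub["Strand"].nunique() == 1
                else _conflict(gid),
            )
        if chrom_sizes is None:
            chrom_sizes = {}
            for g in genes.values():
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
        return cls(genes, dict(chrom_sizes))

    @classmethod
    def from_bed12(cls, path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> "GenomeAnnotation":
        cols = ["chrom", "start", "end", "name", "score", "strand",
                "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
        per_gene: dict[str, list[tuple[str, str, list[Interval]]]] = {}
        for row in df.itertuples(index=False):
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            exons = [(row.start + s, row.start + s + z) for s, z in zip(starts, sizes)]
            per_gene.setdefault(str(row.name), []).append((str(row.chrom), str(row.strand), exons))
        genes = {gid: merge_transcripts(gid, txs) for gid, txs in sorted(per_gene.items())}
        if chrom_sizes is None:
            chrom_sizes = {}
            for g in genes.values():
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
        return cls(genes, dict(chrom_sizes))

    def to_bed12(self, path: str | Path) -> None:
        rows = []
        for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            sizes = ",".join(str(b - a) for a, b in g.exons) + ","
            starts = ",".join(str(a - g.start) for a, _ in g.exons) + ","
            rows.append((g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                         g.start, g.end, "0,0,0", g.n_exons, sizes, starts))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    def to_gtf(self, path: str | Path, source: str = "rtscan") -> None:
        """Write one transcript with its exons per merged gene (1-based inclusive)."""
        lines = []
        for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.m";'
            lines.append(f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}")
            for a, b in g.exons:
                lines.append(f"{g.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}")
        Path(path).write_text("\n".join(lines) + "\n")


def _conflict(gid: str):
    raise ValueError(f"{gid}: transcripts disagree on chromosome or strand")


def merge_transcripts(gene_id: str, transcripts: Sequence[tuple[str, str, Sequence[Interval]]]) -> GeneModel:
    """Merge transcripts of one gene into a single model by exon interval union.

    Parameters
    ----------
    transcripts : sequence of (chrom, strand, exon interval list)

    Raises
    ------
    ValueError
        If transcripts disagree on chromosome or strand.
    """
    if not transcripts:
        raise ValueError(f"{gene_id}: no transcripts to merge")
    chroms = {t[0] for t in transcripts}
    strands = {t[1] for t in transcripts}
    if len(chroms) != 1 or len(strands) != 1:
        _conflict(gene_id)
    exons = union_intervals(iv for _, _, exs in transcripts for iv in exs)
    return GeneModel(gene_id, chroms.pop(), strands.pop(), exons)


def downstream_interval(gene: GeneModel, length_bp: int,
                        chrom_sizes: Mapping[str, int]) -> tuple[int, int, bool]:
    """Strand-oriented zone of ``length_bp`` immediately 3' of the gene's TTS.

    Returns ``(start, end, truncated)`` in genomic coordinates; traversal order
    is always TTS-proximal to distal (right-to-left for '-' genes). The zone is
    clipped at chromosome bounds and flagged truncated when clipped.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    size = chrom_sizes[gene.chrom]
    if gene.strand == "+":
        start, end = gene.tts, gene.tts + length_bp
    else:
        start, end = gene.tts - length_bp, gene.tts
    cstart, cend = max(0, start), min(size, end)
    return cstart, cend, (cstart, cend) != (start, end)


def eligible_readthrough_genes(annotation: GenomeAnnotation, clear_zone_bp: int = 5000) -> set[str]:
    """Genes whose downstream clear zone contains no other annotated gene.

    A gene is retained iff no other gene, on either strand, overlaps the
    strand-oriented interval of ``clear_zone_bp`` downstream of its TTS.
    Genes whose body overlaps another gene are also dropped: their downstream
    windows would be ambiguous. Zones truncated by a chromosome end are tested
    as truncated.
    """
    if clear_zone_bp <= 0:
        raise ValueError("clear_zone_bp must be positive")
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    keep: set[str] = set()
    for g in annotation:
        tree = trees[g.chrom]
        if any(iv.data != g.gene_id for iv in tree.overlap(g.start, g.end)):
            continue
        zs, ze, _ = downstream_interval(g, clear_zone_bp, annotation.chrom_sizes) \
            if (g.strand == "+" and g.tts < annotation.chrom_sizes[g.chrom]) or \
               (g.strand == "-" and g.tts > 0) else (0, 0, True)
        if zs < ze and any(iv.data != g.gene_id for iv in tree.overlap(zs, ze)):
            continue
        keep.add(g.gene_id)
    return keep


def build_tandem_pairs(annotation: GenomeAnnotation) -> list[TandemPair]:
    """Nearest same-strand downstream neighbour for every gene.

    For each gene the closest gene on the same chromosome and strand whose TSS
    lies 3' of the gene's TTS forms its tandem pair; overlapping genes
    (downstream TSS inside the upstream body) never pair.
    """
    pairs: list[TandemPair] = []
    for chrom in sorted(annotation.chrom_sizes):
        for strand in "+-":
            genes = annotation.genes_on(chrom, strand)
            if len(genes) < 2:
                continue
            if strand == "+":
                tss_sorted = sorted(genes, key=lambda g: g.tss)
                keys = [g.tss for g in tss_sorted]
                for g in genes:
                    i = bisect.bisect_left(keys, g.tts)
                    while i < len(tss_sorted) and tss_sorted[i].gene_id == g.gene_id:
                        i += 1
                    if i < len(tss_sorted):
                        d = tss_sorted[i]
                        pairs.append(TandemPair(g.gene_id, d.gene_id, chrom, strand, (g.tts, d.tss)))
            else:
                tss_sorted = sorted(genes, key=lambda g: g.tss)
                keys = [g.tss for g in tss_sorted]
                for g in genes:
                    i = bisect.bisect_right(keys, g.tts) - 1
                    while i >= 0 and tss_sorted[i].gene_id == g.gene_id:
                        i -= 1
                    if i >= 0:
                        d = tss_sorted[i]
                        pairs.append(TandemPair(g.gene_id, d.gene_id, chrom, strand, (d.tss, g.tts)))
    return sorted(pairs, key=lambda p: (p.chrom, p.intergenic, p.upstream_id))


def pairs_to_tsv(pairs: Iterable[TandemPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.upstream_id, p.downstream_id, p.chrom, p.strand, p.gap_bp) for p in pairs],
        columns=["upstream_id", "downstream_id", "chrom", "strand", "gap_bp"],
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sorted(chrom_sizes.items())))
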