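"""Read-through RNA chimera calling from split-read junction evidence.

A read-through chimera is a transcript joining exons of two tandem genes by
intergenic splicing after a termination failure — no DNA rearrangement is
involved, so only cis, same-chromosome, same-strand junctions between the
genes of a tandem pair are considered. A junction supports a chimera when its
donor coordinate matches an exon 3' boundary of the upstream gene and its
acceptor coordinate matches an exon 5' boundary of the downstream gene
(within a small tolerance for alignment jitter). Calls require at least two
distinct supporting reads and a junction span of at least 100 bp.

Exon coordinate conventions (0-based half-open, in genome coordinates):
donor boundary of an exon is its 3' edge in transcription order (``end`` on
'+', ``start`` on '-'); acceptor boundary is its 5' edge (``start`` on '+',
``end`` on '-').
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation, TandemPair


class JunctionRecord(NamedTuple):
    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    read_id: str


@dataclass(frozen=True)
class ChimeraCall:
    """One supported exon-to-exon junction between the genes of a tandem pair."""

    upstream_id: str
    downstream_id: str
    donor_exon_rank_from_end: int  # 1 = last exon of the upstream gene
    acceptor_exon_rank: int        # 1 = first exon of the downstream gene
    n_supporting_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_supporting_reads < 2:
            raise ValueError("chimera calls require at least two supporting reads")
        if self.donor_exon_rank_from_end < 1 or self.acceptor_exon_rank < 1:
            raise ValueError("exon ranks are 1-based")


def read_junctions(path: str | Path) -> list[JunctionRecord]:
    """Read a tab-delimited junction file (chrom, donor_pos, acceptor_pos, strand, read_id)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "donor_pos", "acceptor_pos", "strand", "read_id"],
                     dtype={"chrom": str, "read_id": str}, comment="#")
    return [JunctionRecord(r.chrom, int(r.donor_pos), int(r.acceptor_pos), r.strand, r.read_id)
            for r in df.itertuples(index=False)]


def write_junctions(junctions: Iterable[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f"{j.chrom}\t{j.donor_pos}\t{j.acceptor_pos}\t{j.strand}\t{j.read_id}\n")


def _boundary_maps(annotation: GenomeAnnotation, pairs: Sequence[TandemPair], tol: int):
    """Position lookup tables for donor/acceptor exon boundaries of tandem pairs."""
    donors: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    acceptors: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
    for pi, pair in enumerate(pairs):
        up = annotation.genes[pair.upstream_id]
        down = annotation.genes[pair.downstream_id]
        up_tx = up.exons_in_transcription_order()
        down_tx = down.exons_in_transcription_order()
        for rank_from_end, exon in enumerate(reversed(up_tx), start=1):
            pos = exon[1] if up.strand == "+" else exon[0]
            for d in range(-tol, tol + 1):
                donors.setdefault((pair.chrom, pair.strand, pos + d), []).append((pi, rank_from_end))
        for rank, exon in enumerate(down_tx, start=1):
            pos = exon[0] if down.strand == "+" else exon[1]
            for d in range(-tol, tol + 1):
                acceptors.setdefault((pair.chrom, pair.strand, pos + d), []).append((pi, rank))
    return donors, acceptors


def call_chimeras(junctions: Sequence[JunctionRecord], annotation: GenomeAnnotation,
                  pairs: Sequence[TandemPair], min_support: int = 2,
                  min_dist_bp: int = 100, boundary_tol: int = 3,
                  sample_id: str = "") -> tuple[list[ChimeraCall], int]:
    """Call read-through chimeras between tandem genes from junction records.

    A junction contributes iff its donor matches an upstream exon 3' boundary
    and its acceptor a downstream exon 5' boundary of the *same* tandem pair
    (+-``boundary_tol`` bp), with span >= ``min_dist_bp``. Supporting reads are
    deduplicated by read_id per junction before counting; groups with fewer
    than ``min_support`` distinct reads are dropped.

    Returns the calls plus the number of junctions matching no annotated
    boundary pair (reported, not called).
    """
    donors, acceptors = _boundary_maps(annotation, pairs, boundary_tol)
    support: dict[tuple[int, int, int], set[str]] = {}
    n_unassigned = 0
    for j in junctions:
        if abs(j.acceptor_pos - j.donor_pos) < min_dist_bp:
            continue
        dhits = donors.get((j.chrom, j.strand, j.donor_pos), [])
        ahits = acceptors.get((j.chrom, j.strand, j.acceptor_pos), [])
        apairs = {pi for pi, _ in ahits}
        matched = False
        for pi, drank in dhits:
            if pi in apairs:
                arank = next(r for q, r in ahits if q == pi)
                support.setdefault((pi, drank, arank), set()).add(j.read_id)
                matched = True
        if not matched:
            n_unassigned += 1
    calls = []
    for (pi, drank, arank), reads in sorted(support.items()):
        if len(reads) >= min_support:
            pair = pairs[pi]
            calls.append(ChimeraCall(pair.upstream_id, pair.downstream_id,
                                     drank, arank, len(reads), sample_id))
    return calls, n_unassigned


def classify_splice_pattern(call: ChimeraCall) -> str:
    """Label a chimera by its exon-pair splice pattern, e.g. ``E[last-1]->E2``."""
    d = call.donor_exon_rank_from_end
    donor = "E[last]" if d == 1 else f"E[last-{d - 1}]"
    return f"{donor}->E{call.acceptor_exon_rank}"


def pattern_histogram(calls: Iterable[ChimeraCall]) -> pd.Series:
    """Event counts per splice pattern over a cohort, most frequent first."""
    labels = [classify_splice_pattern(c) for c in calls]
    return pd.Series(labels, dtype=str).value_counts()


@dataclass
class ChimeraAssociation:
    r: float
    p: float
    n_samples: int
    high_mean: float | None = None
    low_mean: float | None = None


def chimera_readthrough_association(
        burdens: Mapping[str, int], chimera_counts: Mapping[str, int],
        strata: Mapping[str, str] | None = None,
        method: str = "pearson") -> ChimeraAssociation:
    """Cross-sample correlation between read-through burden and chimera count.

    ``burdens`` maps sample_id to its number of read-through genes and
    ``chimera_counts`` to its number of chimera calls; samples missing from
    either map are ignored. With ``strata`` (sample -> 'high'/'low'), per-stratum
    mean chimera counts are also reported.

    Raises
    ------
    ValueError
        With fewer than 3 overlapping samples the correlation is undefined.
    """
    samples = sorted(set(burdens) & set(chimera_counts))
    if len(samples) < 3:
        raise ValueError("chimera/read-through association needs at least 3 samples")
    x = np.array([burdens[s] for s in samples], dtype=float)
    y = np.array([chimera_counts[s] for s in samples], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("association undefined: constant counts across samples")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    res = corr(x, y)
    high_mean = low_mean = None
    if strata is not None:
        hi = [chimera_counts[s] for s in samples if strata.get(s) == "high"]
        lo = [chimera_counts[s] for s in samples if strata.get(s) == "low"]
        high_mean = float(np.mean(hi)) if hi else None
        low_mean = float(np.mean(lo)) if lo else None
    return ChimeraAssociation(float(res.statistic), float(res.pvalue), len(samples),
                              high_mean, low_mean)


def calls_to_dataframe(calls: Sequence[ChimeraCall]) -> pd.DataFrame:
    rows = [{"sample_id": c.sample_id, "upstream_id": c.upstream_id,
             "downstream_id": c.downstream_id,
             "donor_exon_rank_from_end": c.donor_exon_rank_from_end,
             "acceptor_exon_rank": c.acceptor_exon_rank,
             "n_supporting_reads": c.n_supporting_reads,
             "pattern": classify_splice_pattern(c)} for c in calls]
    return pd.DataFrame(rows, columns=["sample_id", "upstream_id", "downstream_id",
                                       "donor_exon_rank_from_end", "acceptor_exon_rank",
                                       "n_supporting_reads", "pattern"])
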