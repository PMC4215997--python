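"""Genome organization: chromosomal distribution, tandem clusters, and
tandem-vs-segmental duplication classification.

A tandem duplication is called when both copies sit on the same chromosome
within a small window (default 20 kb); copies on different chromosomes are
segmental duplicates, classed by the size of the syntenic block that covers
them (> 1 Mb = "large" fragment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import CHROMOSOMES, DuplicatedBlock, GeneRecord

log = logging.getLogger(__name__)

DEFAULT_TANDEM_WINDOW_BP = 20_000
DEFAULT_LARGE_THRESHOLD_BP = 1_000_000


@dataclass(frozen=True)
class ChromSummary:
    counts: dict[str, int]
    occupied_count: int
    absent: tuple[str, ...]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    members: tuple[str, ...]
    span_bp: int

    @property
    def size(self) -> int:
        return len(self.members)


def chromosome_summary(genes: list[GeneRecord]) -> ChromSummary:
    """Count family members per chromosome over the full 20-label set."""
    counts = {c: 0 for c in CHROMOSOMES}
    for g in genes:
        counts[g.chromosome] += 1
    absent = tuple(c for c in CHROMOSOMES if counts[c] == 0)
    return ChromSummary(
        counts=counts,
        occupied_count=len(CHROMOSOMES) - len(absent),
        absent=absent,
    )


def detect_tandem_clusters(
    genes: list[GeneRecord], max_gap_bp: int = DEFAULT_TANDEM_WINDOW_BP
) -> list[GeneCluster]:
    """Group genes into maximal runs of near-adjacent intervals.

    Per chromosome, genes are sorted by normalized start and chained while
    the gap between successive intervals (next start minus previous end) is
    <= ``max_gap_bp``; the boundary is inclusive. Singleton genes come back
    as size-1 clusters, so the clusters partition the input. Cluster span is
    max(end) - min(start) over members.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be non-negative")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        run = [ordered[0]]
        for g in ordered[1:]:
            if g.start - run[-1].end <= max_gap_bp:
                run.append(g)
            else:
                clusters.append(_make_cluster(chrom, run))
                run = [g]
        clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, members: list[GeneRecord]) -> GeneCluster:
    span = max(g.end for g in members) - min(g.start for g in members)
    return GeneCluster(
        chromosome=chrom,
        members=tuple(g.gene_id for g in members),
        span_bp=span,
    )


def classify_duplication(
    pair: tuple[GeneRecord, GeneRecord],
    blocks: list[DuplicatedBlock] | None = None,
    tandem_window_bp: int = DEFAULT_TANDEM_WINDOW_BP,
    large_threshold_bp: int = DEFAULT_LARGE_THRESHOLD_BP,
) -> tuple[str, str]:
    """Classify one duplicate pair as (mode, fragment_class).

    Tandem iff both genes share a chromosome and the inter-gene gap is
    <= ``tandem_window_bp``; otherwise segmental. Segmental pairs take
    fragment class "large" when the covering duplicated block is longer
    than ``large_threshold_bp``, "small" otherwise, and "n/a" (with a
    warning) when no block covers both genes. The result is symmetric in
    the two genes.
    """
    a, b = pair
    if a.chromosome == b.chromosome:
        gap = max(a.start, b.start) - min(a.end, b.end)
        if gap <= tandem_window_bp:
            return ("tandem", "n/a")
    covering = None
    for blk in blocks or []:
        covers_a = blk.covers(a.chromosome, a.start, a.end)
        covers_b = blk.covers(b.chromosome, b.start, b.end)
        if covers_a and covers_b:
            covering = blk
            break
    if covering is None:
        log.warning(
            "segmental pair %s/%s covered by no duplicated block; "
            "fragment class n/a", a.gene_id, b.gene_id,
        )
        return ("segmental", "n/a")
    frag = "large" if covering.length_bp > large_threshold_bp else "small"
    return ("segmental", frag)
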