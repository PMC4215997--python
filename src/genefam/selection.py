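"""Domestication-selection scan from wild vs cultivated allele counts.

A biallelic SNP is called a putative selected site when the allele-count
distribution is *reversed* between the wild and cultivated panels: the
majority allele in one population is the minority allele in the other. A
tied population (equal counts) against a strict majority in the other also
counts as a reversal; two ties do not. Genes carrying one or more selected
sites are candidates for artificial selection during domestication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .model import SnpSite

log = logging.getLogger(__name__)


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


def classify_site(site: SnpSite, min_freq_diff: Optional[float] = None) -> bool:
    """Classify one SNP site as selected (majority reversal) or not.

    With the default strict-sign rule, the verdict is invariant under
    allele relabeling and under swapping the two populations. The optional
    ``min_freq_diff`` additionally requires the allele-frequency difference
    between populations to reach the given magnitude.
    """
    a1, a2 = site.alleles
    w1, w2 = site.wild_counts[a1], site.wild_counts[a2]
    c1, c2 = site.cult_counts[a1], site.cult_counts[a2]
    if w1 + w2 == 0 or c1 + c2 == 0:
        raise ValueError(
            f"{site.gene_id}:{site.position}: a population has no observations"
        )
    s_w, s_c = _sign(w1 - w2), _sign(c1 - c2)
    if s_w * s_c < 0:
        reversed_dist = True
    elif (s_w == 0) != (s_c == 0):
        reversed_dist = True
    else:
        reversed_dist = False
    if reversed_dist and min_freq_diff is not None:
        fdiff = abs(w1 / (w1 + w2) - c1 / (c1 + c2))
        reversed_dist = fdiff >= min_freq_diff
    return reversed_dist


@dataclass(frozen=True)
class GeneSelection:
    gene_id: str
    n_sites_tested: int
    n_sites_selected: int

    @property
    def all_sites_selected(self) -> bool:
        return self.n_sites_tested > 0 and self.n_sites_selected == self.n_sites_tested


@dataclass(frozen=True)
class SelectionSummary:
    per_gene: dict[str, GeneSelection] = field(default_factory=dict)

    @property
    def n_sites_tested(self) -> int:
        return sum(g.n_sites_tested for g in self.per_gene.values())

    @property
    def n_sites_selected(self) -> int:
        return sum(g.n_sites_selected for g in self.per_gene.values())

    @property
    def genes_with_any(self) -> int:
        return sum(1 for g in self.per_gene.values() if g.n_sites_selected >= 1)

    @property
    def genes_with_multiple(self) -> int:
        return sum(1 for g in self.per_gene.values() if g.n_sites_selected >= 2)

    @property
    def genes_with_one(self) -> int:
        return sum(1 for g in self.per_gene.values() if g.n_sites_selected == 1)


def summarize_selection(
    sites: list[SnpSite], min_freq_diff: Optional[float] = None
) -> SelectionSummary:
    """Classify every site and aggregate per gene.

    Sites where either population has zero observed calls are skipped
    with a warning (missing genotype data), not counted as tested.
    """
    tested: dict[str, int] = {}
    selected: dict[str, int] = {}
    for site in sites:
        if sum(site.wild_counts.values()) == 0 or sum(site.cult_counts.values()) == 0:
            log.warning(
                "%s:%d skipped: a population has no observed calls",
                site.gene_id, site.position,
            )
            continue
        tested[site.gene_id] = tested.get(site.gene_id, 0) + 1
        if classify_site(site, min_freq_diff=min_freq_diff):
            selected[site.gene_id] = selected.get(site.gene_id, 0) + 1
    per_gene = {
        g: GeneSelection(
            gene_id=g, n_sites_tested=n, n_sites_selected=selected.get(g, 0)
        )
        for g, n in tested.items()
    }
    return SelectionSummary(per_gene=per_gene)


@dataclass(frozen=True)
class HaplotypePanel:
    """Per-population haplotype strings over one gene's SNP alleles."""

    gene_id: str
    wild: tuple[str, ...]
    cult: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {len(h) for h in self.wild} | {len(h) for h in self.cult}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.gene_id}: haplotype lengths differ: {sorted(lengths)}"
            )


@dataclass(frozen=True)
class HaplotypeCounts:
    gene_id: str
    n_wild: int
    n_cult: int
    private_wild: frozenset
    private_cult: frozenset


def count_haplotypes(panel: HaplotypePanel) -> HaplotypeCounts:
    """Distinct haplotypes per population, plus population-private ones."""
    wild, cult = set(panel.wild), set(panel.cult)
    return HaplotypeCounts(
        gene_id=panel.gene_id,
        n_wild=len(wild),
        n_cult=len(cult),
        private_wild=frozenset(wild - cult),
        private_cult=frozenset(cult - wild),
    )
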