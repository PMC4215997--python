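"""Domain types shared across the gene-family analysis pipeline.

Coordinates are 1-based inclusive, as printed in genome browsers and GFF3.
Gene tables from older genome releases frequently list minus-strand genes
with start > end; :class:`GeneRecord` keeps the raw coordinates verbatim and
additionally carries a strand-normalized interval with ``start <= end``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

#: Soybean (Glycine max) chromosome labels.
CHROMOSOMES = tuple(f"Gm{i:02d}" for i in range(1, 21))


@dataclass(frozen=True)
class GeneRecord:
    """One gene-family member anchored on the genome.

    ``start_raw``/``end_raw`` are the base positions as printed in the source
    table (1-based, inclusive, possibly reversed for minus-strand genes);
    ``start``/``end`` are strand-normalized so ``start <= end``. ``strand``
    is inferred: "-" iff ``start_raw > end_raw``.
    """

    gene_id: str
    locus: str
    chromosome: str
    start_raw: int
    end_raw: int
    aa_length: int
    n_exons: int
    transcript: str = ""

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(
                f"{self.gene_id}: unknown chromosome label {self.chromosome!r}"
            )
        if self.aa_length < 1:
            raise ValueError(f"{self.gene_id}: aa_length must be >= 1")

    @property
    def strand(self) -> str:
        return "-" if self.start_raw > self.end_raw else "+"

    @property
    def start(self) -> int:
        return min(self.start_raw, self.end_raw)

    @property
    def end(self) -> int:
        return max(self.start_raw, self.end_raw)

    @property
    def span_bp(self) -> int:
        """Genomic footprint, end - start + 1 (1-based inclusive)."""
        return self.end - self.start + 1

    def span_consistent_with_protein(self) -> bool:
        """Whether the genomic span can hold the coding sequence.

        A protein of L residues needs at least 3*(L+1) coding bases (CDS plus
        stop). Some published tables carry truncated coordinates that fail
        this check; such rows are kept verbatim and flagged, not corrected.
        """
        return self.span_bp >= 3 * (self.aa_length + 1)


@dataclass(frozen=True)
class DuplicatePair:
    """A duplicated gene pair with its divergence estimates.

    ``mode`` is "tandem" (adjacent copies on one chromosome) or "segmental"
    (copies on different chromosomes within a syntenic block).
    ``fragment_class`` records the size class of the covering duplicated
    block: "large" (> 1 Mb), "small", or "n/a" for tandem pairs or pairs
    with no covering block.
    """

    gene_a: str
    gene_b: str
    mode: str
    fragment_class: str
    ka: float
    ks: float
    ratio: Optional[float]
    date_mya: float

    def __post_init__(self) -> None:
        if self.mode not in ("tandem", "segmental"):
            raise ValueError(f"unknown duplication mode {self.mode!r}")
        if self.fragment_class not in ("large", "small", "n/a"):
            raise ValueError(f"unknown fragment class {self.fragment_class!r}")
        if self.mode == "tandem" and self.fragment_class != "n/a":
            raise ValueError("tandem pairs carry no fragment size class")
        if self.ka < 0 or self.ks < 0:
            raise ValueError("ka and ks must be non-negative")
        if self.date_mya < 0:
            raise ValueError("date_mya must be non-negative")

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None and not math.isnan(self.ratio)


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP with per-population allele counts.

    Both populations must segregate (or be fixed) for the same two alleles.
    ``selected`` is None until the site has been classified.
    """

    gene_id: str
    position: int
    wild_counts: dict[str, int]
    cult_counts: dict[str, int]
    selected: Optional[bool] = None

    def __post_init__(self) -> None:
        for name, counts in (("wild", self.wild_counts), ("cultivar", self.cult_counts)):
            if len(counts) != 2:
                raise ValueError(
                    f"{self.gene_id}:{self.position}: {name} counts must "
                    f"cover exactly 2 alleles, got {sorted(counts)}"
                )
            if any(c < 0 for c in counts.values()):
                raise ValueError(f"{self.gene_id}:{self.position}: negative count")
        if set(self.wild_counts) != set(self.cult_counts):
            raise ValueError(
                f"{self.gene_id}:{self.position}: allele sets differ between "
                f"populations: {sorted(self.wild_counts)} vs {sorted(self.cult_counts)}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return tuple(sorted(self.wild_counts))


@dataclass(frozen=True)
class DuplicatedBlock:
    """A pair of syntenic genomic segments from a duplication event."""

    block_id: str
    chrom_a: str
    span_a: tuple[int, int]
    chrom_b: str
    span_b: tuple[int, int]
    length_bp: int

    def __post_init__(self) -> None:
        for span in (self.span_a, self.span_b):
            if span[0] > span[1]:
                raise ValueError(f"block {self.block_id}: malformed span {span}")
        if self.length_bp <= 0:
            raise ValueError(f"block {self.block_id}: length_bp must be > 0")

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """Whether either segment fully contains the given interval."""
        for bc, (bs, be) in ((self.chrom_a, self.span_a), (self.chrom_b, self.span_b)):
            if bc == chrom and bs <= start and end <= be:
                return True
        return False


@dataclass(frozen=True)
class KaKsConfig:
    """Parameters for Ka/Ks estimation and Ks-based molecular dating.

    ``lam`` is the synonymous substitution rate per synonymous site per
    year; the soybean default is 6.1e-9.
    """

    lam: float = 6.1e-9
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x conditions non-negative expression values.

    ``state`` tracks the normalization applied so far:
    raw_counts -> rpkm -> log2.
    """

    values: pd.DataFrame
    state: str = "raw_counts"

    _STATES = ("raw_counts", "rpkm", "log2")

    def __post_init__(self) -> None:
        if self.state not in self._STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("condition labels must be unique")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SimGroundTruth:
    """Planted truth emitted alongside simulated data."""

    pairs: tuple = ()
    pair_ks: dict = field(default_factory=dict)
    pair_dates_mya: dict = field(default_factory=dict)
    selected_sites: frozenset = frozenset()
    expression_clusters: dict = field(default_factory=dict)
    expressed_genes: frozenset = frozenset()
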