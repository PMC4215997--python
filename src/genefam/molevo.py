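"""Nei–Gojobori (1986) Ka/Ks estimation and Ks-based duplication dating.

The NG86 method counts, for each codon, the fraction of possible point
mutations that are synonymous (synonymous "sites"), and for each codon
pair the synonymous and nonsynonymous differences averaged over all
minimal mutational pathways. Proportions are corrected for multiple hits
with the Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p), which is
undefined once p >= 3/4.

Duplication ages follow the molecular-clock relation T = Ks / (2 lambda),
with the soybean synonymous rate lambda = 6.1e-9 per site per year by
default, reported in million years (Mya).

Conventions: mutations that create a stop codon count as nonsynonymous for
site counting (so S + N is exactly 3x the compared codons), and mutational
pathways passing through a stop codon are excluded from the pathway
average, falling back to all pathways if every one is blocked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from Bio.Data import CodonTable

from .model import DuplicatePair, KaKsConfig
from .phylo import Alignment

GAP_CODON_CHARS = frozenset("-.")


def _codon_maps(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    return fwd, frozenset(table.stop_codons)


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned coding sequences; gaps come in whole-codon units."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    genetic_code: int = 1

    def __post_init__(self) -> None:
        fwd, stops = _codon_maps(self.genetic_code)
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("codon alignment rows have unequal lengths")
        (length,) = lengths
        if length % 3:
            raise ValueError("codon alignment length not divisible by 3")
        for name, row in zip(self.ids, self.rows):
            for c in range(0, length, 3):
                codon = row[c:c + 3]
                gaps = sum(ch in GAP_CODON_CHARS for ch in codon)
                if gaps == 3:
                    continue
                if gaps:
                    raise ValueError(f"{name}: partial-codon gap at {c}")
                if codon in stops and c < length - 3:
                    raise ValueError(f"{name}: internal stop codon at {c}")

    @classmethod
    def from_dict(cls, seqs: dict[str, str], genetic_code: int = 1) -> "CodonAlignment":
        return cls(ids=tuple(seqs), rows=tuple(seqs.values()),
                   genetic_code=genetic_code)

    def row(self, name: str) -> str:
        return self.rows[self.ids.index(name)]


@dataclass(frozen=True)
class KaKsResult:
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    jc_valid_ka: bool
    jc_valid_ks: bool
    n_codons: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def backtranslate_alignment(
    protein_aln: Alignment, cds: dict[str, str], genetic_code: int = 1
) -> CodonAlignment:
    """Thread unaligned CDS onto a protein alignment, codon by codon.

    Each aligned residue is replaced by its source codon and each protein
    gap by a three-base gap. The CDS must translate exactly to the
    ungapped protein row (a trailing stop codon on the CDS is allowed).
    """
    fwd, stops = _codon_maps(genetic_code)
    rows = []
    for name in protein_aln.ids:
        if name not in cds:
            raise ValueError(f"no CDS for {name}")
        nt = cds[name].upper()
        if len(nt) % 3:
            raise ValueError(f"{name}: CDS length not divisible by 3")
        codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        prot = protein_aln.row(name)
        n_residues = sum(ch not in GAP_CODON_CHARS for ch in prot)
        if len(codons) != n_residues:
            raise ValueError(
                f"{name}: CDS has {len(codons)} codons but protein row has "
                f"{n_residues} residues"
            )
        out = []
        it = iter(codons)
        for pos, ch in enumerate(prot):
            if ch in GAP_CODON_CHARS:
                out.append("---")
                continue
            codon = next(it)
            if codon in stops:
                raise ValueError(f"{name}: internal stop codon for residue {pos}")
            aa = fwd.get(codon)
            if aa is None:
                raise ValueError(f"{name}: unrecognized codon {codon!r}")
            if aa != ch.upper():
                raise ValueError(
                    f"{name}: codon {codon} translates to {aa}, protein row "
                    f"has {ch} at column {pos}"
                )
            out.append(codon)
        rows.append("".join(out))
    return CodonAlignment(ids=protein_aln.ids, rows=tuple(rows),
                          genetic_code=genetic_code)


def synonymous_site_fraction(codon: str, genetic_code: int = 1) -> float:
    """NG86 synonymous site count for one codon (between 0 and 3).

    Each position contributes the fraction of its three possible point
    mutations that preserve the amino acid; mutations to stop codons are
    treated as nonsynonymous.
    """
    fwd, _ = _codon_maps(genetic_code)
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if fwd[mutant] == aa and fwd[mutant] != "*":
                syn += 1
        s += syn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str, fwd, stops) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if fwd[nxt] == "*" and nxt != c2:
                through_stop = True
            if fwd[cur] != "*" and fwd[nxt] != "*" and fwd[cur] == fwd[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_avg = sum(p[0] for p in paths) / len(paths)
    nd_avg = sum(p[1] for p in paths) / len(paths)
    return sd_avg, nd_avg


def ng86_kaks(
    caln: CodonAlignment,
    pair: tuple[str, str],
    config: KaKsConfig = KaKsConfig(),
) -> KaKsResult:
    """NG86 Ka/Ks for one pair of rows in a codon alignment.

    Codon columns with a gap in either row are dropped (pairwise deletion).
    ``ratio`` is None when Ks is zero or either rate is undefined because
    its proportion reached the Jukes–Cantor singularity (p >= 3/4).
    """
    fwd, stops = _codon_maps(config.genetic_code)
    row_a, row_b = caln.row(pair[0]), caln.row(pair[1])
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for c in range(0, len(row_a), 3):
        ca, cb = row_a[c:c + 3], row_b[c:c + 3]
        if any(ch in GAP_CODON_CHARS for ch in ca + cb):
            continue
        n_codons += 1
        s_a += synonymous_site_fraction(ca, config.genetic_code)
        s_b += synonymous_site_fraction(cb, config.genetic_code)
        dsd, dnd = _pathway_diffs(ca, cb, fwd, stops)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise ValueError(f"no comparable codons between {pair[0]} and {pair[1]}")
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks, valid_ks = _jukes_cantor(ps)
    ka, valid_ka = _jukes_cantor(pn)
    ratio = None
    if valid_ka and valid_ks and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio,
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
        jc_valid_ka=valid_ka, jc_valid_ks=valid_ks, n_codons=n_codons,
    )


def _jukes_cantor(p: float) -> tuple[Optional[float], bool]:
    if p >= 0.75:
        return None, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), True


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-away-from-zero, the convention printed tables use."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def date_duplication(ks: float, config: KaKsConfig = KaKsConfig()) -> float:
    """Duplication age in Mya from Ks under T = Ks / (2 lambda)."""
    if ks < 0:
        raise ValueError("ks must be non-negative")
    return ks / (2.0 * config.lam) / 1e6


@dataclass(frozen=True)
class PairSummary:
    n_pairs: int
    n_segmental: int
    n_tandem: int
    n_large: int
    n_small: int
    ks_min: Optional[float]
    ks_max: Optional[float]
    ks_mean: Optional[float]
    date_min: Optional[float]
    date_max: Optional[float]
    date_mean: Optional[float]
    n_segmental_ratio_below: int
    n_segmental_ratio_at_or_above: int
    n_tandem_ratio_at_or_above: int
    ratio_threshold: float


def summarize_pairs(
    pairs: list[DuplicatePair], ratio_threshold: float = 0.3
) -> PairSummary:
    """Aggregate Ks, dates, and Ka/Ks ratio classes over duplicate pairs."""
    seg = [p for p in pairs if p.mode == "segmental"]
    tan = [p for p in pairs if p.mode == "tandem"]
    ks_vals = [p.ks for p in pairs]
    dates = [p.date_mya for p in pairs]
    return PairSummary(
        n_pairs=len(pairs),
        n_segmental=len(seg),
        n_tandem=len(tan),
        n_large=sum(p.fragment_class == "large" for p in pairs),
        n_small=sum(p.fragment_class == "small" for p in pairs),
        ks_min=min(ks_vals) if ks_vals else None,
        ks_max=max(ks_vals) if ks_vals else None,
        ks_mean=sum(ks_vals) / len(ks_vals) if ks_vals else None,
        date_min=min(dates) if dates else None,
        date_max=max(dates) if dates else None,
        date_mean=sum(dates) / len(dates) if dates else None,
        n_segmental_ratio_below=sum(
            1 for p in seg if p.ratio_defined and p.ratio < ratio_threshold
        ),
        n_segmental_ratio_at_or_above=sum(
            1 for p in seg if p.ratio_defined and p.ratio >= ratio_threshold
        ),
        n_tandem_ratio_at_or_above=sum(
            1 for p in tan if p.ratio_defined and p.ratio >= ratio_threshold
        ),
        ratio_threshold=ratio_threshold,
    )
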