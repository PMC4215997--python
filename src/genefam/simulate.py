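"""Synthetic-data generators with known ground truth.

These emulate the three external data sources the real study drew on —
genome-wide gene-family sequences (for Ka/Ks and phylogeny), resequencing
SNP panels of wild vs cultivated accessions (for the selection scan), and
multi-tissue RNA-seq matrices (for expression clustering) — so every
pipeline stage can be exercised end-to-end with planted truth.

Defaults follow the study system: 69 family members, panels of 17 wild
and 14 cultivated accessions, a synonymous rate of 6.1e-9 per site per
year, and duplication ages near the ~13 Mya Glycine-specific genome
duplication.

Codon evolution is a uniform-rate Markov jump process: point mutations
are proposed at rate lambda per nucleotide site per year, proposals
creating stop codons are rejected, synonymous proposals are always
accepted and nonsynonymous ones are accepted with probability equal to
the target Ka/Ks. Under this scheme the expected synonymous divergence of
a pair duplicated T years ago is E[Ks] = 2*lambda*T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq

from .model import (
    CHROMOSOMES,
    DuplicatedBlock,
    GeneRecord,
    ExpressionMatrix,
    SimGroundTruth,
    SnpSite,
)
from .phylo import DistanceMatrix

import pandas as pd

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_AA = dict(_TABLE.forward_table)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generators."""

    seed: int = 0
    n_genes: int = 69
    duplication_times_mya: tuple[float, ...] = (9.0, 13.0, 16.0)
    lam: float = 6.1e-9
    target_kaks: float = 0.3
    n_codons: int = 500
    n_wild: int = 17
    n_cult: int = 14
    n_snp_sites: int = 38
    fraction_selected: float = 0.5
    contrast: float = 0.8
    null_major_freq: float = 0.7
    n_tissues: int = 14
    n_clusters: int = 5
    signal: float = 20.0
    noise: float = 0.2
    n_unexpressed: int = 34

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_selected <= 1.0:
            raise ValueError("fraction_selected must be in [0, 1]")
        for name in ("n_genes", "n_codons", "n_wild", "n_cult",
                     "n_snp_sites", "n_tissues", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


def _rng(cfg: SimConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random coding sequence of sense codons (no stops), ATG-initiated."""
    codons = ["ATG"] + [
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    ]
    return "".join(codons)


def evolve_cds(
    seq: str, years: float, lam: float, omega: float, rng: np.random.Generator
) -> str:
    """Evolve a CDS for ``years`` under the rejection-sampling mutation model."""
    bases = list(seq)
    n_events = rng.poisson(lam * years * len(bases))
    positions = rng.integers(0, len(bases), size=n_events)
    choices = rng.integers(0, 3, size=n_events)
    accepts = rng.random(size=n_events)
    for pos, choice, u in zip(positions, choices, accepts):
        old = bases[pos]
        alt = [b for b in "ACGT" if b != old][choice]
        c0 = 3 * (pos // 3)
        codon = bases[c0:c0 + 3]
        mutant = codon.copy()
        mutant[pos - c0] = alt
        mut_codon = "".join(mutant)
        if mut_codon in _STOPS:
            continue
        if _AA["".join(codon)] != _AA[mut_codon] and u >= omega:
            continue
        bases[pos] = alt
    return "".join(bases)


def simulate_family(cfg: SimConfig):
    """Simulate duplicate gene pairs with known duplication ages.

    Each scheduled time T (Mya) produces one pair: an independent random
    ancestor duplicated T Mya, with both copies evolved separately since.
    Pairs are laid out on the genome so that odd-numbered pairs are tandem
    (adjacent, same chromosome) and even-numbered ones segmental (different
    chromosomes, each covered by an emitted duplicated block). Extra
    singleton genes pad the family to ``n_genes``.

    Returns (cds, proteins, gene_records, blocks, ground_truth).
    """
    rng = _rng(cfg)
    cds: dict[str, str] = {}
    records: list[GeneRecord] = []
    blocks: list[DuplicatedBlock] = []
    pairs = []
    pair_ks = {}
    pair_dates = {}

    for i, t_mya in enumerate(cfg.duplication_times_mya):
        years = t_mya * 1e6
        ancestor = random_cds(cfg.n_codons, rng)
        name_a, name_b = f"simgene{i + 1}a", f"simgene{i + 1}b"
        cds[name_a] = evolve_cds(ancestor, years, cfg.lam, cfg.target_kaks, rng)
        cds[name_b] = evolve_cds(ancestor, years, cfg.lam, cfg.target_kaks, rng)
        pairs.append((name_a, name_b))
        pair_ks[(name_a, name_b)] = 2.0 * cfg.lam * years
        pair_dates[(name_a, name_b)] = t_mya
        tandem = i % 2 == 0
        chrom_a = CHROMOSOMES[(2 * i) % len(CHROMOSOMES)]
        start_a = 1_000_000 + 100_000 * i
        end_a = start_a + 3 * cfg.n_codons - 1
        if tandem:
            chrom_b, start_b = chrom_a, end_a + 4_000
        else:
            chrom_b = CHROMOSOMES[(2 * i + 1) % len(CHROMOSOMES)]
            start_b = start_a
            length = 2_000_000 if i % 4 == 1 else 500_000
            blocks.append(DuplicatedBlock(
                block_id=f"simblock{i + 1}",
                chrom_a=chrom_a, span_a=(start_a - 200_000, end_a + 200_000),
                chrom_b=chrom_b,
                span_b=(start_b - 200_000, start_b + 3 * cfg.n_codons + 200_000),
                length_bp=length,
            ))
        end_b = start_b + 3 * cfg.n_codons - 1
        for name, chrom, s, e in (
            (name_a, chrom_a, start_a, end_a), (name_b, chrom_b, start_b, end_b)
        ):
            records.append(GeneRecord(
                gene_id=name, locus=name, chromosome=chrom,
                start_raw=s, end_raw=e, aa_length=cfg.n_codons, n_exons=1,
            ))

    i = 0
    while len(cds) < cfg.n_genes:
        name = f"simsingleton{i + 1}"
        cds[name] = random_cds(cfg.n_codons, rng)
        chrom = CHROMOSOMES[(7 * i + 3) % len(CHROMOSOMES)]
        start = 30_000_000 + 1_000_000 * i
        records.append(GeneRecord(
            gene_id=name, locus=name, chromosome=chrom,
            start_raw=start, end_raw=start + 3 * cfg.n_codons - 1,
            aa_length=cfg.n_codons, n_exons=1,
        ))
        i += 1

    proteins = {name: str(Seq(s).translate()) for name, s in cds.items()}
    truth = SimGroundTruth(
        pairs=tuple(pairs), pair_ks=pair_ks, pair_dates_mya=pair_dates,
    )
    return cds, proteins, records, blocks, truth


def simulate_pair(
    t_mya: float, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """One duplicate CDS pair diverged for ``t_mya``; E[Ks] = 2*lam*T."""
    years = t_mya * 1e6
    ancestor = random_cds(cfg.n_codons, rng)
    return (
        evolve_cds(ancestor, years, cfg.lam, cfg.target_kaks, rng),
        evolve_cds(ancestor, years, cfg.lam, cfg.target_kaks, rng),
    )


_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


def simulate_snp_panel(cfg: SimConfig):
    """Wild/cultivar allele-count panels with planted reversal sites.

    Selected sites put the wild major-allele frequency at
    0.5 + contrast/2 and the cultivar frequency of the same allele at
    0.5 - contrast/2 (opposite majority); neutral sites share one major
    frequency in both panels. Counts are binomial draws over the panel
    sizes. Returns (sites, ground_truth).
    """
    rng = _rng(cfg)
    n_selected = int(round(cfg.fraction_selected * cfg.n_snp_sites))
    sites = []
    truth_keys = set()
    for s in range(cfg.n_snp_sites):
        gene = f"simgene{s % max(1, cfg.n_snp_sites // 3) + 1}"
        pos = 1_000_000 + 1_000 * s
        a1, a2 = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
        planted = s < n_selected
        if planted:
            p_wild = 0.5 + cfg.contrast / 2.0
            p_cult = 0.5 - cfg.contrast / 2.0
            truth_keys.add((gene, pos))
        else:
            p_wild = p_cult = cfg.null_major_freq
        k_w = int(rng.binomial(cfg.n_wild, p_wild))
        k_c = int(rng.binomial(cfg.n_cult, p_cult))
        sites.append(SnpSite(
            gene_id=gene, position=pos,
            wild_counts={a1: k_w, a2: cfg.n_wild - k_w},
            cult_counts={a1: k_c, a2: cfg.n_cult - k_c},
        ))
    truth = SimGroundTruth(selected_sites=frozenset(truth_keys))
    return sites, truth


def simulate_expression(cfg: SimConfig):
    """Tissue-specific expression clusters with planted labels.

    Expressed genes are split into ``n_clusters`` groups; group c has mean
    ``signal`` in its own contiguous tissue block and 1 elsewhere, with
    multiplicative lognormal noise of sigma ``noise``. ``n_unexpressed``
    genes are all-zero rows. Returns (matrix, ground_truth).
    """
    rng = _rng(cfg)
    n_expressed = cfg.n_genes - cfg.n_unexpressed
    if n_expressed < cfg.n_clusters:
        raise ValueError("fewer expressed genes than clusters")
    genes = [f"simgene{i + 1}" for i in range(cfg.n_genes)]
    tissues = [f"tissue{j + 1}" for j in range(cfg.n_tissues)]
    bounds = np.linspace(0, cfg.n_tissues, cfg.n_clusters + 1).astype(int)
    values = np.zeros((cfg.n_genes, cfg.n_tissues))
    labels = {}
    for i in range(n_expressed):
        c = i % cfg.n_clusters
        labels[genes[i]] = c + 1
        mean = np.ones(cfg.n_tissues)
        mean[bounds[c]:bounds[c + 1]] = cfg.signal
        if cfg.noise > 0:
            mean = mean * rng.lognormal(0.0, cfg.noise, size=cfg.n_tissues)
        values[i] = mean
    df = pd.DataFrame(values, index=genes, columns=tissues)
    truth = SimGroundTruth(
        expression_clusters=labels,
        expressed_genes=frozenset(genes[:n_expressed]),
    )
    return ExpressionMatrix(values=df, state="rpkm"), truth


def random_additive_tree(
    n_leaves: int, rng: np.random.Generator,
    min_branch: float = 0.1, max_branch: float = 1.0,
):
    """A random unrooted binary tree and its additive distance matrix.

    Built by sequentially attaching leaves to random edges with branch
    lengths uniform in [min_branch, max_branch]; the returned matrix holds
    exact leaf-to-leaf path lengths, so neighbor joining should recover
    the generating topology exactly.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    names = [f"t{i + 1}" for i in range(n_leaves)]

    def bl():
        return float(rng.uniform(min_branch, max_branch))

    leaves = [Clade(name=names[i], branch_length=bl()) for i in range(3)]
    root = Clade(clades=leaves[:3], branch_length=0.0)
    tree = Tree(root=root, rooted=False)
    for i in range(3, n_leaves):
        # pick a random non-root clade and insert a new node on its edge
        clades = [c for c in tree.find_clades() if c is not root]
        target = clades[int(rng.integers(0, len(clades)))]
        parent = tree.root
        path = tree.get_path(target)
        parent = path[-2] if len(path) > 1 else tree.root
        split = rng.uniform(0.2, 0.8) * target.branch_length
        new_leaf = Clade(name=names[i], branch_length=bl())
        inner = Clade(
            clades=[target, new_leaf],
            branch_length=target.branch_length - split,
        )
        target.branch_length = split
        parent.clades[parent.clades.index(target)] = inner

    terminals = tree.get_terminals()
    depths = tree.depths()
    n = len(terminals)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.common_ancestor(terminals[i], terminals[j])
            d = depths[terminals[i]] + depths[terminals[j]] - 2 * depths[mrca]
            m[i, j] = m[j, i] = d
    ids = tuple(t.name for t in terminals)
    return tree, DistanceMatrix(ids=ids, matrix=m, method="additive")
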