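"""Phylogenetics: p-distance, neighbor joining, bootstrap, paralog pairs.

The tree machinery follows what MEGA-style family studies do: pairwise
p-distances with pairwise gap deletion, Saitou–Nei neighbor joining, and
nonparametric bootstrap over alignment columns with supports attached to
the internal bipartitions of the point-estimate tree. Trees are Biopython
``Bio.Phylo`` objects, so Newick round-trips come for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

PathLike = Union[str, Path]

GAP_CHARS = frozenset("-.")

_ROMAN = ("I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII "
          "XVIII XIX XX").split()


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else str(i + 1)


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: ordered ids with equal-length rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("alignment ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Alignment":
        return cls(ids=tuple(seqs), rows=tuple(seqs.values()))

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.ids.index(name)]

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.length, size=self.length)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(ids=self.ids, rows=rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray
    method: str = "p-distance"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def _pair_stats(row_a: str, row_b: str) -> tuple[int, int]:
    """(comparable sites, mismatches) under pairwise gap deletion."""
    comparable = mismatches = 0
    for x, y in zip(row_a, row_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    return comparable, mismatches


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distance: mismatches / compared sites, gaps excluded."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable, mismatches = _pair_stats(aln.rows[i], aln.rows[j])
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            d[i, j] = d[j, i] = mismatches / comparable
    return DistanceMatrix(ids=aln.ids, matrix=d, method="p-distance")


def percent_identity(aln: Alignment, pair: tuple[str, str]) -> float:
    """Percent identical sites for one pair, pairwise gap deletion."""
    comparable, mismatches = _pair_stats(aln.row(pair[0]), aln.row(pair[1]))
    if comparable == 0:
        raise ValueError(f"no comparable sites between {pair[0]} and {pair[1]}")
    return 100.0 * (comparable - mismatches) / comparable


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Q-matrix ties break on the lowest (row, column) index pair so results
    are platform-independent. Negative branch lengths are clamped to zero
    with the deficit moved onto the sibling branch, preserving the joined
    pair's summed length. The returned tree is unrooted, represented with
    a trifurcating root-equivalent node.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Clade] = [Clade(name=name) for name in d.ids]
    dist = d.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) pair among the minima
        flat = np.argmin(q)
        qmin = q.flat[flat]
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i_sub, j_sub = min((int(a), int(b)) for a, b in ties if a < b)
        i, j = active[i_sub], active[j_sub]

        li = 0.5 * sub[i_sub, j_sub] + (r[i_sub] - r[j_sub]) / (2 * (m - 2))
        lj = sub[i_sub, j_sub] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = Clade(clades=[child_i, child_j])

        # distances from the new node to every other active node
        dnew = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        dist = np.vstack([dist, dnew])
        dnew_col = np.append(dnew, 0.0)
        dist = np.column_stack([dist, dnew_col])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # resolve the final three nodes around a trifurcating hub
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.branch_length = length
    root = Clade(clades=[nodes[a], nodes[b], nodes[c]], branch_length=0.0)
    return Tree(root=root, rooted=False)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def leaf_names(tree: Tree) -> list[str]:
    return [t.name for t in tree.get_terminals()]


def bipartitions(tree: Tree) -> dict[int, frozenset]:
    """Canonical nontrivial bipartitions keyed by id() of the inner clade.

    Each internal (non-root) clade defines the split {leaves below it} vs
    the rest; the canonical form is the smaller side (ties broken by
    sorted leaf names), so it is rooting-invariant.
    """
    all_leaves = frozenset(leaf_names(tree))
    out = {}
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        below = frozenset(t.name for t in clade.get_terminals())
        if len(below) < 2 or len(all_leaves - below) < 2:
            continue
        out[id(clade)] = _canonical_split(below, all_leaves)
    return out


def _canonical_split(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def same_topology(t1: Tree, t2: Tree) -> bool:
    """Unrooted-topology equality over shared leaf sets via bipartitions."""
    if set(leaf_names(t1)) != set(leaf_names(t2)):
        return False
    return set(bipartitions(t1).values()) == set(bipartitions(t2).values())


def bootstrap_support(
    aln: Alignment, n_reps: int = 1000, seed: Optional[int] = None
) -> Tree:
    """NJ point tree with column-bootstrap supports on internal nodes.

    Supports are the percentage of replicate trees containing each internal
    bipartition of the point tree; with a fixed seed the result is exactly
    reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(p_distance(aln))
    splits = bipartitions(tree)
    hits = {key: 0 for key in splits}
    wanted = {}
    for key, split in splits.items():
        wanted.setdefault(split, []).append(key)
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_splits = set(bipartitions(neighbor_joining(p_distance(rep))).values())
        for split, keys in wanted.items():
            if split in rep_splits:
                for key in keys:
                    hits[key] += 1
    for clade in tree.get_nonterminals():
        if id(clade) in hits:
            clade.confidence = 100.0 * hits[id(clade)] / n_reps
    return tree


def extract_paralog_pairs(
    tree: Tree, min_support: float = 50.0
) -> list[tuple[str, str]]:
    """Leaf pairs that are mutual sisters (cherries) with adequate support.

    A cherry's joining node must carry bootstrap support >= ``min_support``
    (nodes without a support value pass). Cherries are disjoint by
    construction, so each leaf appears in at most one pair.
    """
    pairs = []
    for clade in tree.get_nonterminals():
        if len(clade.clades) == 2 and all(c.is_terminal() for c in clade.clades):
            if clade.confidence is not None and clade.confidence < min_support:
                continue
            a, b = sorted(c.name for c in clade.clades)
            pairs.append((a, b))
    return sorted(pairs)


def _clade_height(clade: Clade) -> float:
    if clade.is_terminal():
        return 0.0
    return max((c.branch_length or 0.0) + _clade_height(c) for c in clade.clades)


def assign_subgroups(tree: Tree, k: int) -> dict[str, str]:
    """Cut the tree into k subgroups at its deepest internal edges.

    Clusters start from the root clade and are split greedily: at each step
    the cluster with the greatest height (longest path down to its leaves)
    is divided at its root node, until k clusters exist. Ties break on
    traversal order. Labels are Roman numerals assigned in order of first
    leaf appearance along the tree's leaf ordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    leaves = leaf_names(tree)
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds leaf count {len(leaves)}")

    order = {id(c): i for i, c in enumerate(tree.find_clades())}
    # a cluster is a list of clades; its leaves are the union below them
    clusters: list[list[Clade]] = [[tree.root]]

    def height(cluster: list[Clade]) -> float:
        return max(_clade_height(c) for c in cluster)

    def splittable(cluster: list[Clade]) -> bool:
        return len(cluster) > 1 or not cluster[0].is_terminal()

    while len(clusters) < k:
        candidates = [c for c in clusters if splittable(c)]
        best = max(
            candidates,
            key=lambda c: (height(c), -min(order[id(x)] for x in c)),
        )
        clusters.remove(best)
        if len(best) > 1:
            # previously lumped siblings: peel off the tallest clade
            tallest = max(best, key=lambda c: (_clade_height(c), -order[id(c)]))
            rest = [c for c in best if c is not tallest]
            clusters.extend([[tallest], rest])
        else:
            children = list(best[0].clades)
            need = k - len(clusters)
            if len(children) - 1 <= need:
                clusters.extend([c] for c in children)
            else:
                children.sort(key=lambda c: (-_clade_height(c), order[id(c)]))
                for c in children[:need]:
                    clusters.append([c])
                clusters.append(children[need:])

    cluster_leaves = []
    for cluster in clusters:
        names = []
        for clade in cluster:
            names.extend(t.name for t in clade.get_terminals())
        cluster_leaves.append(names)
    cluster_leaves.sort(key=lambda names: min(leaves.index(n) for n in names))
    labels = {}
    for i, names in enumerate(cluster_leaves):
        for name in names:
            labels[name] = _roman(i)
    return labels


def write_newick(tree: Tree, path: PathLike) -> None:
    Phylo.write(tree, str(path), "newick")


def read_newick(path: PathLike) -> Tree:
    return Phylo.read(str(path), "newick")


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (patristic distances)."""
    terminals = tree.get_terminals()
    names = tuple(t.name for t in terminals)
    depths = tree.depths()
    n = len(terminals)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.common_ancestor(terminals[i], terminals[j])
            dij = depths[terminals[i]] + depths[terminals[j]] - 2 * depths[mrca]
            m[i, j] = m[j, i] = dij
    return DistanceMatrix(ids=names, matrix=m, method="patristic")
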