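"""p-distance, neighbor joining, bootstrap, paralog pairs, subgroups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam import phylo
from genefam.simulate import SimConfig, random_additive_tree, simulate_family


def aln(**seqs):
    return phylo.Alignment.from_dict(seqs)


class TestPDistance:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "TGCA", 1.0),
        ("AAAAAAAA", "AAAAAATT", 0.25),
        ("AC-T", "ACGT", 0.0),           # gap column excluded
    ])
    def test_pairwise_values(self, a, b, expected):
        d = phylo.p_distance(aln(x=a, y=b))
        assert d.get("x", "y") == pytest.approx(expected)

    def test_zero_comparable_sites_error(self):
        with pytest.raises(ValueError, match="x.*y|y.*x"):
            phylo.p_distance(aln(x="A--A", y="-GG-"))

    def test_symmetry_bounds(self):
        a = aln(x="ACGTACGT", y="ACGAACGA", z="TTTTACGT")
        d = phylo.p_distance(a)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.all((d.matrix >= 0) & (d.matrix <= 1))
        assert np.allclose(np.diag(d.matrix), 0)


class TestPercentIdentity:
    def test_identical(self):
        assert phylo.percent_identity(aln(x="ACGT", y="ACGT"), ("x", "y")) == 100.0

    def test_three_of_four(self):
        assert phylo.percent_identity(aln(x="ACGT", y="ACGA"), ("x", "y")) == 75.0

    def test_disjoint_gaps_error(self):
        with pytest.raises(ValueError):
            phylo.percent_identity(aln(x="AC--", y="--GT"), ("x", "y"))


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        ids = ("A", "B", "C")
        m = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids=ids, matrix=m))
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        # three-point formulas: l_A = (dAB + dAC - dBC)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_four_taxon_additive_matrix(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        m = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(ids=ids, matrix=m))
        splits = set(phylo.bipartitions(tree).values())
        assert frozenset({"A", "B"}) in splits
        back = phylo.tree_distance_matrix(tree)
        idx = [back.ids.index(i) for i in ids]
        assert np.allclose(back.matrix[np.ix_(idx, idx)], m)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(phylo.DistanceMatrix(
                ids=("A", "B"), matrix=np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_tree_recovery(self, seed):
        """NJ reproduces random additive trees (4-12 leaves) exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        true_tree, dm = random_additive_tree(n, rng)
        nj = phylo.neighbor_joining(dm)
        assert phylo.same_topology(true_tree, nj)
        back = phylo.tree_distance_matrix(nj)
        idx = [back.ids.index(i) for i in dm.ids]
        assert np.allclose(back.matrix[np.ix_(idx, idx)], dm.matrix, atol=1e-9)


CLEAN = dict(A="AAAAAAAACC", B="AAAAAAAACC", C="GGGGGGGGTT",
             D="GGGGGGGGTT", E="ACACACACGG")


class TestBootstrap:
    def test_clean_clades_get_full_support(self):
        tree = phylo.bootstrap_support(aln(**CLEAN), n_reps=25, seed=0)
        supports = [c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self):
        tree = phylo.bootstrap_support(aln(**CLEAN), n_reps=1, seed=3)
        supports = {c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None}
        assert supports <= {0.0, 100.0}

    def test_seed_reproducibility(self):
        seqs = dict(A="ACGGTTAACC", B="ACGGTTAACG", C="TTGGAACCGG",
                    D="TTGGAACCGA", E="ACAGTTAACC")
        t1 = phylo.bootstrap_support(aln(**seqs), n_reps=30, seed=11)
        t2 = phylo.bootstrap_support(aln(**seqs), n_reps=30, seed=11)
        s1 = sorted(c.confidence for c in t1.get_nonterminals()
                    if c.confidence is not None)
        s2 = sorted(c.confidence for c in t2.get_nonterminals()
                    if c.confidence is not None)
        assert s1 == s2


class TestParalogPairs:
    def test_support_threshold(self):
        from io import StringIO

        from Bio import Phylo
        nwk = "((A:1,B:1)95:1,(C:1,D:1)40:1,E:2);"
        tree = Phylo.read(StringIO(nwk), "newick")
        assert phylo.extract_paralog_pairs(tree, 50) == [("A", "B")]

    def test_star_tree_has_no_pairs(self):
        from io import StringIO

        from Bio import Phylo
        tree = Phylo.read(StringIO("(A:1,B:1,C:1,D:1);"), "newick")
        assert phylo.extract_paralog_pairs(tree) == []

    def test_planted_duplications_recovered(self):
        cfg = SimConfig(seed=3, duplication_times_mya=(5.0, 6.0, 7.0),
                        n_genes=6, n_codons=200)
        _, proteins, _, _, truth = simulate_family(cfg)
        tree = phylo.neighbor_joining(
            phylo.p_distance(phylo.Alignment.from_dict(proteins)))
        found = phylo.extract_paralog_pairs(tree, min_support=0)
        assert set(found) == {tuple(sorted(p)) for p in truth.pairs}


class TestSubgroups:
    def _tree(self):
        cfg = SimConfig(seed=3, duplication_times_mya=(5.0, 6.0, 7.0),
                        n_genes=6, n_codons=200)
        _, proteins, _, _, truth = simulate_family(cfg)
        tree = phylo.neighbor_joining(
            phylo.p_distance(phylo.Alignment.from_dict(proteins)))
        return tree, truth

    def test_k1_single_label(self):
        tree, _ = self._tree()
        labels = phylo.assign_subgroups(tree, 1)
        assert len(set(labels.values())) == 1

    def test_k_equals_leaves_singletons(self):
        tree, _ = self._tree()
        labels = phylo.assign_subgroups(tree, 6)
        assert len(set(labels.values())) == 6

    def test_k_too_large(self):
        tree, _ = self._tree()
        with pytest.raises(ValueError):
            phylo.assign_subgroups(tree, 7)

    def test_planted_clades_recovered(self):
        tree, truth = self._tree()
        labels = phylo.assign_subgroups(tree, 3)
        groups = {frozenset(n for n, l in labels.items() if l == lab)
                  for lab in set(labels.values())}
        assert groups == {frozenset(p) for p in truth.pairs}


class TestNewickRoundTrip:
    def test_topology_lengths_supports_survive(self, tmp_path):
        tree = phylo.bootstrap_support(aln(**CLEAN), n_reps=20, seed=2)
        path = tmp_path / "t.nwk"
        phylo.write_newick(tree, path)
        back = phylo.read_newick(path)
        assert phylo.same_topology(tree, back)
        d1, d2 = phylo.tree_distance_matrix(tree), phylo.tree_distance_matrix(back)
        idx = [d2.ids.index(i) for i in d1.ids]
        assert np.allclose(d2.matrix[np.ix_(idx, idx)], d1.matrix, atol=1e-6)
        s1 = sorted(c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None)
        s2 = sorted(float(c.confidence) for c in back.get_nonterminals()
                    if c.confidence is not None)
        assert np.allclose(s1, s2)


@given(st.integers(0, 10_000))
@settings(max_examples=15, deadline=None)
def test_nj_additive_recovery_property(seed):
    """Property: NJ is exact on additive matrices of random trees."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    true_tree, dm = random_additive_tree(n, rng)
    nj = phylo.neighbor_joining(dm)
    assert phylo.same_topology(true_tree, nj)
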