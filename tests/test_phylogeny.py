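"""p-distance, neighbor joining, bootstrap, and newick serialization."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkDM
from skbio.tree import nj as skbio_nj

from erfkit import phylogeny as phy
from erfkit import synthetic as syn


def random_additive_tree(n_taxa: int, rng) -> tuple[dict, phy.TreeNode]:
    """Random unrooted binary tree with branch lengths in [0.1, 1];
    returns (leaf-to-leaf distances, the tree)."""
    from skbio import TreeNode
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    root = phy.TreeNode(children=nodes)
    dists = {}
    for x, y in itertools.combinations(sorted(t.name for t in root.tips()), 2):
        dists[(x, y)] = root.find(x).distance(root.find(y))
    return dists, root


def dm_from_dists(dists) -> phy.DistanceMatrix:
    ids = sorted({x for pair in dists for x in pair})
    n = len(ids)
    m = np.zeros((n, n))
    for (x, y), d in dists.items():
        i, j = ids.index(x), ids.index(y)
        m[i, j] = m[j, i] = d
    return phy.DistanceMatrix(ids, m)


class TestPDistance:
    def test_identical_sequences_zero(self):
        d = phy.pdistance_matrix({"a": "ACDEF", "b": "ACDEF"})
        assert d.matrix[0, 1] == 0.0

    def test_hand_counted_mismatch(self):
        d = phy.pdistance_matrix({"a": "ACDEF", "b": "ACDFF"})
        assert d.matrix[0, 1] == pytest.approx(0.2)

    def test_pairwise_deletion_skips_gap_columns(self):
        d = phy.pdistance_matrix({"a": "AC-EF", "b": "ACDEF"})
        assert d.matrix[0, 1] == 0.0
        assert d.site_counts[0, 1] == 4

    def test_zero_shared_columns_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            phy.pdistance_matrix({"a": "AC--", "b": "--DE"})

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            phy.pdistance_matrix({"a": "ACDE", "b": "ACD"})

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        aln = {}
        for i in range(6):
            seq = list(syn.random_protein(rng, 40))
            for p in rng.choice(40, 6, replace=False):
                seq[p] = "-"
            aln[f"s{i}"] = "".join(seq)
        got = phy.pdistance_matrix(aln)
        ids = list(aln)
        for i, j in itertools.combinations(range(len(ids)), 2):
            a, b = aln[ids[i]], aln[ids[j]]
            cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            expected = sum(x != y for x, y in cols) / len(cols)
            assert got.matrix[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = phy.neighbor_joining(phy.DistanceMatrix(["A", "B", "C"], m))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise distances below
        dists = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                 ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        tree = phy.neighbor_joining(dm_from_dists(dists))
        assert phy.bipartitions(tree) in ({frozenset({"C", "D"})},
                                          {frozenset({"A", "B"})})
        for x, y in itertools.combinations("ABCD", 2):
            assert tree.find(x).distance(tree.find(y)) \
                == pytest.approx(dists[(x, y)])

    @pytest.mark.parametrize("n_taxa", [6, 9, 12])
    def test_consistency_on_random_additive_matrices(self, n_taxa):
        """NJ recovers the generating topology and path lengths on additive
        data (100 draws at n=6, fewer at larger n)."""
        rng = np.random.default_rng(50 + n_taxa)
        n_draws = 100 if n_taxa == 6 else 20
        for _ in range(n_draws):
            dists, true_tree = random_additive_tree(n_taxa, rng)
            tree = phy.neighbor_joining(dm_from_dists(dists))
            assert phy.bipartitions(tree) == phy.bipartitions(true_tree)
            for (x, y), d in dists.items():
                assert tree.find(x).distance(tree.find(y)) == pytest.approx(d)

    def test_agrees_with_skbio_nj(self):
        rng = np.random.default_rng(77)
        dists, _ = random_additive_tree(8, rng)
        dm = dm_from_dists(dists)
        ours = phy.neighbor_joining(dm)
        theirs = skbio_nj(SkDM(dm.matrix, dm.ids))
        assert phy.bipartitions(ours) == phy.bipartitions(theirs)

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(88)
        dists, _ = random_additive_tree(7, rng)
        dm = dm_from_dists(dists)
        perm = list(rng.permutation(len(dm.ids)))
        dm2 = phy.DistanceMatrix([dm.ids[k] for k in perm],
                                 dm.matrix[np.ix_(perm, perm)])
        assert phy.bipartitions(phy.neighbor_joining(dm)) \
            == phy.bipartitions(phy.neighbor_joining(dm2))

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            phy.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phy.neighbor_joining(
                phy.DistanceMatrix(["a", "b"], np.array([[0., 1.], [1., 0.]])))


class TestBootstrap:
    def test_planted_split_gets_high_support(self):
        """Two well-separated 3-taxon clades: the central bipartition is
        supported in >= 99% of replicates."""
        rng = np.random.default_rng(5)
        core_a = syn.random_protein(rng, 60)
        core_b = syn.random_protein(rng, 60)
        aln = {}
        for i in range(3):
            aln[f"a{i}"] = syn.mutate_copy(core_a, 0.95, rng)
            aln[f"b{i}"] = syn.mutate_copy(core_b, 0.95, rng)
        _, supports = phy.bootstrap_support(aln, n_replicates=200, seed=1)
        central = frozenset({"b0", "b1", "b2"})
        assert supports[central] >= 99

    def test_uniform_columns_give_full_support(self):
        # one column pattern repeated: every resample is the same alignment
        pattern = {"t0": "A", "t1": "C", "t2": "D", "t3": "E", "t4": "F"}
        aln = {k: v * 80 for k, v in pattern.items()}
        _, supports = phy.bootstrap_support(aln, n_replicates=50, seed=2)
        assert all(s == 100 for s in supports.values())

    def test_deterministic_for_fixed_seed(self):
        aln, _ = syn.make_block_alignment(6, 40, 0.9, seed=9)
        r1 = phy.bootstrap_support(aln, n_replicates=50, seed=3)[1]
        r2 = phy.bootstrap_support(aln, n_replicates=50, seed=3)[1]
        assert r1 == r2


class TestNewick:
    def test_three_taxon_form(self):
        m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        text = phy.write_newick(
            phy.neighbor_joining(phy.DistanceMatrix(["A", "B", "C"], m)))
        assert text.startswith("(") and text.endswith(";")
        for leaf in "ABC":
            assert leaf in text

    def test_round_trip_random_trees(self, tmp_path):
        rng = np.random.default_rng(10)
        for k in range(20):
            dists, _ = random_additive_tree(int(rng.integers(4, 9)), rng)
            tree = phy.neighbor_joining(dm_from_dists(dists))
            path = tmp_path / f"t{k}.nwk"
            phy.write_newick(tree, path)
            back = phy.read_newick(str(path))
            assert phy.bipartitions(back) == phy.bipartitions(tree)
            for tip in tree.tips():
                assert back.find(tip.name).length \
                    == pytest.approx(tip.length, abs=1e-9)

    def test_supports_survive_round_trip(self, tmp_path):
        aln, _ = syn.make_block_alignment(6, 40, 0.9, seed=12)
        tree, supports = phy.bootstrap_support(aln, n_replicates=50, seed=4)
        path = tmp_path / "s.nwk"
        phy.write_newick(tree, path)
        back = phy.read_newick(str(path))
        back_labels = sorted(int(n.name) for n in back.non_tips()
                             if n.name is not None)
        assert back_labels == sorted(supports.values())
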