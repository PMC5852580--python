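"""p-distances, neighbor-joining, bootstrap supports, class assignment."""

import numpy as np
import pytest

from genefam.errors import ValidationError
from genefam.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    assign_classes,
    bootstrap_supports,
    nj_tree,
    p_distance_matrix,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def tree_distances(tree: PhyloTree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths (independent check of NJ additivity)."""
    # collect edge lists by recursion
    dists: dict[frozenset, float] = {}

    def leaf_depths(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(leaf_depths(c, acc + c.length))
        return out

    def walk(node):
        # paths through this node between leaves of different child subtrees
        depth_sets = [leaf_depths(c, c.length) for c in node.children]
        for i in range(len(depth_sets)):
            for j in range(i + 1, len(depth_sets)):
                for la, da in depth_sets[i].items():
                    for lb, db in depth_sets[j].items():
                        dists[frozenset((la, lb))] = da + db
        for c in node.children:
            walk(c)

    walk(tree.root)
    return dists


class TestPDistance:
    def test_identical_rows_give_zero(self):
        dm = p_distance_matrix({"a": "MKV", "b": "MKV"})
        assert dm[("a", "b")] == 0.0

    def test_single_mismatch_over_ten_columns(self):
        dm = p_distance_matrix({"a": "M" * 10, "b": "M" * 9 + "K"})
        assert dm[("a", "b")] == pytest.approx(0.1)

    def test_complete_deletion_removes_gap_columns_globally(self):
        with_gap = p_distance_matrix({"a": "MKV-A", "b": "MRV-A", "c": "MKVCA"})
        without = p_distance_matrix({"a": "MKVA", "b": "MRVA", "c": "MKVA"})
        assert np.allclose(with_gap.values, without.values)

    def test_all_columns_gapped_rejected(self):
        with pytest.raises(ValidationError):
            p_distance_matrix({"a": "--", "b": "AA"})


class TestNJ:
    def test_three_taxon_pendant_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        tree = nj_tree(dm)
        assert tree.bipartitions() == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        }
        got = tree_distances(tree)
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1 :]:
                assert got[frozenset((a, b))] == pytest.approx(dm[(a, b)])

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # caterpillar ((A:1,B:1):1,(C:1,(D:1,E:1):1):1) as unrooted distances
        taxa = list("ABCDE")
        d = {
            ("A", "B"): 2, ("A", "C"): 4, ("A", "D"): 5, ("A", "E"): 5,
            ("B", "C"): 4, ("B", "D"): 5, ("B", "E"): 5,
            ("C", "D"): 3, ("C", "E"): 3, ("D", "E"): 2,
        }
        m = np.zeros((5, 5))
        for (a, b), v in d.items():
            i, j = taxa.index(a), taxa.index(b)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(taxa, m))
        got = tree_distances(tree)
        for (a, b), v in d.items():
            assert got[frozenset((a, b))] == pytest.approx(v)

    def test_taxon_permutation_gives_isomorphic_tree(self, rng):
        n = 6
        base = rng.uniform(0.1, 1.0, size=(n, n))
        m = np.triu(base, 1)
        m = m + m.T
        taxa = [f"t{i}" for i in range(n)]
        perm = rng.permutation(n)
        t1 = nj_tree(DistanceMatrix(taxa, m))
        t2 = nj_tree(
            DistanceMatrix([taxa[i] for i in perm], m[np.ix_(perm, perm)])
        )
        assert t1.bipartitions() == t2.bipartitions()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


def _two_clade_msa(rng, n_per_clade=4, length=120, p_within=0.01):
    anc1 = "".join(rng.choice(AA, length))
    anc2 = "".join(rng.choice(AA, length))

    def mutate(s, p):
        return "".join(rng.choice(AA) if rng.random() < p else c for c in s)

    msa = {f"c1_{i}": mutate(anc1, p_within) for i in range(n_per_clade)}
    msa.update({f"c2_{i}": mutate(anc2, p_within) for i in range(n_per_clade)})
    return msa


class TestBootstrap:
    def test_planted_clade_split_strongly_supported(self, rng):
        msa = _two_clade_msa(rng)
        tree = bootstrap_supports(msa, n_replicates=200, seed=7)
        clade1 = frozenset(k for k in msa if k.startswith("c1"))
        clade2 = frozenset(k for k in msa if k.startswith("c2"))
        split = frozenset({clade1, clade2})
        supports = {}

        def collect(node):
            for c in node.children:
                side = c.leaf_names()
                if len(side) >= 2 and len(tree.leaf_names - side) >= 2:
                    supports[frozenset({side, tree.leaf_names - side})] = c.support
                collect(c)

        collect(tree.root)
        assert supports[split] >= 95.0

    def test_reproducible_under_fixed_seed(self, rng):
        msa = _two_clade_msa(rng, n_per_clade=3, length=60)
        t1 = bootstrap_supports(msa, n_replicates=50, seed=3)
        t2 = bootstrap_supports(msa, n_replicates=50, seed=3)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_bounds(self, rng):
        msa = _two_clade_msa(rng, n_per_clade=3, length=60, p_within=0.2)
        tree = bootstrap_supports(msa, n_replicates=50, seed=5)

        def check(node):
            for c in node.children:
                if c.support is not None:
                    assert 0.0 <= c.support <= 100.0
                check(c)

        check(tree.root)

    def test_identical_sequences_flagged_unresolved(self):
        msa = {f"t{i}": "MKVMKV" for i in range(4)}
        tree = bootstrap_supports(msa, n_replicates=10, seed=1)
        assert not tree.resolved


class TestAssignClasses:
    def test_query_sister_to_single_reference(self, rng):
        msa = _two_clade_msa(rng)
        tree = nj_tree(p_distance_matrix(msa))
        labels = {"c1_0": "tau", "c2_0": "phi"}
        got = assign_classes(tree, labels)
        for q, cls in got.items():
            assert cls == ("tau" if q.startswith("c1") else "phi")

    def test_mixed_smallest_clade_is_unclassified(self):
        # star-ish tree where the query's nearest labeled clade mixes classes
        dm = DistanceMatrix(
            ["q", "tau_ref", "phi_ref"],
            np.array([[0, 0.3, 0.3], [0.3, 0, 0.3], [0.3, 0.3, 0]]),
        )
        tree = nj_tree(dm)
        got = assign_classes(tree, {"tau_ref": "tau", "phi_ref": "phi"})
        assert got["q"] == "unclassified"

    def test_no_labels_rejected(self, rng):
        tree = nj_tree(p_distance_matrix(_two_clade_msa(rng, n_per_clade=2)))
        with pytest.raises(ValidationError):
            assign_classes(tree, {})

    def test_simulated_recovery_rate(self, rng):
        correct = total = 0
        for rep in range(5):
            msa = _two_clade_msa(rng, n_per_clade=5, length=150)
            tree = nj_tree(p_distance_matrix(msa))
            got = assign_classes(tree, {"c1_0": "tau", "c2_0": "phi"})
            for q, cls in got.items():
                total += 1
                correct += cls == ("tau" if q.startswith("c1") else "phi")
        assert correct / total >= 0.95
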