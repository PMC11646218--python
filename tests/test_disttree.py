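import itertools

import dendropy
import numpy as np
import pytest

from foldphylo.disttree import (
    DegenerateMatrixError,
    PhyloTree,
    all_topologies,
    fitch_tree,
    fm_objective,
    ls_branch_lengths,
    robinson_foulds,
)
from foldphylo.metrics import DistanceMatrix
from foldphylo.synthetic import make_distance_fixture, yule_tree


def quartet(la, lb, lc, ld, internal):
    """((a,b),(c,d)) with given branch lengths."""
    adj = {
        0: {2: la}, 1: {2: lb}, 2: {0: la, 1: lb, 3: internal},
        3: {2: internal, 4: lc, 5: ld}, 4: {3: lc}, 5: {3: ld},
    }
    return PhyloTree(adj, {0: "a", 1: "b", 4: "c", 5: "d"})


def dm_from_tree(tree):
    return DistanceMatrix(tree.labels, tree.patristic_matrix(), "SAS")


def fm_oracle(D, labels, tree, power=2.0):
    """Direct-summation oracle for the weighted least-squares misfit."""
    P = tree.patristic_matrix(labels)
    total = 0.0
    for i, j in itertools.combinations(range(len(labels)), 2):
        total += (D[i, j] - P[i, j]) ** 2 / D[i, j] ** power
    return total


class TestObjective:
    def test_zero_on_exact_tree(self):
        t = quartet(1.0, 2.0, 0.5, 1.5, 0.8)
        assert fm_objective(dm_from_tree(t), t) == pytest.approx(0.0, abs=1e-20)

    def test_star_distances(self):
        adj = {0: {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}}
        for k in range(1, 5):
            adj[k] = {0: 1.0}
        star = PhyloTree(adj, {k: lab for k, lab in zip(range(1, 5), "abcd")})
        assert fm_objective(dm_from_tree(star), star) == pytest.approx(0.0, abs=1e-20)

    def test_wrong_topology_matches_direct_summation(self):
        truth = quartet(1.0, 1.0, 1.0, 1.0, 2.0)
        dm = dm_from_tree(truth)
        # deliberately wrong grouping ((a,c),(b,d)) with arbitrary lengths
        wrong = PhyloTree(
            {
                0: {2: 1.0}, 1: {2: 0.7}, 2: {0: 1.0, 1: 0.7, 3: 0.4},
                3: {2: 0.4, 4: 1.2, 5: 0.9}, 4: {3: 1.2}, 5: {3: 0.9},
            },
            {0: "a", 1: "c", 4: "b", 5: "d"},
        )
        got = fm_objective(dm, wrong)
        want = fm_oracle(dm.d, dm.labels, wrong)
        assert got == pytest.approx(want, rel=1e-12)


class TestBranchLengths:
    def test_recovers_additive_lengths(self):
        t = quartet(1.0, 2.0, 0.5, 1.5, 0.8)
        fitted = ls_branch_lengths(t, dm_from_tree(t))
        P = fitted.patristic_matrix(t.labels)
        np.testing.assert_allclose(P, t.patristic_matrix(t.labels), atol=1e-8)

    def test_negative_solution_clamped(self):
        # matrix that drives the internal edge negative unconstrained:
        # d(a,b) large, others small
        d = np.array(
            [
                [0.0, 4.0, 1.0, 1.0],
                [4.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        dm = DistanceMatrix(list("abcd"), d)
        t = quartet(1.0, 1.0, 1.0, 1.0, 1.0)
        fitted = ls_branch_lengths(t, dm)
        lens = [fitted.adj[u][v] for u, v in fitted.edges()]
        assert all(l >= 0 for l in lens)
        assert fm_objective(dm, fitted) >= 0

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        dm = DistanceMatrix(list("abc"), d)
        topo = next(all_topologies(list("abc")))
        fitted = ls_branch_lengths(topo, dm)
        # three-point formulas: ea = (dab + dac - dbc)/2 etc.
        expect = {"a": 1.0, "b": 2.0, "c": 3.0}
        for lab, e in expect.items():
            node = fitted.leaf_node(lab)
            (ln,) = fitted.adj[node].values()
            assert ln == pytest.approx(e, abs=1e-10)

    def test_duplicate_taxa_degeneracy(self):
        d = np.array(
            [
                [0.0, 0.0, 2.0, 2.0],
                [0.0, 0.0, 2.0, 2.0],
                [2.0, 2.0, 0.0, 1.0],
                [2.0, 2.0, 1.0, 0.0],
            ]
        )
        dm = DistanceMatrix(list("abcd"), d)
        with pytest.raises(DegenerateMatrixError):
            ls_branch_lengths(quartet(1, 1, 1, 1, 1), dm)


class TestFitchTree:
    @pytest.mark.parametrize("n", [5, 8])
    def test_additive_matrix_recovered(self, n):
        truth = yule_tree(n, seed=n)
        dm = make_distance_fixture(truth, 0.0, 0)
        t = fitch_tree(dm, n_restarts=3, seed=1)
        assert robinson_foulds(t, truth) == 0
        assert fm_objective(dm, t) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("n,seed", [(4, 0), (4, 1), (5, 0), (5, 1)])
    def test_matches_exhaustive_search(self, n, seed):
        rng = np.random.default_rng([n, seed])
        x = rng.uniform(0.5, 3.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        dm = DistanceMatrix(labels, d)
        best = min(
            fm_objective(dm, ls_branch_lengths(topo, dm))
            for topo in all_topologies(labels)
        )
        t = fitch_tree(dm, n_restarts=5, seed=1)
        assert fm_objective(dm, t) == pytest.approx(best, abs=1e-8)

    def test_relabeling_invariance(self):
        truth = yule_tree(6, seed=11)
        dm = make_distance_fixture(truth, 0.05, 3)
        t1 = fitch_tree(dm, n_restarts=3, seed=5)
        perm = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)], dm.metric_name
        )
        t2 = fitch_tree(dm2, n_restarts=3, seed=5)
        assert robinson_foulds(t1, t2) == 0


class TestRobinsonFoulds:
    def test_identical(self):
        t = yule_tree(7, seed=2)
        assert robinson_foulds(t, t.copy()) == 0

    def test_single_nni_gives_two(self):
        from foldphylo.disttree import _nni_neighbors

        t = yule_tree(6, seed=4)
        other = next(iter(_nni_neighbors(t)))
        assert robinson_foulds(t, other) == 2

    def test_matches_dendropy(self):
        t1 = yule_tree(8, seed=5)
        t2 = yule_tree(8, seed=6)
        mine = robinson_foulds(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == ref

    def test_leafset_mismatch(self):
        t1 = yule_tree(5, seed=1)
        t2 = yule_tree(6, seed=1)
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


class TestNewick:
    def test_roundtrip_preserves_patristic(self):
        t = yule_tree(9, seed=8)
        back = PhyloTree.from_newick(t.to_newick())
        assert sorted(back.labels) == sorted(t.labels)
        np.testing.assert_allclose(
            back.patristic_matrix(t.labels), t.patristic_matrix(t.labels), atol=1e-6
        )

    def test_quoted_names(self):
        t = quartet(1, 1, 1, 1, 1)
        t.leaves[t.leaf_node("a")] = "odd name (x)"
        back = PhyloTree.from_newick(t.to_newick())
        assert "odd name (x)" in back.labels


def test_topology_count():
    assert len(list(all_topologies(list("abcd")))) == 3
    assert len(list(all_topologies(list("abcde")))) == 15
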