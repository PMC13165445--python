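import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from msapclade import (
    bootstrap_supports,
    distance_matrix,
    nei_li_distance,
    neighbor_joining,
    read_newick,
    root_with_outgroup,
    support_for_clade,
    to_newick,
    total_branch_length,
)
from msapclade.nj_clustering import DistanceError, _bipartitions

from conftest import make_matrix


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns TreeNode."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.05, 1.0))
        nodes[i] = parent
        del nodes[j]
    root = TreeNode(children=nodes)
    return root


def path_length_matrix(t):
    dm = t.tip_tip_distances()
    order = sorted(dm.ids)
    return dm.filter(order).data, order


# -- Nei-Li distance -------------------------------------------------------


class TestNeiLi:
    def test_identical_vectors_zero(self):
        assert nei_li_distance([1, 1, 0, 1], [1, 1, 0, 1]) == 0.0

    def test_disjoint_presence_one(self):
        assert nei_li_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_hand_computed_half(self):
        # a=1, b=1, c=1 -> 1 - 2/(2+1+1) = 0.5
        assert nei_li_distance([1, 1, 0], [1, 0, 1]) == 0.5

    def test_missing_excluded_pairwise(self):
        # with the missing locus dropped, vectors are identical
        assert nei_li_distance([1, -1, 0], [1, 1, 0]) == 0.0

    def test_all_missing_raises(self):
        with pytest.raises(DistanceError):
            nei_li_distance([-1, -1], [0, 1])

    def test_shared_absences_carry_no_signal(self):
        d0 = nei_li_distance([1, 0, 1], [1, 1, 0])
        d1 = nei_li_distance([1, 0, 1, 0, 0], [1, 1, 0, 0, 0])
        assert d0 == d1

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.sampled_from([0, 1]), st.sampled_from([0, 1])),
            min_size=1,
            max_size=30,
        )
    )
    def test_symmetric_and_bounded(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        d = nei_li_distance(x, y)
        assert d == nei_li_distance(y, x)
        assert 0.0 <= d <= 1.0
        if x == y:
            assert d == 0.0


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self):
        m = make_matrix([[1, 0, 1], [1, 0, 1]])
        assert np.array_equal(distance_matrix(m).data, np.zeros((2, 2)))

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        vals[rng.random(vals.shape) < 0.1] = -1
        m = make_matrix(vals.tolist())
        dm = distance_matrix(m)
        for i in range(6):
            for j in range(6):
                expect = (
                    0.0 if i == j else nei_li_distance(vals[i], vals[j])
                )
                assert dm.data[i, j] == pytest.approx(expect)

    def test_sample_permutation_permutes_entries(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 2, size=(5, 30)).astype(np.int8)
        m = make_matrix(vals.tolist())
        dm = distance_matrix(m)
        perm = rng.permutation(5)
        m2 = m.reorder_samples([m.sample_ids[i] for i in perm])
        dm2 = distance_matrix(m2)
        assert np.allclose(dm2.filter(dm.ids).data, dm.data)


# -- neighbor joining ------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            [[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]], ids=list("ABC")
        )
        t = neighbor_joining(dm)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.1, "C": 0.3})
        assert total_branch_length(t) == pytest.approx(0.5)

    @pytest.mark.parametrize("n_taxa", [4, 5, 8])
    def test_recovers_additive_matrices_exactly(self, n_taxa):
        """On additive distances NJ must reproduce all path lengths."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            true_tree = random_additive_tree(n_taxa, rng)
            d_true, order = path_length_matrix(true_tree)
            inferred = neighbor_joining(
                DistanceMatrix(d_true, ids=order)
            )
            d_inf, order_inf = path_length_matrix(inferred)
            assert order_inf == order
            assert np.allclose(d_inf, d_true, atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self):
        rng = np.random.default_rng(17)
        true_tree = random_additive_tree(6, rng)
        d_true, order = path_length_matrix(true_tree)
        dm = DistanceMatrix(d_true, ids=order)
        ours, _ = path_length_matrix(neighbor_joining(dm))
        reference, _ = path_length_matrix(skbio_nj(dm))
        assert np.allclose(ours, reference, atol=1e-9)

    def test_zero_distance_cherry(self):
        dm = DistanceMatrix(
            [
                [0.0, 0.0, 0.5, 0.5],
                [0.0, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.4],
                [0.5, 0.5, 0.4, 0.0],
            ],
            ids=list("ABCD"),
        )
        t = neighbor_joining(dm)
        a = t.find("A")
        b = t.find("B")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            d = rng.random((n, n)) * 0.9
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            t = neighbor_joining(DistanceMatrix(d, ids=[f"T{i}" for i in range(n)]))
            assert all(
                (node.length or 0.0) >= 0.0
                for node in t.traverse()
                if not node.is_root()
            )

    def test_scaling_distances_scales_total_length(self):
        rng = np.random.default_rng(12)
        true_tree = random_additive_tree(6, rng)
        d, order = path_length_matrix(true_tree)
        t1 = neighbor_joining(DistanceMatrix(d, ids=order))
        t3 = neighbor_joining(DistanceMatrix(3.0 * d, ids=order))
        assert total_branch_length(t3) == pytest.approx(
            3.0 * total_branch_length(t1)
        )

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=list("AB")))


# -- rooting ---------------------------------------------------------------


class TestRooting:
    def test_three_taxon_only_resolution(self):
        t = read_newick("(A:0.1,B:0.1,C:0.3);")
        rooted = root_with_outgroup(t, "C")
        ingroup = [c for c in rooted.children if c.name != "C"]
        assert len(rooted.children) == 2
        assert {tip.name for tip in ingroup[0].tips()} == {"A", "B"}

    def test_rerooting_same_leaf_idempotent(self):
        t = read_newick("((A:1,B:2):0.5,(C:1,D:1):0.5,E:3);")
        r1 = root_with_outgroup(t, "E")
        r2 = root_with_outgroup(r1, "E")
        d1, o1 = (r1.tip_tip_distances(), None)
        assert np.allclose(
            r1.tip_tip_distances().filter(sorted("ABCDE")).data,
            r2.tip_tip_distances().filter(sorted("ABCDE")).data,
        )

    def test_path_lengths_preserved(self):
        rng = np.random.default_rng(23)
        t = random_additive_tree(7, rng)
        d0, order = path_length_matrix(t)
        rooted = root_with_outgroup(t, "T0")
        d1, order1 = path_length_matrix(rooted)
        assert order1 == order
        assert np.allclose(d1, d0)

    def test_unknown_outgroup_raises(self):
        t = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(KeyError):
            root_with_outgroup(t, "Z")


# -- bootstrap -------------------------------------------------------------


class TestBootstrap:
    def test_identical_locus_copies_give_full_support(self):
        # every locus identical: all replicates reproduce the same tree
        col = [1, 1, 0, 0, 1]
        m = make_matrix([list(row) for row in zip(*[col] * 20)])
        t = bootstrap_supports(m, n_reps=25, seed=1)
        supports = [
            node.support
            for node in t.non_tips(include_self=False)
            if hasattr(node, "support")
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_seed_reproducibility(self, default_panel):
        _, aflp, _, _, truth = default_panel
        from msapclade import filter_monomorphic

        m = filter_monomorphic(aflp)
        s1 = support_for_clade(
            bootstrap_supports(m, n_reps=30, seed=7), truth.clade_a
        )
        s2 = support_for_clade(
            bootstrap_supports(m, n_reps=30, seed=7), truth.clade_a
        )
        assert s1 == s2

    def test_supports_bounded(self, default_panel):
        _, aflp, _, _, _ = default_panel
        from msapclade import filter_monomorphic

        t = bootstrap_supports(filter_monomorphic(aflp), n_reps=20, seed=3)
        for node in t.non_tips(include_self=False):
            if hasattr(node, "support"):
                assert 0.0 <= node.support <= 100.0

    def test_rejects_zero_replicates(self, toy_matrix):
        with pytest.raises(ValueError):
            bootstrap_supports(toy_matrix, n_reps=0)


# -- serialization ---------------------------------------------------------


def test_newick_round_trip_preserves_lengths_and_supports():
    t = read_newick("((A:0.1,B:0.2):0.3,(C:0.1,D:0.4):0.2,E:0.5);")
    for node in t.non_tips(include_self=False):
        node.support = 87.0
    nwk = to_newick(t)
    assert ":0.10000" in nwk and "87.0" in nwk
    back = read_newick(nwk)
    assert {tip.name for tip in back.tips()} == set("ABCDE")
    d0 = t.tip_tip_distances().filter(sorted("ABCDE")).data
    d1 = back.tip_tip_distances().filter(sorted("ABCDE")).data
    assert np.allclose(d0, d1)


def test_bipartitions_invariant_to_rooting():
    t = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    rooted = root_with_outgroup(t.copy(), "E")
    assert _bipartitions(t) == _bipartitions(rooted)
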