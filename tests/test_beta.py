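import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from afmeta.beta import (
    Ordination,
    gradient_correlation,
    pcoa,
    read_newick,
    reference_tree,
    triplet_distance,
    upgma,
    write_newick,
)


def dm(data, ids):
    return DistanceMatrix(np.asarray(data, dtype=float), ids)


# ---------------------------------------------------------------- UPGMA


class TestUpgma:
    def test_two_samples(self):
        tree = upgma(dm([[0, 0.4], [0.4, 0]], ["A", "B"]))
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_hand_example(self):
        tree = upgma(dm([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ["A", "B", "C"]))
        # ((A,B),C): A,B merge at height 1, root at height 4
        ab = tree.lca([t for t in tree.tips() if t.name in "AB"])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        a = next(t for t in tree.tips() if t.name == "A")
        c = next(t for t in tree.tips() if t.name == "C")
        assert a.length == pytest.approx(1.0)
        assert ab.length == pytest.approx(3.0)  # 4 - 1
        assert c.length == pytest.approx(4.0)

    def test_identical_rows_merge_first(self):
        tree = upgma(
            dm(
                [[0, 0, 5], [0, 0, 5], [5, 5, 0]],
                ["x", "y", "z"],
            )
        )
        xy = tree.lca([t for t in tree.tips() if t.name in "xy"])
        assert {t.name for t in xy.tips()} == {"x", "y"}
        assert next(t for t in tree.tips() if t.name == "x").length == 0.0

    def test_nan_rejected(self):
        # poke NaN into the matrix directly to bypass skbio validation
        d = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        d.data[0, 1] = np.nan
        d.data[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            upgma(d)

    def test_output_is_ultrametric(self, rng):
        n = 10
        pts = rng.normal(size=(n, 3))
        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(n)])
        tree = upgma(d)
        dists = []
        for t in tree.tips():
            acc, node = 0.0, t
            while node.parent is not None:
                acc += node.length
                node = node.parent
            dists.append(acc)
        assert max(dists) - min(dists) < 1e-9

    def test_reconstructs_ultrametric_matrix(self, rng):
        # random ultrametric tree -> cophenetic matrix -> UPGMA recovers it
        names = [f"s{i}" for i in range(8)]
        Z = linkage(rng.random(len(names) * (len(names) - 1) // 2), "average")
        coph = squareform(cophenet(Z))
        tree = upgma(DistanceMatrix(coph, names))
        # pairwise tree distances equal the input matrix
        for i, a in enumerate(names):
            ta = next(t for t in tree.tips() if t.name == a)
            for j, b in enumerate(names):
                if i < j:
                    tb = next(t for t in tree.tips() if t.name == b)
                    assert ta.distance(tb) == pytest.approx(coph[i, j])

    def test_matches_scipy_average_linkage(self, rng):
        # independent route: scipy's average-linkage cophenetic distances
        n = 9
        condensed = rng.uniform(1, 10, size=n * (n - 1) // 2)
        names = [f"s{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(squareform(condensed), names))
        coph = squareform(cophenet(linkage(condensed, "average")))
        for i, j in itertools.combinations(range(n), 2):
            ta = next(t for t in tree.tips() if t.name == names[i])
            tb = next(t for t in tree.tips() if t.name == names[j])
            assert ta.distance(tb) == pytest.approx(coph[i, j], rel=1e-9)


# ------------------------------------------------------- triplet distance


def brute_force_triplet(t1, t2, penalize_unresolved=False):
    """Independent oracle: classify each 3-subset by leaf-set containment.

    xy|z iff some clade contains x and y but not z.
    """

    def topology(tree, a, b, c):
        for node in tree.non_tips(include_self=True):
            leaves = {t.name for t in node.tips()}
            for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
                if x in leaves and y in leaves and z not in leaves:
                    return frozenset((x, y))
        return None

    names = sorted(t.name for t in t1.tips())
    count = 0
    for a, b, c in itertools.combinations(names, 3):
        top1 = topology(t1, a, b, c)
        top2 = topology(t2, a, b, c)
        if top1 != top2:
            if penalize_unresolved or (top1 is not None and top2 is not None):
                count += 1
    return count


def random_tree(names, rng, p_contract=0.3):
    """Random rooted tree: random binary shape, then random edge
    contractions to create polytomies."""
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    tree = nodes[0]
    for node in list(tree.non_tips()):
        if node.parent is not None and rng.random() < p_contract:
            parent = node.parent
            parent.extend(node.children)
            parent.remove(node)
    return tree


class TestTripletDistance:
    def test_identical_trees(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        assert triplet_distance(t, TreeNode.read(["((A,B),(C,D));"])) == 0

    def test_worked_pair(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,C),(B,D));"])
        assert triplet_distance(t1, t2) == 4
        assert triplet_distance(t1, t2, penalize_unresolved=True) == 4

    def test_cherry_swap_invariant(self):
        t1 = TreeNode.read(["(((A,B),C),D);"])
        t2 = TreeNode.read(["(((B,A),C),D);"])
        assert triplet_distance(t1, t2) == 0

    def test_star_vs_resolved_conventions(self):
        star = TreeNode.read(["(A,B,C,D);"])
        caterpillar = TreeNode.read(["(((A,B),C),D);"])
        # refinements are compatible by default...
        assert triplet_distance(star, caterpillar) == 0
        # ...and each resolved triplet counts under the strict variant
        assert (
            triplet_distance(star, caterpillar, penalize_unresolved=True) == 4
        )

    def test_oracle_equivalence_random_trees(self, rng):
        names = [f"L{i}" for i in range(9)]
        for _ in range(30):
            t1 = random_tree(names, rng)
            t2 = random_tree(names, rng)
            for strict in (False, True):
                assert triplet_distance(
                    t1, t2, penalize_unresolved=strict
                ) == brute_force_triplet(t1, t2, penalize_unresolved=strict)

    def test_semimetric_properties(self, rng):
        names = [f"L{i}" for i in range(7)]
        t1 = random_tree(names, rng)
        t2 = random_tree(names, rng)
        assert triplet_distance(t1, t1) == 0
        assert triplet_distance(t1, t2) == triplet_distance(t2, t1)
        assert triplet_distance(t1, t2) <= math.comb(len(names), 3)

    def test_leaf_mismatch(self):
        t1 = TreeNode.read(["((A,B),C);"])
        t2 = TreeNode.read(["((A,B),D);"])
        with pytest.raises(ValueError, match="leaf label sets"):
            triplet_distance(t1, t2)

    def test_too_few_leaves(self):
        t = TreeNode.read(["(A,B);"])
        with pytest.raises(ValueError, match="at least 3"):
            triplet_distance(t, TreeNode.read(["(A,B);"]))


class TestReferenceTree:
    def test_two_groups(self):
        tree = reference_tree({"A": "g1", "B": "g1", "C": "g2"})
        g1 = tree.lca([t for t in tree.tips() if t.name in "AB"])
        assert {t.name for t in g1.tips()} == {"A", "B"}
        assert len(tree.children) == 2

    def test_singleton_group_attaches_leaf(self):
        tree = reference_tree({"A": "g1", "B": "g1", "C": "g2"})
        c = next(t for t in tree.tips() if t.name == "C")
        assert c.parent is tree

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 groups"):
            reference_tree({"A": "g", "B": "g"})

    def test_strict_distance_counts_resolved_triplets(self):
        # two polytomous groups: within-group triplets are unresolved in
        # the reference, so a binary tree pays exactly for its resolutions
        ref = reference_tree({n: "g1" for n in "ABC"} | {"D": "g2"})
        caterpillar = TreeNode.read(["(((A,B),C),D);"])
        assert triplet_distance(ref, caterpillar) == 0
        assert (
            triplet_distance(ref, caterpillar, penalize_unresolved=True) == 1
        )

    def test_three_groups_of_twenty(self):
        groups = {f"s{i}": f"g{i % 3}" for i in range(60)}
        tree = reference_tree(groups)
        assert len(tree.children) == 3
        assert all(len(list(ch.tips())) == 20 for ch in tree.children)


# ----------------------------------------------------------------- PCoA


class TestPcoa:
    def test_collinear_configuration(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        o = pcoa(dm(D, ["a", "b", "c"]), dims=1)
        centered = pts - pts.mean()
        got = o.coordinates[:, 0]
        assert np.allclose(got, centered, atol=1e-9) or np.allclose(
            got, -centered, atol=1e-9
        )

    def test_recovers_2d_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        o = pcoa(dm(D, [f"s{i}" for i in range(12)]), dims=2)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, o.coordinates)
        assert disparity < 1e-8

    def test_duplicate_samples_identical_coordinates(self):
        D = np.array(
            [[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float
        )
        o = pcoa(dm(D, ["a", "b", "c"]), dims=1)
        assert o.coordinates[0, 0] == pytest.approx(o.coordinates[1, 0])

    def test_equilateral_eigenvalues_equal(self):
        D = np.ones((4, 4)) - np.eye(4)
        o = pcoa(dm(D, list("abcd")), dims=3)
        assert np.allclose(o.eigenvalues, o.eigenvalues[0])

    def test_warns_when_axes_unavailable(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        with pytest.warns(UserWarning, match="positive-eigenvalue"):
            o = pcoa(dm(D, ["a", "b", "c"]), dims=3)
        assert o.coordinates.shape[1] == 1

    def test_axes_sorted(self, rng):
        pts = rng.normal(size=(10, 4)) * [5, 3, 1, 0.5]
        D = squareform(pdist(pts))
        o = pcoa(dm(D, [f"s{i}" for i in range(10)]), dims=4)
        assert (np.diff(o.eigenvalues) <= 1e-9).all()


class TestGradientCorrelation:
    def _ord(self, pc1):
        return Ordination(np.array(pc1)[:, None], np.array([1.0]),
                          [str(i) for i in range(len(pc1))])

    def test_proportional(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert gradient_correlation(self._ord(2 * g), g) == pytest.approx(1.0)

    def test_sign_flip(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert gradient_correlation(self._ord(-g), g) == pytest.approx(1.0)
        assert gradient_correlation(
            self._ord(-g), g, signed=True
        ) == pytest.approx(-1.0)

    def test_orthogonal(self):
        g = np.array([1.0, -1.0, 1.0, -1.0])
        pc1 = np.array([1.0, 1.0, -1.0, -1.0])
        assert gradient_correlation(self._ord(pc1), g) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_errors(self):
        g = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero variance"):
            gradient_correlation(self._ord([1.0, 2.0, 3.0]), g)
        with pytest.raises(ValueError, match="length"):
            gradient_correlation(self._ord([1.0, 2.0]), np.array([1.0]))


def test_newick_roundtrip(tmp_path, rng):
    names = [f"s{i}" for i in range(6)]
    t = random_tree(names, rng)
    path = str(tmp_path / "t.nwk")
    write_newick(t, path)
    t2 = read_newick(path)
    assert triplet_distance(t, t2) == 0
    assert triplet_distance(t, t2, penalize_unresolved=True) == 0
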