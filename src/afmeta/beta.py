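"""Beta-diversity evaluation: UPGMA clustering, rooted-tree triplet
distance, principal coordinates analysis and gradient correlation.

Group designs are scored by clustering the samples with UPGMA and counting
rooted triplets that disagree with a reference tree (a star-of-polytomies
built from the true group labels).  Gradient designs are scored by the
absolute Pearson correlation between the first principal coordinate and the
known gradient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA (size-weighted average linkage) tree of the samples.

    Repeatedly merges the closest pair of clusters at height d/2; the
    distance from a merged cluster to any other is the size-weighted mean of
    its members' distances.  Ties break on the lexicographically smallest
    pair of cluster representative labels, so the tree is deterministic.
    Returns a rooted ultrametric skbio TreeNode with branch lengths equal to
    height differences.
    """
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    # cluster state: representative label (lexicographic min), size, node,
    # current height; distances kept in a dict over frozen index pairs
    nodes = {i: TreeNode(name=dm.ids[i]) for i in range(n)}
    reps = {i: str(dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    dist = {
        (i, j): float(dm.data[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            pair_key = tuple(sorted((reps[i], reps[j])))
            key = (d, pair_key)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d = dist[(i, j)]
        height = d / 2.0
        node = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = height - heights[i]
        nodes[j].length = height - heights[j]
        new = next_id
        next_id += 1
        for m in active - {i, j}:
            dim = dist[tuple(sorted((i, m)))]
            djm = dist[tuple(sorted((j, m)))]
            dnew = (sizes[i] * dim + sizes[j] * djm) / (sizes[i] + sizes[j])
            dist[tuple(sorted((new, m)))] = dnew
        for key in [p for p in dist if i in p or j in p]:
            del dist[key]
        active -= {i, j}
        active.add(new)
        nodes[new] = node
        reps[new] = min(reps[i], reps[j])
        sizes[new] = sizes[i] + sizes[j]
        heights[new] = height
    root = nodes[active.pop()]
    root.length = None
    return root


def reference_tree(groups: dict) -> TreeNode:
    """Star-of-polytomies reference tree from sample -> group labels.

    One polytomous node per group under the root; groups with a single
    member attach that leaf directly to the root.  Within-group order is not
    part of the ground truth, so triplets inside a group are unresolved.
    """
    by_group: dict = {}
    for sample, g in groups.items():
        by_group.setdefault(g, []).append(str(sample))
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    children = []
    for g in sorted(by_group, key=str):
        members = sorted(by_group[g])
        if not members:
            raise ValueError(f"group {g!r} has no members")
        if len(members) == 1:
            children.append(TreeNode(name=members[0], length=1.0))
        else:
            node = TreeNode(
                children=[TreeNode(name=m, length=1.0) for m in members],
                length=1.0,
            )
            children.append(node)
    return TreeNode(children=children)


def _lca_depth_matrix(tree: TreeNode, leaf_names) -> np.ndarray:
    """Depth (edges from root) of the LCA of every leaf pair."""
    paths = {}
    ids = {}
    for node in tree.traverse(include_self=True):
        ids[id(node)] = len(ids)
    for leaf in tree.tips():
        path = [ids[id(a)] for a in reversed(list(leaf.ancestors()))]
        path.append(ids[id(leaf)])
        paths[leaf.name] = path
    n = len(leaf_names)
    D = np.zeros((n, n), dtype=np.int64)
    plist = [paths[name] for name in leaf_names]
    for i in range(n):
        pi = plist[i]
        for j in range(i + 1, n):
            pj = plist[j]
            depth = 0
            for a, b in zip(pi, pj):
                if a != b:
                    break
                depth += 1
            D[i, j] = D[j, i] = depth - 1
    return D


def _triplet_codes(D: np.ndarray, trips: np.ndarray) -> np.ndarray:
    """Topology code per triplet: 0 unresolved, 1 ab|c, 2 ac|b, 3 bc|a.

    The pair whose LCA is strictly deeper than the triple's LCA is the
    cherry; if all three pairwise LCAs coincide the triplet is unresolved.
    """
    a, b, c = trips[:, 0], trips[:, 1], trips[:, 2]
    d = np.stack([D[a, b], D[a, c], D[b, c]])
    alleq = (d[0] == d[1]) & (d[1] == d[2])
    return np.where(alleq, 0, d.argmax(axis=0) + 1)


def triplet_distance(
    t1: TreeNode, t2: TreeNode, penalize_unresolved: bool = False
) -> int:
    """Number of 3-leaf subsets whose rooted topologies conflict.

    A triplet is either resolved (one cherry pair below the triple's LCA) or
    unresolved (all three leaves coalesce at one node).  By default only
    contradictions count: triplets resolved in both trees but with
    different cherries.  A resolved triplet against an unresolved one is a
    compatible refinement, not a conflict — reference trees deliberately
    leave within-group order (and the order of group-level splits) open, so
    a clustering must not be penalized for resolving them.  With
    ``penalize_unresolved=True`` refinements count as different too (the
    strict variant); under that convention any binary tree keeps a floor
    distance to a multi-polytomy reference.
    """
    names1 = sorted(leaf.name for leaf in t1.tips())
    names2 = sorted(leaf.name for leaf in t2.tips())
    if names1 != names2:
        raise ValueError("trees have different leaf label sets")
    n = len(names1)
    if len(set(names1)) != n:
        raise ValueError("duplicate leaf labels")
    if n < 3:
        raise ValueError("triplet distance needs at least 3 leaves")
    D1 = _lca_depth_matrix(t1, names1)
    D2 = _lca_depth_matrix(t2, names1)
    trips = np.array(
        list(itertools.combinations(range(n), 3)), dtype=np.int64
    )
    c1 = _triplet_codes(D1, trips)
    c2 = _triplet_codes(D2, trips)
    diff = c1 != c2
    if not penalize_unresolved:
        diff &= (c1 != 0) & (c2 != 0)
    return int(diff.sum())


@dataclass
class Ordination:
    """PCoA embedding: samples x axes coordinates, axes sorted by
    non-increasing eigenvalue; only positive-eigenvalue axes are kept."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    ids: list


def pcoa(dm: DistanceMatrix, dims: int = 2) -> Ordination:
    """Classical MDS (Gower-centered eigendecomposition) of a dissimilarity
    matrix.

    Axes with non-positive eigenvalues are dropped; if fewer than ``dims``
    positive axes exist the available ones are returned with a warning.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    with warnings.catch_warnings():
        # full eigendecomposition is intended: all axes are needed to rank
        # and filter by eigenvalue
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.values
    tol = max(abs(eig).max(), 1.0) * 1e-12
    pos = eig > tol
    if pos.sum() < dims:
        warnings.warn(
            f"only {int(pos.sum())} positive-eigenvalue axes available "
            f"(requested {dims})",
            stacklevel=2,
        )
    keep = min(dims, int(pos.sum()))
    coords = res.samples.values[:, :keep]
    return Ordination(
        coordinates=coords,
        eigenvalues=eig[:keep],
        ids=[str(i) for i in res.samples.index],
    )


def gradient_correlation(
    ordination: Ordination, gradient, signed: bool = False
) -> float:
    """Pearson correlation between PC1 and a known gradient.

    Returned as an absolute value by default because the orientation of a
    PCoA axis is arbitrary; ``signed=True`` gives the raw coefficient for
    exploratory use.
    """
    gradient = np.asarray(gradient, dtype=float)
    pc1 = ordination.coordinates[:, 0]
    if gradient.shape != pc1.shape:
        raise ValueError("gradient length must equal the number of samples")
    if np.ptp(pc1) == 0 or np.ptp(gradient) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(pc1, gradient).statistic)
    return r if signed else abs(r)


def write_newick(tree: TreeNode, path: str) -> None:
    tree.write(path, format="newick")


def read_newick(path: str) -> TreeNode:
    return TreeNode.read(path, format="newick")
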