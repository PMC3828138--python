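"""Distance-based tree reconstruction: NJ and UPGMA.

Neighbor joining follows the standard agglomeration with one correction
suited to lineage trees, where branch lengths are division counts and can
never be negative: whenever a negative branch length appears during
agglomeration it is set to zero and the deficit is transferred to its
sibling branch, which preserves the cherry's total path length and leaves
the topology untouched.  Rooting uses the putative-zygote pseudo-leaf as an
outgroup.  All pair choices break ties on the lexicographically smallest
label pair so reconstructions are exactly reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np

from .distances import ROOT_LABEL, DistanceMatrix
from .trees import LineageTree, Node

__all__ = [
    "neighbor_joining",
    "upgma",
    "root_tree",
    "assign_normabs_depths",
    "reconstruct",
]


def _tie_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def neighbor_joining(D: DistanceMatrix) -> LineageTree:
    """Saitou–Nei neighbor joining with non-negative branch correction.

    Returns an unrooted tree represented with a trifurcating placeholder
    root (for n >= 3); callers root it via :func:`root_tree`.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        d = float(D.values[0, 1])
        root = Node(children=[
            Node(D.labels[0], d / 2.0), Node(D.labels[1], d / 2.0)
        ])
        tree = LineageTree(root, rooted=False)
        tree.assign_depths()
        return tree

    nodes = [Node(label) for label in D.labels]
    keys = list(D.labels)  # tie-break key: smallest leaf label in cluster
    mat = D.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if i < j:
                cand = _tie_key(keys[i], keys[j])
                if best is None or cand < best[0]:
                    best = (cand, int(i), int(j))
        _, i, j = best
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # negative-branch correction: zero the branch, move the deficit to
        # the sibling so the path length through the cherry is unchanged
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = float(li)
        child_j.branch_length = float(lj)
        parent.add_child(child_i)
        parent.add_child(child_j)

        dnew = 0.5 * (mat[i, :] + mat[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        mat = new_mat

    # final three clusters join at the unrooted placeholder node
    d01, d02, d12 = mat[0, 1], mat[0, 2], mat[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = Node()
    for node, length in zip(nodes, lengths):
        node.branch_length = float(max(length, 0.0))
        center.add_child(node)
    tree = LineageTree(center, rooted=False)
    tree.assign_depths()
    return tree


def upgma(D: DistanceMatrix) -> LineageTree:
    """Average-linkage agglomeration; the result is ultrametric."""
    n = len(D.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [Node(label) for label in D.labels]
    keys = list(D.labels)
    heights = [0.0] * n
    sizes = [1] * n
    mat = D.values.astype(float).copy()

    while len(nodes) > 1:
        m = len(nodes)
        work = mat.copy()
        np.fill_diagonal(work, np.inf)
        dmin = work.min()
        best = None
        for i, j in zip(*np.where(np.isclose(work, dmin, rtol=0, atol=1e-12))):
            if i < j:
                cand = _tie_key(keys[i], keys[j])
                if best is None or cand < best[0]:
                    best = (cand, int(i), int(j))
        _, i, j = best
        h = mat[i, j] / 2.0
        parent = Node()
        for k, child in ((i, nodes[i]), (j, nodes[j])):
            child.branch_length = float(h - heights[k])
            parent.add_child(child)
        dnew = (sizes[i] * mat[i, :] + sizes[j] * mat[j, :]) / (sizes[i] + sizes[j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]
        mat = new_mat

    tree = LineageTree(nodes[0], rooted=True)
    tree.assign_depths()
    return tree


def root_tree(tree: LineageTree, root_label: str = ROOT_LABEL) -> LineageTree:
    """Root at the attachment point of the outgroup pseudo-leaf.

    The pseudo-leaf is removed and its inferred branch length discarded;
    depths are recomputed from the new root.
    """
    tree = tree.copy()
    try:
        pseudo = tree.find_leaf(root_label)
    except KeyError:
        raise ValueError(f"outgroup leaf {root_label!r} not in tree") from None
    attach = pseudo.parent
    if attach is None:
        raise ValueError("outgroup is the entire tree")
    attach.remove_child(pseudo)
    tree.reroot_at(attach)
    tree.assign_depths()
    return tree


def assign_normabs_depths(
    tree: LineageTree, D_abs: DistanceMatrix, root_label: str = ROOT_LABEL
) -> LineageTree:
    """Assign depths from the absolute measure to a rooted topology.

    The normalized-absolute measure strips depth information, so a tree
    built from it carries its topology only; depths are re-estimated from
    the absolute distance matrix (which must include the root pseudo-leaf).
    Leaf depths are the absolute distances to the root; each internal
    node's depth follows bottom-up from the three-point formula

        depth(u) = (dbar(A, root) + dbar(B, root) - dbar(A, B)) / 2

    where A and B are the leaf sets of u's children and dbar is the mean
    pairwise absolute distance.  Negative estimates are clamped to zero and
    parent/child monotonicity is enforced top-down.
    """
    tree = tree.copy()
    if root_label not in D_abs.labels:
        raise ValueError(f"{root_label!r} missing from the distance matrix")
    ridx = D_abs.index(root_label)
    idx = {label: D_abs.index(label) for label in tree.leaf_labels()}

    leafsets = tree.leafsets()
    depths: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            depths[node._uid] = float(D_abs.values[idx[node.label], ridx])
        else:
            if len(node.children) == 1:
                depths[node._uid] = depths[node.children[0]._uid]
                continue
            # mean over all child-pairs generalizes the sibling formula to
            # multifurcations
            vals = []
            kids = node.children
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = [idx[l] for l in leafsets[kids[a]]]
                    ib = [idx[l] for l in leafsets[kids[b]]]
                    da = float(np.mean(D_abs.values[ia, ridx]))
                    db = float(np.mean(D_abs.values[ib, ridx]))
                    dab = float(np.mean(D_abs.values[np.ix_(ia, ib)]))
                    vals.append(0.5 * (da + db - dab))
            est = float(np.mean(vals))
            if est < 0:
                warnings.warn("negative implied depth clamped to 0")
                est = 0.0
            depths[node._uid] = est

    tree.root.depth = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        d = max(depths[node._uid], node.parent.depth)
        node.depth = d
        node.branch_length = d - node.parent.depth
    return tree


def reconstruct(
    D: DistanceMatrix,
    algorithm: str = "nj",
    *,
    D_abs: DistanceMatrix | None = None,
    root_label: str = ROOT_LABEL,
) -> LineageTree:
    """Build a rooted lineage tree from a distance matrix.

    ``nj`` requires the root pseudo-leaf in ``D`` for outgroup rooting; a
    normalized-absolute matrix may be paired with ``D_abs`` to re-estimate
    depths on the inferred topology.  ``upgma`` trees are rooted by
    construction (the pseudo-leaf, if present, is dropped first).
    """
    if algorithm == "nj":
        tree = neighbor_joining(D)
        if root_label in D.labels:
            tree = root_tree(tree, root_label)
        if D_abs is not None:
            tree = assign_normabs_depths(tree, D_abs, root_label)
        return tree
    if algorithm == "upgma":
        labels = [l for l in D.labels if l != root_label]
        if len(labels) != len(D.labels):
            D = D.submatrix(labels)
        return upgma(D)
    raise ValueError(f"unknown algorithm {algorithm!r}")
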