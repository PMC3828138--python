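"""Shared fixtures and independent oracle helpers.

Random-tree generators and brute-force re-computations live here so the
tests can check the library against implementations that share no code
with it.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from mslineage import CellSignature, Dataset, LocusInfo, RootSignature
from mslineage.trees import LineageTree, Node


# ---------------------------------------------------------------------------
# signature / dataset builders


def make_signature(sample_id: str, values: dict, individual="I1", cell_type="T1"):
    """values: {(locus, idx): repeat or None}."""
    return CellSignature(
        sample_id=sample_id,
        individual_id=individual,
        cell_type=cell_type,
        alleles=dict(values),
    )


def make_dataset(value_rows: dict[str, list[int | None]], root_values=None):
    """Build a single-allele-per-locus dataset from {sample: [v1, v2, ...]}."""
    n = max(len(v) for v in value_rows.values())
    keys = [(f"L{i + 1:03d}", 1) for i in range(n)]
    panel = {k: LocusInfo() for k in keys}
    sigs = [
        make_signature(sid, dict(zip(keys, vals)))
        for sid, vals in value_rows.items()
    ]
    root = None
    if root_values is not None:
        root = RootSignature(
            alleles=dict(zip(keys, map(float, root_values))), policy="tail_sample"
        )
    return Dataset(signatures=sigs, root=root, panel=panel)


@pytest.fixture
def toy_dataset():
    return make_dataset(
        {"A": [10, 12, 14, 20], "B": [10, 13, 14, 22], "C": [11, 12, 15, 20]},
        root_values=[10, 12, 14, 20],
    )


# ---------------------------------------------------------------------------
# random trees


def random_binary_tree(labels, rng: random.Random, min_bl=0.5, max_bl=5.0):
    """Random rooted binary tree with positive branch lengths."""
    nodes = [Node(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        a, b = nodes[i], nodes[j]
        a.branch_length = rng.uniform(min_bl, max_bl)
        b.branch_length = rng.uniform(min_bl, max_bl)
        parent = Node(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = LineageTree(nodes[0])
    tree.assign_depths()
    return tree


def random_ultrametric_tree(labels, rng: random.Random):
    """Random tree in which all leaves are equidistant from the root."""
    height = {  # cluster -> current height
    }
    nodes = [(Node(l), 0.0) for l in labels]
    h = 0.0
    while len(nodes) > 1:
        h += rng.uniform(0.5, 3.0)
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.branch_length = h - ha
        b.branch_length = h - hb
        parent = Node(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [(parent, h)]
    tree = LineageTree(nodes[0][0])
    tree.assign_depths()
    return tree


def path_length_matrix(tree: LineageTree):
    """Leaf-to-leaf path lengths via root paths (independent oracle)."""
    paths = {}
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        paths[leaf.label] = path
    labels = sorted(paths)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[labels[i]]
            pj = paths[labels[j]]
            seti = {id(x) for x in pi}
            lca = next(x for x in pj if id(x) in seti)
            di = sum(x.branch_length for x in pi[: pi.index(lca)])
            dj = sum(x.branch_length for x in pj[: pj.index(lca)])
            mat[i, j] = mat[j, i] = di + dj
    return labels, mat


def brute_force_bipartitions(tree: LineageTree):
    """Bipartitions via edge removal on an explicit graph (networkx),
    sharing no traversal code with LineageTree.bipartitions."""
    import networkx as nx

    g = nx.Graph()
    leaves = []
    for node in tree.postorder():
        if node.is_leaf:
            leaves.append(node)
        for child in node.children:
            g.add_edge(id(node), id(child))
    # suppress the root if it has degree 2 (unrooted view)
    rid = id(tree.root)
    if g.degree(rid) == 2:
        a, b = list(g.neighbors(rid))
        g.remove_node(rid)
        g.add_edge(a, b)
    all_labels = frozenset(l.label for l in leaves)
    leaf_ids = {id(l): l.label for l in leaves}
    parts = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(leaf_ids[x] for x in comp if x in leaf_ids)
        g.add_edge(u, v)
        if 2 <= len(side) <= len(all_labels) - 2:
            other = all_labels - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts
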