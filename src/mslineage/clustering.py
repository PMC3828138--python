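"""Clustering-quality statistics on a labelled lineage tree.

Three complementary statistics quantify how well predefined cell groups
(individuals or cell types) separate on a reconstructed tree:

* **QLC** (quality of the largest cluster): for each group the best node
  "degree", where a node's degree is the product of its recall (fraction
  of the group's cells below the node) and its purity (fraction of cells
  below the node that belong to the group), zeroed when purity <= 1/2; the
  tree score is the mean over groups.  1 means every group sits in its own
  clade.
* **TE** (tree entropy): for each unordered group pair, count the maximal
  monochromatic clades each group splits into (with respect to the pair's
  leaves only) and take the log of the number of equally-fragmented
  configurations, ``ln C(n_a-1, c_a-1) + ln C(n_b-1, c_b-1)``; the scalar
  TE is the mean over pairs.  0 means perfect separation; larger values
  mean more interleaving.
* **HS** (hypergeometric score): per node and group an exact upper-tail
  hypergeometric enrichment p-value, Benjamini–Hochberg FDR at q = 0.20
  across all node-by-group tests; the tree score is the mean over groups
  of each group's most significant p-value (lower is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .trees import LineageTree, Node

__all__ = [
    "GroupLabeling",
    "ClusterScoreReport",
    "qlc",
    "tree_entropy",
    "hypergeometric_tail",
    "hypergeometric_score",
    "score_clustering",
]


@dataclass
class GroupLabeling:
    """Map leaf label -> group id, with group sizes."""

    leaf_to_group: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.leaf_to_group.values():
            seen.setdefault(g, None)
        return list(seen)

    def size(self, group: str) -> int:
        return sum(1 for g in self.leaf_to_group.values() if g == group)

    def members(self, group: str) -> set[str]:
        return {l for l, g in self.leaf_to_group.items() if g == group}

    def validate(self, tree: LineageTree) -> None:
        leaves = set(tree.leaf_labels())
        missing = leaves - set(self.leaf_to_group)
        if missing:
            raise ValueError(f"unlabelled leaves: {sorted(missing)[:5]}")
        for group in self.groups:
            if not (self.members(group) & leaves):
                raise ValueError(f"group {group!r} has no members on the tree")

    @classmethod
    def from_leaf_meta(cls, tree: LineageTree, key: str = "individual_id"):
        return cls({l: tree.leaf_meta[l][key] for l in tree.leaf_labels()})


@dataclass
class ClusterScoreReport:
    qlc: float
    qlc_per_type: dict[str, float]
    te_matrix: dict[tuple[str, str], float]
    te_scalar: float
    te_transformed: float
    hs: float
    hs_per_type: dict[str, float]
    significant_nodes: list = field(default_factory=list)


def _node_group_counts(
    tree: LineageTree, labels: GroupLabeling
) -> tuple[list[Node], dict[int, frozenset[str]]]:
    labels.validate(tree)
    leafsets = tree.leafsets()
    nodes = list(tree.postorder())
    return nodes, {n._uid: leafsets[n] for n in nodes}


# ---------------------------------------------------------------------------
# QLC


def qlc(
    tree: LineageTree, labels: GroupLabeling
) -> tuple[float, dict[str, float]]:
    """Quality of the largest cluster; in [0, 1], mean over groups of the
    best node degree (recall x purity, zeroed at purity <= 1/2).

    Every node is a candidate clade, including single leaves (a group of
    one cell is perfectly clustered at its own leaf).
    """
    nodes, leafsets = _node_group_counts(tree, labels)
    per_type: dict[str, float] = {}
    for group in labels.groups:
        members = labels.members(group)
        n_g = len(members)
        best = 0.0
        for node in nodes:
            below = leafsets[node._uid]
            b = len(below & members)
            if b == 0:
                continue
            recall = b / n_g
            purity = b / len(below)
            degree = recall * purity if purity > 0.5 else 0.0
            best = max(best, degree)
        per_type[group] = best
    score = float(np.mean(list(per_type.values())))
    return score, per_type


# ---------------------------------------------------------------------------
# Tree entropy


def _count_clusters(
    tree: LineageTree, members: set[str], pair_leaves: set[str]
) -> int:
    """Number of maximal clades monochromatic for ``members``, restricted
    to the pair's leaves (leaves of other groups are invisible)."""
    leafsets = tree.leafsets()
    status: dict[int, str] = {}  # uid -> 'mono' | 'mixed' | 'empty'
    for node in tree.postorder():
        below = leafsets[node] & pair_leaves
        if not below:
            status[node._uid] = "empty"
        elif below <= members:
            status[node._uid] = "mono"
        else:
            status[node._uid] = "mixed"
    count = 0
    for node in tree.postorder():
        if status[node._uid] != "mono":
            continue
        parent = node.parent
        if parent is None or status[parent._uid] != "mono":
            count += 1
    return count


def tree_entropy(
    tree: LineageTree, labels: GroupLabeling
) -> tuple[dict[tuple[str, str], float], float, float]:
    """Pairwise tree entropies, their mean, and a higher-is-better
    transform (negation) for reporting."""
    labels.validate(tree)
    groups = labels.groups
    if len(groups) < 2:
        raise ValueError("tree entropy needs at least 2 groups")
    te_matrix: dict[tuple[str, str], float] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            ma, mb = labels.members(a), labels.members(b)
            pair_leaves = ma | mb
            c_a = _count_clusters(tree, ma, pair_leaves)
            c_b = _count_clusters(tree, mb, pair_leaves)
            states = math.comb(len(ma) - 1, c_a - 1) * math.comb(
                len(mb) - 1, c_b - 1
            )
            te_matrix[(a, b)] = math.log(states)
    te_scalar = float(np.mean(list(te_matrix.values())))
    return te_matrix, te_scalar, -te_scalar


# ---------------------------------------------------------------------------
# Hypergeometric score


def hypergeometric_tail(N: int, B: int, n_sub: int, b: int) -> float:
    """Exact P(X >= b) for X ~ Hypergeometric(N, B, n_sub)."""
    if not (0 <= b <= min(B, n_sub) and B <= N and n_sub <= N):
        raise ValueError(
            f"inconsistent counts: N={N}, B={B}, n_sub={n_sub}, b={b}"
        )
    return float(hypergeom.sf(b - 1, N, B, n_sub))


def hypergeometric_score(
    tree: LineageTree,
    labels: GroupLabeling,
    fdr_q: float = 0.20,
) -> tuple[float, dict[str, float], list[tuple[str, str, float]]]:
    """Clade-enrichment score: mean over groups of the most significant
    node p-value, plus the BH-FDR-significant (node, group) tests."""
    nodes, leafsets = _node_group_counts(tree, labels)
    N = len(tree.leaf_labels())
    tests: list[tuple[str, str, float]] = []  # (node repr, group, p)
    per_type: dict[str, float] = {}
    for group in labels.groups:
        members = labels.members(group)
        B = len(members)
        best = 1.0
        for node in nodes:
            below = leafsets[node._uid]
            if len(below) == N and node is tree.root:
                continue  # the whole tree is not an informative clade
            b = len(below & members)
            p = hypergeometric_tail(N, B, len(below), b)
            tests.append((",".join(sorted(below)[:3]), group, p))
            best = min(best, p)
        per_type[group] = best
    pvals = [t[2] for t in tests]
    reject, *_ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    significant = [t for t, r in zip(tests, reject) if r]
    hs = float(np.mean(list(per_type.values())))
    return hs, per_type, significant


def score_clustering(
    tree: LineageTree, labels: GroupLabeling, fdr_q: float = 0.20
) -> ClusterScoreReport:
    """All three clustering statistics in one report."""
    qlc_score, qlc_types = qlc(tree, labels)
    te_matrix, te_scalar, te_trans = tree_entropy(tree, labels)
    hs, hs_types, significant = hypergeometric_score(tree, labels, fdr_q)
    return ClusterScoreReport(
        qlc=qlc_score,
        qlc_per_type=qlc_types,
        te_matrix=te_matrix,
        te_scalar=te_scalar,
        te_transformed=te_trans,
        hs=hs,
        hs_per_type=hs_types,
        significant_nodes=significant,
    )
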