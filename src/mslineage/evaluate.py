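"""Benchmark layer: tree comparison, method ranking, reliability tests.

Given per-dataset, per-method scores this module derives the summary
tables used to compare reconstruction methods (average score, normalized
average score, average rank, times-ranked-best, with tied methods sharing
a rank) and implements the two reliability procedures: locus bootstrap
(resampling loci with replacement, 100 trees by default) and the
leaf-label permutation test for clustering significance.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import GroupLabeling, hypergeometric_score, qlc, tree_entropy
from .distances import build_distance_matrix
from .reconstruction import reconstruct
from .signatures import AlleleKey, CellSignature, Dataset
from .trees import LineageTree

__all__ = [
    "SCORE_ORIENTATIONS",
    "partition_similarity",
    "rank_methods",
    "bootstrap_loci",
    "permutation_test",
]

#: score name -> True when higher values mean better performance
SCORE_ORIENTATIONS: dict[str, bool] = {
    "QLC": True,
    "TE": False,
    "HS": False,
    "KS-D": True,
    "KS-p": False,
    "ND": True,
    "Overlap": False,
}


# ---------------------------------------------------------------------------
# topology comparison


def partition_similarity(t1: LineageTree, t2: LineageTree) -> float:
    """Fraction of shared internal-edge leaf bipartitions (Penny & Hendy).

    1.0 iff the two trees induce identical bipartition sets; trees with no
    internal edges (stars) compare as 1.0 to each other.
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    p1, p2 = t1.bipartitions(), t2.bipartitions()
    total = max(len(p1), len(p2))
    if total == 0:
        return 1.0
    return len(p1 & p2) / total


# ---------------------------------------------------------------------------
# ranking


def rank_methods(
    report: pd.DataFrame,
    orientations: Mapping[str, bool] | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables across datasets for every score.

    ``report`` columns: ``dataset``, ``method``, ``score_name``, ``value``.
    Returns ``average_score`` (raw means), ``normalized_average`` (per
    dataset each method relative to the best, oriented so 1 = best),
    ``average_rank`` (rank 1 = best; ties share the best rank) and
    ``top_rank_counts`` — all indexed by method with one column per score.
    """
    orientations = dict(SCORE_ORIENTATIONS, **(orientations or {}))
    required = {"dataset", "method", "score_name", "value"}
    if not required <= set(report.columns):
        raise ValueError(f"report must have columns {sorted(required)}")

    avg, norm, rank, top = {}, {}, {}, {}
    for score_name, sub in report.groupby("score_name"):
        higher_better = orientations.get(score_name, True)
        table = sub.pivot_table(
            index="dataset", columns="method", values="value", aggfunc="mean"
        )
        avg[score_name] = table.mean(axis=0, skipna=True)

        oriented = table if higher_better else -table
        ranks = oriented.rank(axis=1, method="min", ascending=False)
        rank[score_name] = ranks.mean(axis=0, skipna=True)
        top[score_name] = (ranks == 1.0).sum(axis=0)

        norm[score_name] = table.apply(
            lambda row: _normalize_row(row, higher_better), axis=1
        ).mean(axis=0, skipna=True)

    return {
        "average_score": pd.DataFrame(avg),
        "normalized_average": pd.DataFrame(norm),
        "average_rank": pd.DataFrame(rank),
        "top_rank_counts": pd.DataFrame(top),
    }


def _normalize_row(row: pd.Series, higher_better: bool) -> pd.Series:
    """Relative-to-best scores in [0, 1], 1 = the dataset's best method."""
    vals = row.astype(float)
    if higher_better:
        best = vals.max()
        if best == 0:
            return (vals == 0).astype(float)
        if best < 0:  # all-negative transformed scores: shift to [0, 1]
            worst = vals.min()
            span = best - worst
            return (vals - worst) / span if span else vals * 0 + 1.0
        return vals / best
    best = vals.min()
    out = pd.Series(np.nan, index=vals.index)
    for key, v in vals.items():
        if v == best:
            out[key] = 1.0
        elif v > 0:
            out[key] = best / v
        else:
            out[key] = 0.0
    return out


# ---------------------------------------------------------------------------
# bootstrap over loci


def bootstrap_loci(
    dataset: Dataset,
    measure: str = "normabs",
    algorithm: str = "nj",
    n_boot: int = 100,
    seed: int = 0,
    labels: GroupLabeling | None = None,
    min_shared: int = 1,
) -> tuple[dict[frozenset[str], float], pd.DataFrame]:
    """Locus bootstrap: branch supports and score distributions.

    Loci (allele-key groups sharing a locus name, so autosomal allele pairs
    stay together) are drawn with replacement; each resampled dataset is
    reconstructed and, when ``labels`` are given, scored.  Branch support
    is the fraction of bootstrap trees containing each bipartition of the
    tree built from the full dataset.
    """
    loci = dataset.loci()
    if len(loci) < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    rng = np.random.default_rng(seed)

    D_full = build_distance_matrix(
        dataset, measure, include_root=True, min_shared=min_shared
    )
    base_tree = reconstruct(D_full, algorithm)
    base_parts = base_tree.bipartitions()

    counts = {part: 0 for part in base_parts}
    rows = []
    n_used = 0
    for _ in range(n_boot):
        chosen = rng.choice(len(loci), size=len(loci), replace=True)
        boot = _resample_loci(dataset, [loci[i] for i in chosen])
        try:
            D = build_distance_matrix(
                boot, measure, include_root=True, min_shared=min_shared
            )
        except ValueError:
            continue  # a pair lost all usable loci; drop this replicate
        tree = reconstruct(D, algorithm)
        n_used += 1
        parts = tree.bipartitions()
        for part in base_parts:
            if part in parts:
                counts[part] += 1
        if labels is not None:
            q, _ = qlc(tree, labels)
            _, te, _ = tree_entropy(tree, labels)
            hs, _, _ = hypergeometric_score(tree, labels)
            rows.append({"QLC": q, "TE": te, "HS": hs})
    if n_used == 0:
        raise ValueError("no bootstrap replicate produced a usable matrix")
    supports = {part: counts[part] / n_used for part in base_parts}
    scores = pd.DataFrame(rows)
    return supports, scores


def _resample_loci(dataset: Dataset, chosen: list[str]) -> Dataset:
    """Dataset restricted to a multiset of loci (copies renamed)."""
    by_locus: dict[str, list[AlleleKey]] = {}
    for key in dataset.allele_keys():
        by_locus.setdefault(key[0], []).append(key)
    mapping: list[tuple[AlleleKey, AlleleKey]] = []  # (new key, old key)
    panel = {}
    for copy_idx, locus in enumerate(chosen):
        for old in by_locus[locus]:
            new = (f"{locus}~{copy_idx}", old[1])
            mapping.append((new, old))
            panel[new] = dataset.panel.get(old, None) or dataset.panel.get(
                (old[0], 1)
            )
    signatures = []
    for sig in dataset.signatures:
        alleles = {new: sig.alleles.get(old) for new, old in mapping}
        signatures.append(
            CellSignature(
                sample_id=sig.sample_id,
                individual_id=sig.individual_id,
                cell_type=sig.cell_type,
                alleles=alleles,
            )
        )
    root = None
    if dataset.root is not None:
        root_alleles = {}
        for new, old in mapping:
            if old in dataset.root.alleles:
                root_alleles[new] = dataset.root.alleles[old]
        root = dc_replace(dataset.root, alleles=root_alleles)
    return Dataset(
        signatures=signatures, root=root, panel=panel,
        provenance=dataset.provenance + ["bootstrap"],
    )


# ---------------------------------------------------------------------------
# permutation test


def permutation_test(
    tree: LineageTree,
    labels: GroupLabeling,
    score: str = "QLC",
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Leaf-label permutation p-value for a clustering score.

    The topology stays fixed; whole-cell group labels are shuffled.
    p = (1 + #{permutations scoring at least as well}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    score = score.upper()
    if score not in ("QLC", "TE", "HS"):
        raise ValueError("score must be QLC, TE or HS")
    labels.validate(tree)
    higher_better = SCORE_ORIENTATIONS[score]

    def evaluate(lab: GroupLabeling) -> float:
        if score == "QLC":
            return qlc(tree, lab)[0]
        if score == "TE":
            return tree_entropy(tree, lab)[1]
        return hypergeometric_score(tree, lab)[0]

    if len(labels.groups) < 2:
        return 1.0  # degenerate: a single group cannot be separated

    observed = evaluate(labels)
    rng = np.random.default_rng(seed)
    leaves = sorted(labels.leaf_to_group)
    values = [labels.leaf_to_group[l] for l in leaves]
    hits = 0
    for _ in range(n_perm):
        perm = list(rng.permutation(values))
        perm_score = evaluate(GroupLabeling(dict(zip(leaves, perm))))
        good = perm_score >= observed if higher_better else perm_score <= observed
        if good:
            hits += 1
    return (1 + hits) / (1 + n_perm)
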