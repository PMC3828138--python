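"""Forward simulation of MS mutation accrual on lineage trees.

Replicates the benchmark's study conditions: a scaffold tree (root ->
individual zygotes -> cell-type MRCAs -> random binary subtrees to the
sampled cells) with branch lengths in divisions; along every branch of
length ``t`` each locus mutates ``Binomial(t, mu)`` times and each
mutation adds a signed step from the step model (±1 under SMM).  Leaf
repeat counts are reflected at 1 (a repeat count cannot drop below one
unit).  The applied per-branch net changes are recorded so a replicate can
be replayed exactly.

Three study designs are provided:

* ``simulate_replicate`` — the general multi-individual / multi-cell-type
  topologies (presets A: leaves far from their MRCAs; B: leaves close).
* ``simulate_two_stage`` — two "brother" individuals diverging from their
  mother's zygote after ``stage1`` divisions, every cell then accruing
  ``stage2`` divisions; used to study when individuals stop being
  separable.
* ``simulate_depth_pair`` — two cohorts at different known depths
  (shallow: 20 vs 50 divisions; deep: 250 vs 300).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .clustering import GroupLabeling
from .distances import StepModel, build_distance_matrix
from .reconstruction import reconstruct
from .signatures import AlleleKey, CellSignature, Dataset, LocusInfo, RootSignature
from .trees import LineageTree, Node

__all__ = [
    "SimulationConfig",
    "SimulatedReplicate",
    "simulate_replicate",
    "simulate_two_stage",
    "simulate_depth_pair",
    "separation_fraction",
    "replay_leaf_signatures",
]

#: Ancestral repeat counts are drawn uniformly from this closed range.
INITIAL_REPEAT_RANGE = (10, 30)

#: Depth presets (root->zygote, zygote->MRCA, MRCA->leaf) for the two
#: scaffold shapes: A = deep leaves below shallow MRCAs, B = the reverse.
TOPOLOGY_PRESETS = {"A": (5, 5, 50), "B": (50, 50, 5)}


@dataclass
class SimulationConfig:
    topology: str = "A"  # A | B | two_stage | depth_pair
    n_individuals: int = 3
    cell_types_per_individual: int = 5
    cells_per_type: int = 5
    root_to_zygote: int | None = None
    zygote_to_mrca: int | None = None
    mrca_to_leaf: int | None = None
    mutation_rate: float = 1.0 / 100.0
    n_loci: int = 100
    step: StepModel = field(default_factory=lambda: StepModel("SMM"))
    mono_fraction: float = 0.5  # fraction of loci with 1-bp repeat unit
    missing_rate: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        for name in (
            "n_individuals",
            "cell_types_per_individual",
            "cells_per_type",
            "n_loci",
            "n_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.topology in TOPOLOGY_PRESETS:
            d1, d2, d3 = TOPOLOGY_PRESETS[self.topology]
            self.root_to_zygote = d1 if self.root_to_zygote is None else self.root_to_zygote
            self.zygote_to_mrca = d2 if self.zygote_to_mrca is None else self.zygote_to_mrca
            self.mrca_to_leaf = d3 if self.mrca_to_leaf is None else self.mrca_to_leaf


@dataclass
class SimulatedReplicate:
    true_tree: LineageTree
    dataset: Dataset
    labels: GroupLabeling
    events: dict[tuple[int, AlleleKey], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scaffold construction


def _random_binary_subtree(
    parent: Node, leaf_labels: Sequence[str], total_depth: int, rng
) -> None:
    """Attach a random coalescent-shaped binary tree over ``leaf_labels``
    below ``parent``, every leaf ``total_depth`` divisions below it."""
    nodes = [Node(label) for label in leaf_labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    top = nodes[0]

    # place internal nodes proportionally between parent and the leaves
    def level_height(node: Node, level: int) -> int:
        if node.is_leaf:
            node.depth = float(total_depth)
            return 0
        h = 1 + max(level_height(c, level + 1) for c in node.children)
        node.depth = total_depth * level / (level + h) if total_depth else 0.0
        return h

    level_height(top, 0)
    parent.add_child(top)

    # branch lengths from rounded depths; monotone by construction
    def set_bl(node: Node, parent_depth: int) -> None:
        d = int(round(node.depth))
        node.branch_length = float(max(d - parent_depth, 0))
        for c in node.children:
            set_bl(c, d)

    set_bl(top, 0)


def _build_scaffold(config: SimulationConfig) -> tuple[LineageTree, dict[str, str], dict[str, str]]:
    """Scaffold tree plus leaf -> individual and leaf -> cell-type maps."""
    rng = np.random.default_rng(config.seed + 1)
    root = Node("root")
    by_ind: dict[str, str] = {}
    by_type: dict[str, str] = {}
    for i in range(config.n_individuals):
        ind = f"I{i + 1}"
        zygote = Node(branch_length=float(config.root_to_zygote))
        root.add_child(zygote)
        for t in range(config.cell_types_per_individual):
            ctype = f"T{t + 1}"
            mrca = Node(branch_length=float(config.zygote_to_mrca))
            zygote.add_child(mrca)
            leaf_labels = [
                f"{ind}_{ctype}_C{c + 1}" for c in range(config.cells_per_type)
            ]
            _random_binary_subtree(mrca, leaf_labels, config.mrca_to_leaf, rng)
            for label in leaf_labels:
                by_ind[label] = ind
                by_type[label] = f"{ind}:{ctype}"
    tree = LineageTree(root, rooted=True)
    tree.assign_depths()
    return tree, by_ind, by_type


# ---------------------------------------------------------------------------
# mutation accrual


def _make_panel(config: SimulationConfig) -> dict[AlleleKey, LocusInfo]:
    panel: dict[AlleleKey, LocusInfo] = {}
    n_mono = int(round(config.mono_fraction * config.n_loci))
    for i in range(config.n_loci):
        unit = 1 if i < n_mono else 2
        panel[(f"L{i + 1:04d}", 1)] = LocusInfo(basic_unit_length=unit)
    return panel


def _accrue_mutations(
    tree: LineageTree,
    root_values: np.ndarray,
    keys: list[AlleleKey],
    config: SimulationConfig,
    rng,
) -> tuple[dict[int, np.ndarray], dict[tuple[int, AlleleKey], int]]:
    """Simulate repeat counts at every node; returns per-node value arrays
    and the recorded per-branch applied deltas."""
    steps = np.array(sorted(config.step.step_distribution))
    probs = np.array([config.step.step_distribution[s] for s in steps])
    values: dict[int, np.ndarray] = {tree.root._uid: root_values.copy()}
    events: dict[tuple[int, AlleleKey], int] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_vals = values[node.parent._uid]
        vals = parent_vals.copy()
        t = int(round(node.branch_length))
        if t > 0:
            m = rng.binomial(t, config.mutation_rate, size=len(keys))
            for idx in np.nonzero(m)[0]:
                delta = int(rng.choice(steps, size=m[idx], p=probs).sum())
                new = vals[idx] + delta
                if new < 1:
                    new = 1  # reflect at the one-repeat floor
                applied = int(new - vals[idx])
                vals[idx] = new
                if applied != 0:
                    events[(node._uid, keys[idx])] = applied
        values[node._uid] = vals
    return values, events


def simulate_replicate(config: SimulationConfig) -> SimulatedReplicate:
    """One synthetic dataset drawn under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    tree, by_ind, by_type = _build_scaffold(config)
    panel = _make_panel(config)
    keys = sorted(panel)
    root_values = rng.integers(
        INITIAL_REPEAT_RANGE[0], INITIAL_REPEAT_RANGE[1] + 1, size=len(keys)
    ).astype(int)
    values, events = _accrue_mutations(tree, root_values, keys, config, rng)

    signatures = []
    for leaf in tree.leaves():
        vals = values[leaf._uid]
        alleles: dict[AlleleKey, int | None] = {}
        for k, key in enumerate(keys):
            miss = config.missing_rate > 0 and rng.random() < config.missing_rate
            alleles[key] = None if miss else int(vals[k])
        signatures.append(
            CellSignature(
                sample_id=leaf.label,
                individual_id=by_ind[leaf.label],
                cell_type=by_type[leaf.label],
                alleles=alleles,
            )
        )
        tree.leaf_meta[leaf.label] = {
            "individual_id": by_ind[leaf.label],
            "cell_type": by_type[leaf.label],
        }
    root_sig = RootSignature(
        alleles={key: float(v) for key, v in zip(keys, root_values)},
        policy="simulated_zygote",
    )
    dataset = Dataset(
        signatures=signatures, root=root_sig, panel=panel,
        provenance=[f"simulated:{config.topology}:seed={config.seed}"],
    )
    labels = GroupLabeling(dict(by_ind))
    return SimulatedReplicate(
        true_tree=tree, dataset=dataset, labels=labels, events=events
    )


def replay_leaf_signatures(rep: SimulatedReplicate) -> dict[str, dict[AlleleKey, int]]:
    """Re-apply the recorded mutation events from the root down; the result
    must match the stored leaf signatures exactly (conservation check)."""
    root = rep.dataset.root
    out: dict[str, dict[AlleleKey, int]] = {}
    for leaf in rep.true_tree.leaves():
        path = []
        cur = leaf
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        sig = {key: int(round(v)) for key, v in root.alleles.items()}
        for node in reversed(path):
            for key in sig:
                delta = rep.events.get((node._uid, key))
                if delta:
                    sig[key] += delta
        out[leaf.label] = sig
    return out


# ---------------------------------------------------------------------------
# two-stage brothers design


def simulate_two_stage(
    ratio: float,
    stage1: int = 40,
    n_cells_per_individual: int = 3,
    n_loci: int = 50,
    mu: float = 0.01,
    n_replicates: int = 1,
    seed: int = 0,
    step: StepModel | None = None,
    ratio_convention: str = "stage2_over_stage1",
) -> list[SimulatedReplicate]:
    """Two individuals diverging ``stage1`` divisions after their mother's
    zygote; every sampled cell then accrues ``stage2`` divisions.

    ``ratio_convention`` controls the meaning of ``ratio``:
    ``stage2_over_stage1`` (default) sets stage2 = ratio * stage1;
    ``divergence_over_depth`` reads ``ratio`` as stage1/stage2 (so 0.2 with
    stage1 = 40 gives stage2 = 200).
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    if ratio_convention == "stage2_over_stage1":
        stage2 = ratio * stage1
    elif ratio_convention == "divergence_over_depth":
        stage2 = stage1 / ratio
    else:
        raise ValueError(f"unknown ratio convention {ratio_convention!r}")
    if abs(stage2 - round(stage2)) > 1e-9:
        warnings.warn(f"stage2 = {stage2} rounded to {round(stage2)} divisions")
    stage2 = int(round(stage2))

    out = []
    for r in range(n_replicates):
        config = SimulationConfig(
            topology="two_stage",
            n_individuals=2,
            cell_types_per_individual=1,
            cells_per_type=n_cells_per_individual,
            root_to_zygote=stage1,
            zygote_to_mrca=0,
            mrca_to_leaf=stage2,
            mutation_rate=mu,
            n_loci=n_loci,
            step=step or StepModel("SMM"),
            seed=seed + r,
        )
        # star below each zygote: every cell independent over stage2
        rep = _simulate_star(config)
        out.append(rep)
    return out


def _simulate_star(config: SimulationConfig) -> SimulatedReplicate:
    """Like :func:`simulate_replicate` but each individual's cells hang
    directly from its zygote (no within-individual structure)."""
    rng = np.random.default_rng(config.seed)
    root = Node("root")
    by_ind: dict[str, str] = {}
    for i in range(config.n_individuals):
        ind = f"I{i + 1}"
        zygote = Node(branch_length=float(config.root_to_zygote))
        root.add_child(zygote)
        for c in range(config.cells_per_type):
            label = f"{ind}_C{c + 1}"
            zygote.add_child(Node(label, branch_length=float(config.mrca_to_leaf)))
            by_ind[label] = ind
    tree = LineageTree(root, rooted=True)
    tree.assign_depths()

    panel = _make_panel(config)
    keys = sorted(panel)
    root_values = rng.integers(
        INITIAL_REPEAT_RANGE[0], INITIAL_REPEAT_RANGE[1] + 1, size=len(keys)
    ).astype(int)
    values, events = _accrue_mutations(tree, root_values, keys, config, rng)
    signatures = []
    for leaf in tree.leaves():
        alleles = {key: int(v) for key, v in zip(keys, values[leaf._uid])}
        signatures.append(
            CellSignature(
                sample_id=leaf.label,
                individual_id=by_ind[leaf.label],
                cell_type="cell",
                alleles=alleles,
            )
        )
        tree.leaf_meta[leaf.label] = {
            "individual_id": by_ind[leaf.label], "cell_type": "cell"
        }
    root_sig = RootSignature(
        alleles={key: float(v) for key, v in zip(keys, root_values)},
        policy="simulated_zygote",
    )
    dataset = Dataset(
        signatures=signatures, root=root_sig, panel=panel,
        provenance=[f"simulated:{config.topology}:seed={config.seed}"],
    )
    return SimulatedReplicate(
        true_tree=tree,
        dataset=dataset,
        labels=GroupLabeling(dict(by_ind)),
        events=events,
    )


def simulate_depth_pair(
    scenario: str = "shallow",
    n_loci: int = 100,
    mu: float = 0.01,
    n_cells_per_group: int = 10,
    n_replicates: int = 1,
    seed: int = 0,
    step: StepModel | None = None,
) -> list[SimulatedReplicate]:
    """Two cohorts of cells at different known depths below one zygote.

    ``shallow``: 20 vs 50 divisions; ``deep``: 250 vs 300 divisions.  The
    cohorts share the upper scaffold (a common zygote at the root); group
    ids are ``shallow``/``deep``-agnostic cohort names ``G1`` (lesser
    depth) and ``G2``.
    """
    depths = {"shallow": (20, 50), "deep": (250, 300)}
    if scenario not in depths:
        raise ValueError(f"scenario must be one of {sorted(depths)}")
    d1, d2 = depths[scenario]
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        config = SimulationConfig(
            topology="depth_pair",
            n_individuals=1,
            cell_types_per_individual=2,
            cells_per_type=n_cells_per_group,
            root_to_zygote=0,
            zygote_to_mrca=0,
            mrca_to_leaf=0,
            mutation_rate=mu,
            n_loci=n_loci,
            step=step or StepModel("SMM"),
            seed=seed + r,
        )
        root = Node("root")
        by_group: dict[str, str] = {}
        for gname, gdepth in (("G1", d1), ("G2", d2)):
            for c in range(n_cells_per_group):
                label = f"{gname}_C{c + 1}"
                root.add_child(Node(label, branch_length=float(gdepth)))
                by_group[label] = gname
        tree = LineageTree(root, rooted=True)
        tree.assign_depths()
        panel = _make_panel(config)
        keys = sorted(panel)
        root_values = rng.integers(
            INITIAL_REPEAT_RANGE[0], INITIAL_REPEAT_RANGE[1] + 1, size=len(keys)
        ).astype(int)
        values, events = _accrue_mutations(tree, root_values, keys, config, rng)
        signatures = []
        for leaf in tree.leaves():
            alleles = {key: int(v) for key, v in zip(keys, values[leaf._uid])}
            signatures.append(
                CellSignature(
                    sample_id=leaf.label,
                    individual_id="I1",
                    cell_type=by_group[leaf.label],
                    alleles=alleles,
                )
            )
            tree.leaf_meta[leaf.label] = {
                "individual_id": "I1", "cell_type": by_group[leaf.label]
            }
        root_sig = RootSignature(
            alleles={key: float(v) for key, v in zip(keys, root_values)},
            policy="simulated_zygote",
        )
        dataset = Dataset(
            signatures=signatures, root=root_sig, panel=panel,
            provenance=[f"simulated:depth_pair:{scenario}:seed={seed + r}"],
        )
        out.append(
            SimulatedReplicate(
                true_tree=tree,
                dataset=dataset,
                labels=GroupLabeling(dict(by_group)),
                events=events,
            )
        )
    return out


# ---------------------------------------------------------------------------
# separation


def separation_fraction(
    replicates: Iterable[SimulatedReplicate],
    measure: str = "normabs",
    algorithm: str = "nj",
    min_shared: int = 1,
) -> float:
    """Fraction of replicates in which every individual's cells form a
    clade of the reconstructed tree.

    Monophyly is judged in the unrooted sense: an individual is separated
    when some edge of the tree splits exactly its cells from all other
    cells.  The zygote pseudo-leaf used for rooting is not a cell, so its
    attachment point does not affect separation (a group is also counted
    as a clade when the *complement* of its cells is a clade of the rooted
    tree, which happens when the root attaches inside the group's subtree).
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates")
    n_sep = 0
    for rep in reps:
        if len(rep.labels.groups) < 2:
            raise ValueError("separation needs >= 2 individuals per replicate")
        D = build_distance_matrix(
            rep.dataset, measure, include_root=True, min_shared=min_shared
        )
        tree = reconstruct(D, algorithm)
        all_cells = set(tree.leaf_labels())
        ok = True
        for g in rep.labels.groups:
            members = rep.labels.members(g)
            if not (
                tree.is_monophyletic(members)
                or tree.is_monophyletic(all_cells - members)
            ):
                ok = False
                break
        if ok:
            n_sep += 1
    return n_sep / len(reps)
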