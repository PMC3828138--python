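"""Depth-separation statistics between two leaf groups.

Reconstructed depths vary even when the true division counts are equal, so
each group's depth is a distribution.  Three statistics compare them:

* the two-sample Kolmogorov–Smirnov test (distribution equality),
* the normalized distance ``|mean_x - mean_y| / sqrt(sd_x^2 + sd_y^2)``
  between the group means (higher = better separated), and
* the overlap percentage — the fraction of cross-group data-point pairs in
  which a point of one group penetrates past a point of the other (lower =
  better separated; driven by the extreme cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .clustering import GroupLabeling
from .trees import LineageTree

__all__ = [
    "DepthSample",
    "leaf_depths",
    "ks_statistic",
    "normalized_distance",
    "overlap_percentage",
]


@dataclass
class DepthSample:
    group_id: str
    depths: list[float]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be >= 0")


def leaf_depths(
    tree: LineageTree, labels: GroupLabeling, group: str
) -> DepthSample:
    """Depth (divisions from root) of every leaf in ``group``."""
    members = labels.members(group)
    if not members:
        raise KeyError(f"group {group!r} not in labeling")
    depths = [tree.leaf_depth(label) for label in sorted(members)]
    return DepthSample(group_id=group, depths=depths)


def _arrays(x: DepthSample, y: DepthSample) -> tuple[np.ndarray, np.ndarray]:
    ax, ay = np.asarray(x.depths, float), np.asarray(y.depths, float)
    if ax.size == 0 or ay.size == 0:
        raise ValueError("depth samples must be non-empty")
    return ax, ay


def ks_statistic(x: DepthSample, y: DepthSample) -> tuple[float, float]:
    """Two-sample KS statistic D and its p-value."""
    ax, ay = _arrays(x, y)
    res = ks_2samp(ax, ay, method="asymp" if ax.size * ay.size > 400 else "auto")
    return float(res.statistic), float(res.pvalue)


def normalized_distance(x: DepthSample, y: DepthSample) -> float:
    """|mean difference| scaled by the pooled spread (root-sum-of-squares
    of the two sample SDs); +inf when both SDs are zero but means differ."""
    ax, ay = _arrays(x, y)
    num = abs(float(ax.mean() - ay.mean()))
    sx = float(ax.std(ddof=1)) if ax.size > 1 else 0.0
    sy = float(ay.std(ddof=1)) if ay.size > 1 else 0.0
    denom = float(np.hypot(sx, sy))
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero spread in both groups; normalized distance is inf")
        return float("inf")
    return num / denom


def overlap_percentage(x: DepthSample, y: DepthSample) -> float:
    """Percentage in [0, 100] of cross pairs in which the groups
    interpenetrate; ties count as penetration.

    The count of pairs ``x_i >= y_j`` and of pairs ``y_j >= x_i`` measure
    penetration in the two directions; the smaller of the two (0 whenever
    the supports are disjoint, in either order) is normalized by the total
    number of cross pairs.
    """
    ax, ay = _arrays(x, y)
    ge_xy = int(np.sum(ax[:, None] >= ay[None, :]))
    ge_yx = int(np.sum(ay[:, None] >= ax[None, :]))
    return 100.0 * min(ge_xy, ge_yx) / (ax.size * ay.size)
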