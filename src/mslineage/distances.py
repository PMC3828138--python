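"""Pairwise distance measures between cell MS signatures.

Six measure families, all computed over the alleles amplified in both cells
of a pair:

* ``absolute`` — mean absolute repeat-count difference.
* ``normabs`` — mean *length-normalized* absolute difference: each allele's
  difference is divided by the pair-mean repeat count at that allele.  MS
  slippage rates grow roughly linearly with repeat number, so this gives
  loci with fewer expected mutations a larger weight and strips the
  length-driven component of the signal; depths for trees built from this
  measure are taken from the absolute measure instead.
* ``euclidean`` — root-mean-square repeat difference.
* ``equal_or_not`` — number of shared alleles whose repeat counts differ.
* ``ml_smm`` / ``ml_mmm`` — maximum-likelihood estimate of the number of
  divisions separating the pair under a stepwise (±1) or multistep
  symmetric mutation model, with per-locus rates from one of three rate
  models (equal, mono/di, length-dependent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .signatures import (
    MIN_SHARED_DEFAULT,
    AlleleKey,
    CellSignature,
    Dataset,
    LocusInfo,
    RootSignature,
    shared_valid_alleles,
)

__all__ = [
    "MutationRateModel",
    "StepModel",
    "DistanceMatrix",
    "absolute_distance",
    "normalized_absolute_distance",
    "euclidean_distance",
    "equal_or_not_distance",
    "step_transition_probability",
    "transition_table",
    "ml_distance",
    "build_distance_matrix",
    "MEASURES",
    "ROOT_LABEL",
]

#: Label of the pseudo-leaf representing the putative zygote.
ROOT_LABEL = "__root__"

# Default per-division mutation rates (mouse MMR-deficient panel unless
# noted): one shared rate, unit-length-specific rates, and a linear
# length-dependent law mu = slope * repeats + intercept.  The human panel
# uses a single per-meiosis rate.
MOUSE_EQUAL_RATE = 1.0 / 30.0
MOUSE_MONO_RATE = 1.0 / 22.0
MOUSE_DI_RATE = 1.0 / 32.0
MOUSE_LENGTH_SLOPE = 0.0183
MOUSE_LENGTH_INTERCEPT = 1.0 / 2000.0
HUMAN_EQUAL_RATE = 1.0 / 1000.0


@dataclass
class MutationRateModel:
    """Per-locus per-division MS mutation rate model."""

    kind: str = "equal"  # equal | mono_di | length_dependent
    equal_rate: float = MOUSE_EQUAL_RATE
    mono_rate: float = MOUSE_MONO_RATE
    di_rate: float = MOUSE_DI_RATE
    slope: float = MOUSE_LENGTH_SLOPE
    intercept: float = MOUSE_LENGTH_INTERCEPT

    def __post_init__(self) -> None:
        for name in ("equal_rate", "mono_rate", "di_rate"):
            rate = getattr(self, name)
            if not 0.0 < rate < 1.0:
                raise ValueError(f"{name} must be in (0, 1); got {rate}")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")

    def rate_for(self, info: LocusInfo, mean_repeats: float) -> float:
        """Per-division rate for one allele.

        The length-dependent law is parameterized by the pair-mean repeat
        number at the allele (the model does not say which cell's length
        applies, and the mean is symmetric in the pair).
        """
        if self.kind == "equal":
            return self.equal_rate
        if self.kind == "mono_di":
            return self.mono_rate if info.basic_unit_length == 1 else self.di_rate
        if self.kind == "length_dependent":
            mu = self.slope * mean_repeats + self.intercept
            return min(max(mu, 1e-12), 1.0 - 1e-12)
        raise ValueError(f"unknown rate model kind {self.kind!r}")


def _truncated_geometric_steps(p: float, s_max: int) -> dict[int, float]:
    """Symmetric truncated-geometric step law for the multistep model."""
    weights = {s: p * (1 - p) ** (s - 1) for s in range(1, s_max + 1)}
    total = 2 * sum(weights.values())
    return {
        s * sign: w / total
        for s, w in weights.items()
        for sign in (+1, -1)
    }


@dataclass
class StepModel:
    """Distribution of the signed repeat-count step, given a mutation.

    ``SMM``: ±1 with equal probability.  ``MMM``: multiple repeat units per
    event, symmetric truncated-geometric over ±1..±s_max.
    """

    kind: str = "SMM"
    step_distribution: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.step_distribution:
            if self.kind == "SMM":
                self.step_distribution = {+1: 0.5, -1: 0.5}
            elif self.kind == "MMM":
                self.step_distribution = _truncated_geometric_steps(0.5, 5)
            else:
                raise ValueError(f"unknown step model kind {self.kind!r}")
        total = sum(self.step_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"step distribution sums to {total}, not 1")
        for step, prob in self.step_distribution.items():
            if step == 0:
                raise ValueError("step 0 is not a mutation")
            if abs(prob - self.step_distribution.get(-step, -1.0)) > 1e-9:
                raise ValueError("step distribution must be symmetric about 0")

    @property
    def max_step(self) -> int:
        return max(abs(s) for s in self.step_distribution)

    def pmf_array(self) -> np.ndarray:
        """Step pmf on the integer window [-max_step, +max_step]."""
        m = self.max_step
        arr = np.zeros(2 * m + 1)
        for step, prob in self.step_distribution.items():
            arr[step + m] = prob
        return arr


# ---------------------------------------------------------------------------
# simple measures


def _pair_values(
    si: CellSignature, sj: CellSignature, shared: Iterable[AlleleKey]
) -> tuple[np.ndarray, np.ndarray, list[AlleleKey]]:
    keys = sorted(shared)
    if not keys:
        raise ValueError("empty shared allele set; distance undefined")
    xi = np.array([si.alleles[k] for k in keys], dtype=float)
    xj = np.array([sj.alleles[k] for k in keys], dtype=float)
    return xi, xj, keys


def absolute_distance(
    si: CellSignature, sj: CellSignature, shared: Iterable[AlleleKey]
) -> float:
    """Mean |x_i - x_j| over the shared alleles."""
    xi, xj, _ = _pair_values(si, sj, shared)
    return float(np.mean(np.abs(xi - xj)))


def normalized_absolute_distance(
    si: CellSignature,
    sj: CellSignature,
    shared: Iterable[AlleleKey],
    root: RootSignature | None = None,
) -> float:
    """Mean of |x_i - x_j| / ((x_i + x_j)/2) over the shared alleles.

    Alleles with a zero normalizer (impossible for valid repeat counts, but
    deviation-coded inputs may produce them) are skipped with a warning.
    ``root`` is accepted for interface symmetry; the normalizer is built
    from the pair itself.
    """
    del root
    xi, xj, _ = _pair_values(si, sj, shared)
    norm = (xi + xj) / 2.0
    ok = norm != 0
    if not np.all(ok):
        warnings.warn("alleles with zero normalizer skipped")
        if not np.any(ok):
            raise ValueError("all shared alleles have zero normalizer")
    return float(np.mean(np.abs(xi[ok] - xj[ok]) / norm[ok]))


def euclidean_distance(
    si: CellSignature,
    sj: CellSignature,
    shared: Iterable[AlleleKey],
    normalize: bool = True,
) -> float:
    """Root-mean-square repeat difference (root-sum-of-squares when
    ``normalize=False``)."""
    xi, xj, _ = _pair_values(si, sj, shared)
    ss = float(np.sum((xi - xj) ** 2))
    if normalize:
        ss /= len(xi)
    return math.sqrt(ss)


def equal_or_not_distance(
    si: CellSignature,
    sj: CellSignature,
    shared: Iterable[AlleleKey],
    normalize: bool = False,
) -> float:
    """Number (fraction when ``normalize=True``) of shared alleles whose
    repeat counts differ."""
    xi, xj, _ = _pair_values(si, sj, shared)
    count = float(np.count_nonzero(xi != xj))
    return count / len(xi) if normalize else count


# ---------------------------------------------------------------------------
# stepwise-model transition probabilities and the ML divergence estimator


def step_transition_probability(
    delta: int, t: int, mu: float, step: StepModel | None = None
) -> float:
    """P(net repeat change = delta after t divisions).

    Per division a mutation occurs with probability ``mu``; given a
    mutation, the signed step is drawn from the step model.  Computed by
    iterated discrete convolution of the per-division change distribution.
    """
    if step is None:
        step = StepModel("SMM")
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1); got {mu}")
    if t < 0:
        raise ValueError(f"t must be >= 0; got {t}")
    table = transition_table(t, mu, step, max_abs_delta=abs(int(delta)))
    return float(table[t, abs(int(delta))])


_TABLE_CACHE: dict[tuple, np.ndarray] = {}


def transition_table(
    t_max: int,
    mu: float,
    step: StepModel,
    max_abs_delta: int | None = None,
) -> np.ndarray:
    """Array ``P[t, |delta|]`` of net-change probabilities for t = 0..t_max.

    Only the non-negative half of the (symmetric) change distribution is
    stored; ``P[t, d]`` is the probability of net change +d (= that of -d).
    """
    m = step.max_step
    if max_abs_delta is None:
        max_abs_delta = min(t_max * m, 200)
    key = (t_max, mu, tuple(sorted(step.step_distribution.items())), max_abs_delta)
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]

    # per-division change pmf on [-m, +m]
    kernel = mu * step.pmf_array()
    kernel[m] += 1.0 - mu

    # working half-width: wide enough that truncating the walk outside it
    # loses negligible mass even at t_max (mean + 10 SD of the step count)
    lam = t_max * mu
    slack = int(math.ceil(m * (lam + 10.0 * math.sqrt(lam) + 10.0)))
    width = max(max_abs_delta + m, min(slack, t_max * m + m))
    size = 2 * width + 1
    pmf = np.zeros(size)
    pmf[width] = 1.0  # t = 0: no change
    out = np.zeros((t_max + 1, max_abs_delta + 1))
    out[0, 0] = 1.0
    for t in range(1, t_max + 1):
        pmf = np.convolve(pmf, kernel)[m:-m]  # keep window centred
        out[t, :] = pmf[width : width + max_abs_delta + 1]
    _TABLE_CACHE[key] = out
    return out


def ml_distance(
    si: CellSignature,
    sj: CellSignature,
    shared: Iterable[AlleleKey],
    step: StepModel,
    rates: MutationRateModel,
    t_grid: Sequence[int] | None = None,
    panel: Mapping[AlleleKey, LocusInfo] | None = None,
    t_max: int = 1000,
) -> float:
    """Maximum-likelihood number of divisions separating two cells.

    Loci are treated as independent; the log-likelihood of a separation of
    ``t`` divisions is the sum over shared alleles of
    ``log P(x_i - x_j | t, mu_allele)`` and the estimate is the argmax over
    an integer grid 0..t_max.
    """
    xi, xj, keys = _pair_values(si, sj, shared)
    deltas = np.abs(xi - xj).astype(int)
    if t_grid is None:
        t_grid = np.arange(0, t_max + 1)
    else:
        t_grid = np.asarray(list(t_grid), dtype=int)
    grid_max = int(t_grid.max())
    panel = panel or {}

    max_delta = int(deltas.max()) if len(deltas) else 0
    loglik = np.zeros(len(t_grid))
    # group alleles by rate so one transition table serves many loci
    mus: dict[float, list[int]] = {}
    for idx, key in enumerate(keys):
        info = panel.get(key, LocusInfo())
        mu = rates.rate_for(info, (xi[idx] + xj[idx]) / 2.0)
        if mu <= 0.0:
            raise ValueError(f"zero mutation rate at allele {key}")
        mus.setdefault(round(mu, 12), []).append(idx)
    for mu, idxs in mus.items():
        table = transition_table(grid_max, mu, step, max_abs_delta=max_delta)
        probs = table[np.ix_(t_grid, deltas[idxs])]
        with np.errstate(divide="ignore"):
            loglik += np.sum(np.log(probs), axis=1)
    if np.all(np.isneginf(loglik)):
        raise ValueError("likelihood identically zero on the t grid")
    return float(t_grid[int(np.argmax(loglik))])


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus the per-pair shared-allele counts."""

    labels: list[str]
    values: np.ndarray
    measure: str
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            measure=self.measure,
            n_shared=self.n_shared[np.ix_(idx, idx)],
        )

    # --- IO ---------------------------------------------------------------

    def to_phylip(self, path: str | Path) -> None:
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(label + "  " + "  ".join(f"{v:.8f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join([""] + self.labels)]
        for label, row in zip(self.labels, self.values):
            lines.append("\t".join([label] + [f"{v:.8f}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, measure: str = "") -> "DistanceMatrix":
        rows = [l.split("\t") for l in Path(path).read_text().splitlines() if l]
        labels = rows[0][1:]
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(
            labels=labels,
            values=values,
            measure=measure,
            n_shared=np.zeros_like(values, dtype=int),
        )


def _root_as_signature(root: RootSignature) -> CellSignature:
    alleles = {}
    for key, value in root.alleles.items():
        alleles[key] = max(1, int(round(value)))
    return CellSignature(
        sample_id=ROOT_LABEL, individual_id=ROOT_LABEL, cell_type=ROOT_LABEL,
        alleles=alleles,
    )


#: measure name -> callable(si, sj, shared, **options)
MEASURES: dict[str, Callable] = {
    "absolute": absolute_distance,
    "normabs": normalized_absolute_distance,
    "euclidean": euclidean_distance,
    "equal_or_not": equal_or_not_distance,
}


def build_distance_matrix(
    dataset: Dataset,
    measure: str,
    *,
    include_root: bool = False,
    min_shared: int = MIN_SHARED_DEFAULT,
    step: StepModel | None = None,
    rates: MutationRateModel | None = None,
    t_max: int = 1000,
) -> DistanceMatrix:
    """Pairwise application of one measure over shared valid alleles.

    ``measure`` is one of ``absolute``, ``normabs``, ``euclidean``,
    ``equal_or_not``, ``ml_smm``, ``ml_mmm``.  With ``include_root`` a
    pseudo-leaf for the root signature is appended (used for outgroup
    rooting).
    """
    cells = list(dataset.signatures)
    if include_root:
        if dataset.root is None:
            raise ValueError("dataset has no root signature")
        cells.append(_root_as_signature(dataset.root))
    if len(cells) < 2:
        raise ValueError("need at least 2 signatures")

    if measure in ("ml_smm", "ml_mmm"):
        step = step or StepModel("SMM" if measure == "ml_smm" else "MMM")
        rates = rates or MutationRateModel("equal")

        def fn(si, sj, shared):
            return ml_distance(
                si, sj, shared, step, rates, panel=dataset.panel, t_max=t_max
            )
    elif measure in MEASURES:
        fn = MEASURES[measure]
    else:
        raise ValueError(f"unknown measure {measure!r}")

    n = len(cells)
    values = np.zeros((n, n))
    n_shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_shared[i, i] = cells[i].n_valid
        for j in range(i + 1, n):
            try:
                shared = shared_valid_alleles(cells[i], cells[j], min_shared)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({cells[i].sample_id}, {cells[j].sample_id}): {exc}"
                ) from exc
            d = fn(cells[i], cells[j], shared.keys)
            values[i, j] = values[j, i] = d
            n_shared[i, j] = n_shared[j, i] = len(shared)
    return DistanceMatrix(
        labels=[c.sample_id for c in cells],
        values=values,
        measure=measure,
        n_shared=n_shared,
    )
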