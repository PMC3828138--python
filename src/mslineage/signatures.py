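"""Single-cell microsatellite signature tables.

A cell's *genomic signature* is the vector of repeat counts of a panel of
microsatellite (MS) loci.  Tables follow the supplementary layout used for
such experiments: one row per cell with ``Sample ID``, ``Animal ID`` and
``Tissue`` columns followed by two columns per locus (the two alleles);
``X`` marks data that failed to amplify and an empty cell a locus that was
not measured.  Both alleles of an autosomal locus are treated as independent
single-allele loci; chromosome-X loci of male individuals carry one allele.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "MISSING",
    "AlleleKey",
    "CellSignature",
    "RootSignature",
    "LocusInfo",
    "Dataset",
    "read_allele_table",
    "write_allele_table",
    "read_metadata",
    "compute_root_signature",
    "shared_valid_alleles",
    "SharedAlleles",
]

#: Sentinel for an allele that was not measured or failed to amplify.
MISSING = None

#: (locus name, allele index).  Allele index is 1 or 2; X-linked loci in
#: males have index 1 only.
AlleleKey = tuple[str, int]

#: Default minimum number of shared valid alleles below which a pairwise
#: distance is flagged unreliable.
MIN_SHARED_DEFAULT = 25

#: Heterozygous alleles closer than this many repeat units cannot be phased
#: by sorting and the locus is treated as unusable for that cell.
PHASING_MIN_GAP = 2


@dataclass
class CellSignature:
    """MS repeat counts of one sampled cell, with missingness."""

    sample_id: str
    individual_id: str
    cell_type: str
    alleles: dict[AlleleKey, int | None] = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return sum(1 for v in self.alleles.values() if v is not None)

    def valid_keys(self) -> set[AlleleKey]:
        return {k for k, v in self.alleles.items() if v is not None}

    def __post_init__(self) -> None:
        for key, value in self.alleles.items():
            if value is not None and value < 1:
                raise ValueError(
                    f"repeat count must be >= 1; got {value!r} at {key} "
                    f"in sample {self.sample_id!r}"
                )


@dataclass
class RootSignature:
    """The putative zygote's signature, used to root reconstructed trees.

    Policies mirror experimental practice: for mice the zygote signature is
    read off bulk tail DNA (``tail_sample``), for humans it is the per-locus
    median over all cells (``median_of_cells``), and for trees combining
    several individuals it is a weighted mean of their zygotes
    (``weighted_mean``).
    """

    alleles: dict[AlleleKey, float]
    policy: str = "median_of_cells"

    def __post_init__(self) -> None:
        for key, value in self.alleles.items():
            if value is None or value != value:  # NaN check
                raise ValueError(f"root signature value at {key} is not finite")


@dataclass
class LocusInfo:
    """Panel metadata for one single-allele locus."""

    basic_unit_length: int = 1  # 1 = mono-, 2 = di-nucleotide repeat
    reference_repeat_number: float = 0.0
    chromosome: str = ""

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome.upper() == "X"


@dataclass
class Dataset:
    """A set of cell signatures sharing one locus panel, plus a root."""

    signatures: list[CellSignature]
    root: RootSignature | None = None
    panel: dict[AlleleKey, LocusInfo] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.signatures]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        for sig in self.signatures:
            unknown = set(sig.alleles) - set(self.panel)
            if self.panel and unknown:
                raise ValueError(
                    f"sample {sig.sample_id!r} carries alleles absent from "
                    f"the panel: {sorted(unknown)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.signatures]

    def get(self, sample_id: str) -> CellSignature:
        for sig in self.signatures:
            if sig.sample_id == sample_id:
                return sig
        raise KeyError(sample_id)

    def allele_keys(self) -> list[AlleleKey]:
        if self.panel:
            return sorted(self.panel)
        keys: set[AlleleKey] = set()
        for sig in self.signatures:
            keys |= set(sig.alleles)
        return sorted(keys)

    def loci(self) -> list[str]:
        """Locus names (allele indices collapsed), in panel order."""
        seen: dict[str, None] = {}
        for locus, _ in self.allele_keys():
            seen.setdefault(locus, None)
        return list(seen)


# ---------------------------------------------------------------------------
# metadata (Table S1 layout)


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read individual-level metadata: one row per organism.

    Expected tab- or comma-delimited columns: ``Animal ID`` (or ``Name``),
    then any of ``Species``, ``Gender``, ``Age``, ``Cell types``.  Returns a
    mapping animal id -> column dict (lower-cased keys).
    """
    path = Path(path)
    rows = _read_delimited(path)
    if not rows:
        raise ValueError(f"empty metadata file: {path}")
    header = [h.strip() for h in rows[0]]
    lower = [h.lower() for h in header]
    id_col = None
    for cand in ("animal id", "name", "individual", "id"):
        if cand in lower:
            id_col = lower.index(cand)
            break
    if id_col is None:
        raise ValueError(f"metadata header lacks an Animal ID column: {header}")
    out: dict[str, dict[str, str]] = {}
    for row in rows[1:]:
        if not any(cell.strip() for cell in row):
            continue
        rec = {lower[i]: row[i].strip() for i in range(min(len(row), len(header)))}
        out[row[id_col].strip()] = rec
    return out


def _read_delimited(path: Path) -> list[list[str]]:
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return [line.split(sep) for line in text.splitlines()]


# ---------------------------------------------------------------------------
# allele tables (Table S4 layout)


def read_allele_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    panel: Mapping[AlleleKey, LocusInfo] | None = None,
    drop_single_allele: bool = True,
    phasing_min_gap: int = PHASING_MIN_GAP,
) -> Dataset:
    """Parse a cell-by-locus allele-length table into a :class:`Dataset`.

    The header row holds locus names, each spanning two adjacent columns
    (the second may repeat the name or be blank).  ``X`` and empty cells map
    to :data:`MISSING`.

    Two validity rules are applied per cell:

    * *allelic dropout*: an autosomal locus with exactly one non-missing
      allele is discarded for that cell (both alleles set missing) —
      amplification failure of one heterozygous allele makes the surviving
      call unreliable.  X-linked loci of male individuals are exempt.
    * *phasing*: heterozygous autosomal alleles are ordered by value, which
      is only well defined when the two repeat numbers are clearly distinct
      (difference >= ``phasing_min_gap``); ambiguous loci are discarded for
      that cell.
    """
    path = Path(path)
    rows = _read_delimited(path)
    if len(rows) < 2:
        raise ValueError(f"allele table {path} has no data rows")
    header = [h.strip() for h in rows[0]]
    if len(header) < 4:
        raise ValueError(f"allele table {path}: header too short: {header}")
    loci = _parse_locus_header(header[3:])

    metadata = read_metadata(metadata_path) if metadata_path else {}

    if panel is None:
        panel = {}
        for locus in dict.fromkeys(loci):
            info = LocusInfo(
                basic_unit_length=_infer_unit(locus),
                chromosome=_infer_chromosome(locus),
            )
            panel[(locus, 1)] = info
            if loci.count(locus) > 1:
                panel[(locus, 2)] = info
    else:
        panel = dict(panel)
        for locus in loci:
            if (locus, 1) not in panel:
                raise ValueError(f"locus {locus!r} in data but not in panel")

    signatures = []
    for r, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        sample_id, animal_id, tissue = (c.strip() for c in row[:3])
        meta = metadata.get(animal_id, {})
        cell_type = tissue or meta.get("cell types", "")
        male = meta.get("gender", "").lower() in ("m", "male")
        alleles: dict[AlleleKey, int | None] = {}
        seen_count: dict[str, int] = {}
        for c, locus in enumerate(loci):
            raw = row[3 + c].strip() if 3 + c < len(row) else ""
            seen_count[locus] = seen_count.get(locus, 0) + 1
            idx = seen_count[locus]  # first column of the pair -> 1, second -> 2
            if idx > 2:
                raise ValueError(f"locus {locus!r} spans more than two columns")
            key = (locus, idx)
            if raw in ("", "X", "x"):
                alleles[key] = MISSING
                continue
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric repeat value {raw!r} at row {r}, locus {locus}"
                ) from None
            info = panel[(locus, 1)]
            repeats = value - info.reference_repeat_number
            if abs(repeats - round(repeats)) > 1e-9:
                raise ValueError(
                    f"non-integer repeat count {repeats} at row {r}, locus {locus}"
                )
            alleles[key] = int(round(repeats))

        _apply_locus_validity(
            alleles,
            panel,
            male=male,
            drop_single_allele=drop_single_allele,
            phasing_min_gap=phasing_min_gap,
        )
        signatures.append(
            CellSignature(
                sample_id=sample_id,
                individual_id=animal_id,
                cell_type=cell_type,
                alleles=alleles,
            )
        )

    prov = [str(path)] + ([str(metadata_path)] if metadata_path else [])
    return Dataset(signatures=signatures, panel=dict(panel), provenance=prov)


def _parse_locus_header(cells: Sequence[str]) -> list[str]:
    """Expand a locus header where each locus spans two columns."""
    loci: list[str] = []
    last = ""
    for cell in cells:
        name = cell.strip()
        if name:
            loci.append(name)
            last = name
        else:
            if not last:
                raise ValueError("locus header starts with an empty cell")
            loci.append(last)
    return loci


def _infer_unit(locus: str) -> int:
    # Panel naming convention: [Org][Chrom]_[Unit letter(s)][repeats]_[serial]
    parts = locus.split("_")
    if len(parts) >= 2 and parts[1]:
        unit = "".join(ch for ch in parts[1] if ch.isalpha())
        if len(unit) in (1, 2):
            return len(unit)
    return 1


def _infer_chromosome(locus: str) -> str:
    head = locus.split("_")[0]
    if head[1:].upper().startswith("X") or head.upper() == "X":
        return "X"
    return head[1:] if len(head) > 1 else ""


def _apply_locus_validity(
    alleles: dict[AlleleKey, int | None],
    panel: Mapping[AlleleKey, LocusInfo],
    *,
    male: bool,
    drop_single_allele: bool,
    phasing_min_gap: int,
) -> None:
    loci = {locus for locus, _ in alleles}
    for locus in loci:
        info = panel.get((locus, 1), LocusInfo())
        hemizygous = male and info.is_x_linked
        a1 = alleles.get((locus, 1))
        a2 = alleles.get((locus, 2))
        if hemizygous:
            # one allele expected: keep the first, drop the second key
            alleles.pop((locus, 2), None)
            continue
        if (locus, 2) not in alleles:
            continue  # single-allele locus (e.g. simulated panels)
        if drop_single_allele and (a1 is None) != (a2 is None):
            alleles[(locus, 1)] = MISSING
            alleles[(locus, 2)] = MISSING
            continue
        if a1 is not None and a2 is not None:
            if a1 != a2 and abs(a1 - a2) < phasing_min_gap:
                # cannot phase by sorting; unusable for this cell
                alleles[(locus, 1)] = MISSING
                alleles[(locus, 2)] = MISSING
            else:
                alleles[(locus, 1)], alleles[(locus, 2)] = sorted((a1, a2))


def write_allele_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the two-columns-per-locus tab layout."""
    path = Path(path)
    loci = dataset.loci()
    keys = dataset.allele_keys()
    by_locus: dict[str, list[AlleleKey]] = {}
    for key in keys:
        by_locus.setdefault(key[0], []).append(key)
    header = ["Sample ID", "Animal ID", "Tissue"]
    columns: list[AlleleKey] = []
    for locus in loci:
        for key in by_locus[locus]:
            header.append(locus if key[1] == 1 else "")
            columns.append(key)
    lines = ["\t".join(header)]
    for sig in dataset.signatures:
        row = [sig.sample_id, sig.individual_id, sig.cell_type]
        for key in columns:
            value = sig.alleles.get(key, MISSING)
            row.append("X" if value is None else str(value))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# root signature


def compute_root_signature(
    dataset: Dataset,
    policy: str,
    tail_sample_id: str | None = None,
    zygotes: Sequence[RootSignature] | None = None,
    weights: Sequence[float] | None = None,
) -> RootSignature:
    """Build the putative-zygote signature under one of three policies.

    ``tail_sample``: copy the designated bulk (tail DNA) sample verbatim.
    ``median_of_cells``: per-allele lower median over all non-missing cell
    values (lower-median so root repeat counts stay integral).
    ``weighted_mean``: per-allele weighted mean over supplied zygote
    signatures; default weights are uniform.
    """
    if not dataset.signatures and policy != "weighted_mean":
        raise ValueError("cannot derive a root signature from an empty dataset")

    if policy == "tail_sample":
        if tail_sample_id is None:
            raise ValueError("tail_sample policy requires tail_sample_id")
        tail = dataset.get(tail_sample_id)
        alleles: dict[AlleleKey, float] = {}
        for key, value in tail.alleles.items():
            if value is None:
                present = any(
                    s.alleles.get(key) is not None for s in dataset.signatures
                )
                if present:
                    raise ValueError(
                        f"tail sample missing allele {key} that cells carry"
                    )
                warnings.warn(f"allele {key} absent everywhere; dropped from root")
                continue
            alleles[key] = float(value)
        return RootSignature(alleles=alleles, policy=policy)

    if policy == "median_of_cells":
        alleles = {}
        for key in dataset.allele_keys():
            values = [
                s.alleles[key]
                for s in dataset.signatures
                if s.alleles.get(key) is not None
            ]
            if not values:
                warnings.warn(f"allele {key} has no measured values; dropped")
                continue
            alleles[key] = float(statistics.median_low(values))
        return RootSignature(alleles=alleles, policy=policy)

    if policy == "weighted_mean":
        if not zygotes:
            raise ValueError("weighted_mean policy requires at least one zygote")
        if weights is None:
            weights = [1.0] * len(zygotes)
        if len(weights) != len(zygotes):
            raise ValueError("weights and zygotes must align")
        total = float(sum(weights))
        if total <= 0:
            raise ValueError("weights must sum to a positive number")
        alleles = {}
        keys = set().union(*(set(z.alleles) for z in zygotes))
        for key in keys:
            num = 0.0
            den = 0.0
            for z, w in zip(zygotes, weights):
                if key in z.alleles:
                    num += w * z.alleles[key]
                    den += w
            alleles[key] = num / den
        return RootSignature(alleles=alleles, policy=policy)

    raise ValueError(f"unknown root policy {policy!r}")


# ---------------------------------------------------------------------------
# shared alleles


@dataclass(frozen=True)
class SharedAlleles:
    """The allele keys valid in both members of a cell pair."""

    keys: frozenset[AlleleKey]
    reliable: bool

    def __iter__(self):
        return iter(self.keys)

    def __len__(self) -> int:
        return len(self.keys)


def shared_valid_alleles(
    si: CellSignature,
    sj: CellSignature,
    min_shared: int = MIN_SHARED_DEFAULT,
) -> SharedAlleles:
    """Alleles amplified in both cells; flags pairs sharing fewer than
    ``min_shared`` as unreliable.  An empty intersection is an error — no
    distance is defined for such a pair."""
    keys = si.valid_keys() & sj.valid_keys()
    if not keys:
        raise ValueError(
            f"samples {si.sample_id!r} and {sj.sample_id!r} share no valid "
            "alleles; distance undefined"
        )
    return SharedAlleles(keys=frozenset(keys), reliable=len(keys) >= min_shared)
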