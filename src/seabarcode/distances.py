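"""Uncorrected p-distances and the barcoding-gap analysis.

The p-distance between two aligned rows is the proportion of mismatching
sites among sites where *both* rows carry an unambiguous base (pairwise
deletion of gaps, ``?`` and ambiguity codes).  Distances are partitioned
into within-group (intra) and between-group (inter) sets at a chosen
taxonomic rank — singleton-heavy sampling designs use the genus as the
minimal unit —
and the "barcoding gap" is summarised as

* ``gap_stat`` = min(inter) − max(intra): positive iff the distributions
  are separated, and
* ``overlap_fraction``: the share of intra distances ≥ min(inter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment, AlignmentShapeError, MetadataError

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class ParameterError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances; NaN marks an undefined pair."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        assert self.d.shape == (n, n)

    def pairs(self):
        """Yield (label_i, label_j, distance) over i<j, including NaNs."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.labels[i], self.labels[j], self.d[i, j]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class GapReport:
    grouping_rank: str
    intra: list[float]
    inter: list[float]
    n_undefined: int = 0

    summaries: dict = field(init=False)

    def __post_init__(self) -> None:
        self.summaries = {}
        for name, vals in (("intra", self.intra), ("inter", self.inter)):
            if vals:
                self.summaries[name] = {
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "min": float(min(vals)),
                    "max": float(max(vals)),
                }
            else:
                self.summaries[name] = {"n": 0, "mean": None,
                                        "min": None, "max": None}

    @property
    def gap_stat(self) -> float | None:
        """min(inter) − max(intra); ``None`` when either set is empty."""
        if not self.intra or not self.inter:
            return None
        return min(self.inter) - max(self.intra)

    @property
    def overlap_fraction(self) -> float | None:
        if not self.intra or not self.inter:
            return None
        lo = min(self.inter)
        return sum(1 for v in self.intra if v >= lo) / len(self.intra)

    def fraction_below(self, which: str, threshold: float) -> float:
        vals = getattr(self, which)
        if not vals:
            return math.nan
        return sum(1 for v in vals if v < threshold) / len(vals)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE.get(c, -1) for c in seq),
                       dtype=np.int8, count=len(seq))


def p_distance(row_a: str, row_b: str) -> float:
    """Uncorrected p-distance with pairwise deletion; NaN when no site is
    comparable."""
    if len(row_a) != len(row_b):
        raise AlignmentShapeError(
            f"length mismatch: {len(row_a)} vs {len(row_b)}")
    a, b = _encode(row_a.upper()), _encode(row_b.upper())
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        return math.nan
    return float((a[mask] != b[mask]).sum()) / n


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs p-distance matrix (vectorised over encoded rows)."""
    if len(alignment) < 2:
        raise AlignmentShapeError("distance matrix needs at least 2 rows")
    rows = np.stack([_encode(r.seq) for r in alignment.records])
    valid = rows >= 0
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        mask = valid[i] & valid[i + 1:]
        comp = mask.sum(axis=1).astype(float)
        diff = ((rows[i] != rows[i + 1:]) & mask).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dij = np.where(comp > 0, diff / comp, np.nan)
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return DistanceMatrix(labels=alignment.ids(), d=d)


def partition_distances(matrix: DistanceMatrix, metadata,
                        rank: str = "genus") -> GapReport:
    """Split defined pairwise distances into intra-/inter-group sets.

    ``metadata`` maps each label to its group at ``rank`` — either a plain
    ``{label: group}`` dict, or a ``{label: (species, genus, family, site)}``
    taxon table, from which the rank field is picked.
    """
    rank_idx = {"species": 0, "genus": 1, "family": 2}.get(rank)

    def group_of(label: str) -> str:
        if label not in metadata:
            raise MetadataError(f"label {label!r} has no metadata")
        entry = metadata[label]
        if isinstance(entry, tuple):
            if rank_idx is None:
                raise ParameterError(f"unknown rank {rank!r}")
            return entry[rank_idx]
        return entry

    intra, inter = [], []
    n_undef = 0
    for la, lb, dist in matrix.pairs():
        if math.isnan(dist):
            n_undef += 1
            continue
        (intra if group_of(la) == group_of(lb) else inter).append(dist)
    return GapReport(grouping_rank=rank, intra=intra, inter=inter,
                     n_undefined=n_undef)


def gap_histogram(report: GapReport, bin_width: float = 0.005,
                  relative: bool = False) -> dict[str, dict[float, float]]:
    """Bin intra/inter distances into half-open bins [k·w, (k+1)·w).

    Returns ``{"intra": {bin_left: count}, "inter": {...}}``; counts sum to
    the set sizes (or to 1.0 with ``relative=True``).
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    out: dict[str, dict[float, float]] = {}
    for name in ("intra", "inter"):
        vals = getattr(report, name)
        hist: dict[float, float] = {}
        for v in vals:
            k = int(v / bin_width)
            left = round(k * bin_width, 10)
            hist[left] = hist.get(left, 0) + 1
        if relative and vals:
            hist = {k: c / len(vals) for k, c in hist.items()}
        out[name] = dict(sorted(hist.items()))
    return out
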