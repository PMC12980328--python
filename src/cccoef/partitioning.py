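"""Internal clusterings of single features.

The clustermatch coefficient compares two features through partitions of the
samples. Numerical features are partitioned by empirical quantiles over a
sweep of cluster counts k; categorical features carry exactly one partition,
the one defined by their categories. Everything downstream (the ARI engine,
the coefficient) consumes the :class:`PartitionSet` built here.

Quantile partitions use the "type-7" convention (linear interpolation of
order statistics with plotting positions (j-1)/(n-1)), the default of
``np.quantile``. Labels are assigned in rank space: a sample's label is the
number of cut points strictly below its value, with a value exactly equal to
a cut point going to the lower cluster. Because the comparisons are made
against order statistics directly (the interpolated cut never needs to be
materialised as a float), partitions are exactly invariant under strictly
increasing transforms of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureVector",
    "Partition",
    "PartitionSet",
    "quantile_partition",
    "encode_categorical",
    "build_partition_set",
    "DEFAULT_K_RANGE",
]

#: Default sweep of cluster counts for numerical features.
DEFAULT_K_RANGE: tuple[int, ...] = tuple(range(2, 11))


@dataclass(frozen=True)
class FeatureVector:
    """One feature's values across samples, numerical or categorical.

    Parameters
    ----------
    id
        Feature identifier (gene id, metadata variable name, ...).
    kind
        ``"numerical"`` or ``"categorical"``.
    values
        For numerical features a float array; for categorical features an
        integer array of category codes densely numbered from 0 in
        first-occurrence order.
    missing_mask
        Boolean array, True where the sample's value is missing.
    """

    id: str
    kind: str
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if values.ndim != 1 or values.shape != mask.shape or values.size < 1:
            raise ValueError(
                "values and missing_mask must be 1-D of identical length >= 1"
            )
        if self.kind not in ("numerical", "categorical"):
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)

    @classmethod
    def from_numerical(cls, id: str, values: Iterable[float]) -> "FeatureVector":
        """Build a numerical feature; NaN entries become missing."""
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float)
        return cls(id=id, kind="numerical", values=arr, missing_mask=np.isnan(arr))

    @classmethod
    def from_categorical(cls, id: str, values: Iterable[object]) -> "FeatureVector":
        """Build a categorical feature from raw labels.

        Categories are coded 0, 1, 2, ... in first-occurrence order.
        ``None``, ``NaN`` and the strings ``"NA"``/``""`` are missing.
        """
        raw = list(values)
        codes = np.zeros(len(raw), dtype=np.int64)
        mask = np.zeros(len(raw), dtype=bool)
        seen: dict[object, int] = {}
        for i, v in enumerate(raw):
            if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("NA", ""):
                mask[i] = True
                codes[i] = -1
                continue
            if v not in seen:
                seen[v] = len(seen)
            codes[i] = seen[v]
        return cls(id=id, kind="categorical", values=codes, missing_mask=mask)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def nonmissing_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]


@dataclass(frozen=True)
class Partition:
    """Cluster labels over (non-missing) samples for one feature.

    ``labels`` take values in ``[0, k)`` with every cluster non-empty;
    ``source_k`` is the requested cluster count (equal to ``k`` unless ties
    collapsed clusters); ``degenerate`` is True iff fewer than two non-empty
    clusters remain.
    """

    labels: np.ndarray
    k: int
    source_k: int
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ValueError("labels out of range [0, k)")
        if self.degenerate != (self.k < 2):
            raise ValueError("degenerate flag must equal (k < 2)")

    @property
    def n_samples(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class PartitionSet:
    """The family of non-degenerate partitions of one feature."""

    feature_id: str
    partitions: tuple[Partition, ...]
    n_effective: int

    def __len__(self) -> int:
        return len(self.partitions)

    @property
    def label_matrix(self) -> np.ndarray:
        """(n_partitions, n_effective) int64 label matrix."""
        if not self.partitions:
            return np.empty((0, self.n_effective), dtype=np.int64)
        return np.vstack([p.labels for p in self.partitions])

    @property
    def ks(self) -> np.ndarray:
        return np.array([p.k for p in self.partitions], dtype=np.int64)


def _compact_labels(labels: np.ndarray, source_k: int) -> Partition:
    """Renumber labels to consecutive ints over non-empty clusters."""
    present = np.unique(labels)  # sorted; label order follows value order
    k = int(present.size)
    remap = np.full(int(present.max()) + 1 if k else 1, -1, dtype=np.int64)
    remap[present] = np.arange(k, dtype=np.int64)
    return Partition(labels=remap[labels], k=k, source_k=source_k,
                     degenerate=k < 2)


def quantile_partition(values: Sequence[float] | np.ndarray, k: int) -> Partition:
    """Partition numerical values into ``k`` quantile bins.

    Cut points are the empirical quantiles at i/k (i = 1..k-1) under the
    type-7 convention; a sample's label counts the cut points strictly below
    its value (a value equal to a cut point goes to the lower cluster).
    Empty bins are compacted away and flagged as degeneracy when fewer than
    two clusters survive (e.g. constant input).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("quantile_partition requires a non-empty 1-D vector")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if np.isnan(arr).any():
        raise ValueError("quantile_partition input must not contain missing values")

    n = arr.size
    order_stats = np.sort(arr, kind="stable")
    labels = np.zeros(n, dtype=np.int64)
    for i in range(1, k):
        # interpolation position h = (n-1) * i / k, exactly in integer arithmetic
        j, rem = divmod((n - 1) * i, k)
        if rem == 0 or order_stats[j] == order_stats[j + 1]:
            # cut coincides with the order statistic o_j: strictly-above rule
            labels += arr > order_stats[j]
        else:
            # cut lies strictly between o_j and o_{j+1}; sample values above
            # the cut are exactly those >= o_{j+1}
            labels += arr >= order_stats[j + 1]
    return _compact_labels(labels, source_k=k)


def encode_categorical(values: Sequence[object] | np.ndarray) -> Partition:
    """Partition defined by a categorical feature's own categories.

    Labels are category codes in first-occurrence order; degenerate when
    fewer than two distinct categories are present.
    """
    raw = np.asarray(values)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("encode_categorical requires a non-empty 1-D vector")
    if np.issubdtype(raw.dtype, np.integer):
        codes = raw.astype(np.int64)
        if codes.min() < 0:
            raise ValueError("categorical codes must be non-negative")
        # recode to first-occurrence order in case codes arrive sparse
        _, first_idx = np.unique(codes, return_index=True)
        order = codes[np.sort(first_idx)]
        remap = np.full(int(codes.max()) + 1, -1, dtype=np.int64)
        remap[order] = np.arange(order.size, dtype=np.int64)
        labels = remap[codes]
        k = int(order.size)
    else:
        seen: dict[object, int] = {}
        labels = np.zeros(raw.size, dtype=np.int64)
        for i, v in enumerate(raw.tolist()):
            if v not in seen:
                seen[v] = len(seen)
            labels[i] = seen[v]
        k = len(seen)
    return Partition(labels=labels, k=k, source_k=k, degenerate=k < 2)


def build_partition_set(
    feature: FeatureVector,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
) -> PartitionSet:
    """Build all retained partitions of one feature.

    Numerical features get one quantile partition per k in ``k_range``
    (degenerate ones dropped, duplicates retained); categorical features get
    their single category partition. Missing samples are excluded first.
    An empty set is a legal result (constant feature).
    """
    if len(k_range) == 0 or any(int(k) < 2 for k in k_range):
        raise ValueError("k_range must be non-empty with all entries >= 2")
    vals = feature.values[~feature.missing_mask]
    n_eff = int(vals.size)
    if n_eff == 0:
        return PartitionSet(feature.id, (), 0)
    if feature.kind == "categorical":
        part = encode_categorical(vals)
        parts = () if part.degenerate else (part,)
        return PartitionSet(feature.id, parts, n_eff)
    parts = []
    for k in k_range:
        p = quantile_partition(vals, int(k))
        if not p.degenerate:
            parts.append(p)
    return PartitionSet(feature.id, tuple(parts), n_eff)
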