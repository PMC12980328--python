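"""Adjusted Rand Index engine: globally-indexed tasks, batches, max-reduction.

The coefficient needs the ARI of very many partition pairs: every combination
of the two features' internal clusterings, for every feature pair. Each such
combination is one *task* with a unique global index. A batch planner splits
the task range into contiguous, memory-budgeted batches; the executor
evaluates each batch (optionally across worker threads) and reduces each
feature pair to its maximum ARI with a deterministic first-argmax tie-break.
Outputs are bit-identical for any worker count, batch budget or backend.

The ARI itself is the Hubert–Arabie chance-corrected form. Both backends
accumulate the pair-count sums as exact integers and perform one float
division at the end,

    ARI = 2 * (C(n,2) * S - A * B) / (C(n,2) * (A + B) - 2 * A * B)

with S = sum_ij C(n_ij, 2), A = sum_i C(a_i, 2), B = sum_j C(b_j, 2), so the
reference (pure Python) and vectorized (numpy int64) backends agree bit for
bit. int64 accumulation is exact for up to roughly 50,000 samples.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .partitioning import Partition, PartitionSet

__all__ = [
    "ContingencyTable",
    "AriTask",
    "BatchPlan",
    "EngineConfig",
    "PairMax",
    "contingency_table",
    "ari_from_table",
    "ari_pair_oracle",
    "plan_batches",
    "per_task_bytes",
    "execute_tasks",
    "ari_many",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two partitions: counts n_ij with marginals."""

    counts: np.ndarray
    a: np.ndarray  # row sums
    b: np.ndarray  # column sums
    n: int


@dataclass(frozen=True)
class AriTask:
    """One ARI evaluation: partition px of feature pair's x vs py of y."""

    global_index: int
    pair_index: int
    px_index: int
    py_index: int


@dataclass(frozen=True)
class BatchPlan:
    batch_boundaries: tuple[tuple[int, int], ...]
    per_task_bytes: int
    budget_bytes: int


@dataclass(frozen=True)
class EngineConfig:
    """Execution policy for the ARI engine.

    ``budget_bytes`` caps the per-batch working set (default 4 GiB);
    ``workers`` threads evaluate batches concurrently; ``backend`` selects the
    pure-Python reference loop or the vectorized numpy path — both are
    required to produce bit-identical output.
    """

    budget_bytes: int = 4 << 30
    workers: int = 1
    backend: str = "vectorized"

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.backend not in ("reference", "vectorized"):
            raise ValueError(f"unknown backend: {self.backend!r}")


@dataclass(frozen=True)
class PairMax:
    """Per-pair reduction result: raw max ARI and its first argmax."""

    max_ari: float
    argmax: tuple[int, int]  # (px_index, py_index)
    n_tasks: int
    degenerate: bool = False


def contingency_table(p: Partition, q: Partition) -> ContingencyTable:
    """Joint cluster-membership counts of two partitions of the same samples."""
    if p.n_samples != q.n_samples:
        raise ValueError(
            f"partition length mismatch: {p.n_samples} vs {q.n_samples}"
        )
    counts = np.zeros((p.k, q.k), dtype=np.int64)
    np.add.at(counts, (p.labels, q.labels), 1)
    return ContingencyTable(
        counts=counts,
        a=counts.sum(axis=1),
        b=counts.sum(axis=0),
        n=p.n_samples,
    )


def _comb2_int(x: int) -> int:
    return x * (x - 1) // 2


def ari_from_table(t: ContingencyTable) -> float:
    """Hubert–Arabie Adjusted Rand Index from a contingency table.

    Returns 1.0 when the chance-corrected denominator vanishes (both
    partitions trivial and identical), the standard convention.
    """
    if t.n < 2:
        raise ValueError("ARI requires n >= 2 samples")
    s = int(sum(_comb2_int(int(v)) for v in t.counts.ravel()))
    a = int(sum(_comb2_int(int(v)) for v in t.a))
    b = int(sum(_comb2_int(int(v)) for v in t.b))
    pairs = _comb2_int(t.n)
    num = 2 * (pairs * s - a * b)
    den = pairs * (a + b) - 2 * a * b
    if den == 0:
        return 1.0
    # cast before dividing, matching the vectorized backend's int64->float64
    # promotion bit for bit
    return float(num) / float(den)


def ari_pair_oracle(p: Partition, q: Partition) -> float:
    """Brute-force ARI from exhaustive pair-confusion counts (test oracle).

    Enumerates all C(n,2) sample pairs into N11 (together in both), N10, N01,
    N00 and evaluates

        2*(N11*N00 - N10*N01) /
        ((N11+N10)*(N10+N00) + (N11+N01)*(N01+N00))

    independently of the contingency-table closed form.
    """
    if p.n_samples != q.n_samples:
        raise ValueError("partition length mismatch")
    n = p.n_samples
    if n < 2:
        raise ValueError("ARI requires n >= 2 samples")
    n11 = n10 = n01 = n00 = 0
    lp, lq = p.labels, q.labels
    for i in range(n):
        for j in range(i + 1, n):
            same_p = lp[i] == lp[j]
            same_q = lq[i] == lq[j]
            if same_p and same_q:
                n11 += 1
            elif same_p:
                n10 += 1
            elif same_q:
                n01 += 1
            else:
                n00 += 1
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if den == 0:
        return 1.0
    return 2 * (n11 * n00 - n10 * n01) / den


def per_task_bytes(k_max: int) -> int:
    """Declared per-task working-set: one k_max^2 int64 table plus scratch."""
    return 8 * k_max * k_max + 2 * 8 * k_max + 64


def plan_batches(n_tasks: int, per_task_bytes: int, budget_bytes: int) -> BatchPlan:
    """Split [0, n_tasks) into contiguous batches respecting the byte budget."""
    if per_task_bytes < 1 or budget_bytes < 1 or n_tasks < 0:
        raise ValueError("per_task_bytes and budget_bytes must be >= 1")
    batch_size = max(1, budget_bytes // per_task_bytes)
    bounds = tuple(
        (start, min(start + batch_size, n_tasks))
        for start in range(0, n_tasks, batch_size)
    )
    return BatchPlan(bounds, per_task_bytes, budget_bytes)


def ari_many(labels_x: np.ndarray, labels_y: np.ndarray,
             kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
    """Vectorized ARI for T aligned tasks.

    ``labels_x``/``labels_y`` are (T, n) label matrices; ``kx``/``ky`` the
    cluster counts per task. All tasks share the sample count n.
    """
    labels_x = np.atleast_2d(labels_x)
    labels_y = np.atleast_2d(labels_y)
    T, n = labels_x.shape
    if n < 2:
        raise ValueError("ARI requires n >= 2 samples")
    kmax_x = int(kx.max())
    kmax_y = int(ky.max())
    cell = kmax_x * kmax_y
    # fused joint codes: task block + row-major cell within the task's table
    codes = (np.arange(T, dtype=np.int64)[:, None] * cell
             + labels_x * kmax_y + labels_y)
    counts = np.bincount(codes.ravel(), minlength=T * cell).reshape(
        T, kmax_x, kmax_y
    )
    s = (counts * (counts - 1) // 2).sum(axis=(1, 2))
    arow = counts.sum(axis=2)
    bcol = counts.sum(axis=1)
    a = (arow * (arow - 1) // 2).sum(axis=1)
    b = (bcol * (bcol - 1) // 2).sum(axis=1)
    pairs = n * (n - 1) // 2
    num = 2 * (pairs * s - a * b)
    den = pairs * (a + b) - 2 * a * b
    out = np.ones(T, dtype=float)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def _task_layout(
    partition_sets: Sequence[PartitionSet], pairs: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-pair task counts, cumulative global offsets, total task count."""
    m = np.array(
        [len(partition_sets[i]) * len(partition_sets[j]) for i, j in pairs],
        dtype=np.int64,
    )
    offsets = np.concatenate([[0], np.cumsum(m)])
    return m, offsets, int(offsets[-1])


def _eval_batch_vectorized(
    start: int,
    end: int,
    offsets: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    partition_sets: Sequence[PartitionSet],
    out: np.ndarray,
) -> None:
    # batches are contiguous in global index; evaluate per pair-run so each
    # ari_many call shares one sample count
    pair_lo = int(np.searchsorted(offsets, start, side="right") - 1)
    pos = start
    while pos < end:
        pi = pair_lo
        while offsets[pi + 1] <= pos:
            pi += 1
        pair_lo = pi
        i, j = pairs[pi]
        psx, psy = partition_sets[i], partition_sets[j]
        my = len(psy)
        local_lo = pos - int(offsets[pi])
        local_hi = min(end, int(offsets[pi + 1])) - int(offsets[pi])
        idx = np.arange(local_lo, local_hi)
        px, py = np.divmod(idx, my)
        lx = psx.label_matrix[px]
        ly = psy.label_matrix[py]
        out[pos : pos + idx.size] = ari_many(lx, ly, psx.ks[px], psy.ks[py])
        pos += idx.size


def _eval_batch_reference(
    start: int,
    end: int,
    offsets: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    partition_sets: Sequence[PartitionSet],
    out: np.ndarray,
) -> None:
    for g in range(start, end):
        pi = int(np.searchsorted(offsets, g, side="right") - 1)
        i, j = pairs[pi]
        psx, psy = partition_sets[i], partition_sets[j]
        px, py = divmod(g - int(offsets[pi]), len(psy))
        t = contingency_table(psx.partitions[px], psy.partitions[py])
        out[g] = ari_from_table(t)


def execute_tasks(
    partition_sets: Sequence[PartitionSet],
    pairs: Sequence[tuple[int, int]],
    config: EngineConfig = EngineConfig(),
) -> list[PairMax]:
    """Evaluate every partition combination of every pair; reduce to maxima.

    Returns one :class:`PairMax` per pair with the *raw* (possibly negative)
    maximum ARI — non-negativity clamping belongs to the coefficient layer —
    and the first-encountered argmax in global-index order. Pairs whose
    partition set is empty are reported degenerate, not computed. Output is
    identical for any ``workers``/``budget_bytes``/``backend``.
    """
    for i, j in pairs:
        psx, psy = partition_sets[i], partition_sets[j]
        if len(psx) and len(psy) and psx.n_effective != psy.n_effective:
            raise ValueError(
                f"pair ({i},{j}): partition sample counts differ "
                f"({psx.n_effective} vs {psy.n_effective})"
            )
    m, offsets, n_tasks = _task_layout(partition_sets, pairs)
    values = np.empty(n_tasks, dtype=float)
    k_max = max((int(ps.ks.max()) for ps in partition_sets if len(ps)), default=2)
    plan = plan_batches(n_tasks, per_task_bytes(k_max), config.budget_bytes)

    evaluate = (
        _eval_batch_vectorized
        if config.backend == "vectorized"
        else _eval_batch_reference
    )
    if config.workers == 1 or len(plan.batch_boundaries) <= 1:
        for start, end in plan.batch_boundaries:
            evaluate(start, end, offsets, pairs, partition_sets, values)
    else:
        # each batch writes a disjoint slice of `values`; collection order is
        # irrelevant to the result, so threading cannot perturb the output
        with concurrent.futures.ThreadPoolExecutor(config.workers) as pool:
            futures = [
                pool.submit(evaluate, start, end, offsets, pairs,
                            partition_sets, values)
                for start, end in plan.batch_boundaries
            ]
            for f in futures:
                f.result()

    results: list[PairMax] = []
    for pi, (i, j) in enumerate(pairs):
        if m[pi] == 0:
            results.append(PairMax(0.0, (-1, -1), 0, degenerate=True))
            continue
        chunk = values[int(offsets[pi]) : int(offsets[pi + 1])]
        local = int(np.argmax(chunk))  # first occurrence: lowest global index
        my = len(partition_sets[j])
        results.append(
            PairMax(float(chunk[local]), (local // my, local % my), int(m[pi]))
        )
    return results
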