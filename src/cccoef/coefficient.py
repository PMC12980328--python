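"""The Clustermatch Correlation Coefficient (CCC).

CCC(x, y) is the maximum Adjusted Rand Index over every combination of the
two features' internal clusterings, clamped to [0, 1]. It is symmetric,
equals 1 for any monotone functional relationship, stays near 0 for
independent features, and — because partitions are the common currency —
works across numerical and categorical features alike.

Significance is assessed by a permutation null: the second feature's values
are reshuffled ``n_perm`` times and the coefficient recomputed, giving the
add-one Monte-Carlo p-value (1 + #{CCC_perm >= CCC_obs}) / (1 + n_perm).
Since quantile partitions depend only on the multiset of values, permuting a
feature's values and re-partitioning is exactly equivalent to permuting its
partition labels, which is how the null is evaluated internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .ari import EngineConfig, PairMax, ari_many, execute_tasks
from .partitioning import (
    DEFAULT_K_RANGE,
    FeatureVector,
    PartitionSet,
    build_partition_set,
)

__all__ = ["CccConfig", "CccResult", "PairResultTable", "ccc_pair", "ccc_matrix"]


@dataclass(frozen=True)
class CccConfig:
    """Coefficient parameters.

    k_range: cluster-count sweep for numerical features (default 2..10).
    n_perm: permutations for the p-value; 0 (default) disables p-values.
    seed: base seed; each pair's permutation stream derives from
        (seed, pair_index) so results are reproducible and independent of
        execution order or parallelism.
    min_samples: minimum pairwise-complete samples below which a pair is
        reported degenerate rather than estimated from too little data.
    """

    k_range: tuple[int, ...] = DEFAULT_K_RANGE
    n_perm: int = 0
    seed: int = 0
    min_samples: int = 10
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")
        object.__setattr__(self, "k_range", tuple(int(k) for k in self.k_range))

    def provenance(self) -> dict:
        return {
            "software": f"cccoef {__version__}",
            "k_range": ",".join(map(str, self.k_range)),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "min_samples": self.min_samples,
        }


@dataclass(frozen=True)
class CccResult:
    """Coefficient for one feature pair."""

    feature_i: str
    feature_j: str
    ccc: float
    best_kx: int | None
    best_ky: int | None
    pvalue: float | None
    n_used: int
    degenerate: bool
    raw_max_ari: float | None = None  # pre-clamp diagnostic


class PairResultTable:
    """All unordered-pair results of a feature set, with provenance."""

    def __init__(self, results: Sequence[CccResult], provenance: dict):
        self.results = list(results)
        self.provenance = dict(provenance)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_i": [r.feature_i for r in self.results],
                "feature_j": [r.feature_j for r in self.results],
                "ccc": [r.ccc for r in self.results],
                "best_kx": [r.best_kx for r in self.results],
                "best_ky": [r.best_ky for r in self.results],
                "pvalue": [r.pvalue for r in self.results],
                "n_used": [r.n_used for r in self.results],
                "degenerate": [r.degenerate for r in self.results],
            }
        )


def _pair_rng(seed: int, pair_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(pair_index,))
    return np.random.default_rng(ss)


def _max_ccc_tasks(psx: PartitionSet, psy: PartitionSet) -> tuple[float, int, int]:
    """Raw max ARI over the partition cross product, plus argmax indices."""
    my = len(psy)
    px = np.repeat(np.arange(len(psx)), my)
    py = np.tile(np.arange(my), len(psx))
    values = ari_many(
        psx.label_matrix[px], psy.label_matrix[py], psx.ks[px], psy.ks[py]
    )
    local = int(np.argmax(values))
    return float(values[local]), local // my, local % my


def _permutation_pvalue(
    psx: PartitionSet,
    psy: PartitionSet,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 32,
) -> float:
    """Add-one Monte-Carlo p-value by permuting y's partition labels."""
    n = psx.n_effective
    lx, ly = psx.label_matrix, psy.label_matrix
    mx, my = lx.shape[0], ly.shape[0]
    px = np.repeat(np.arange(mx), my)
    py = np.tile(np.arange(my), mx)
    kx, ky = psx.ks[px], psy.ks[py]
    exceed = 0
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(p)])  # (p, n)
        # (p, T, n) stacks: x labels repeat, y labels permuted per draw
        big_lx = np.broadcast_to(lx[px], (p,) + lx[px].shape).reshape(-1, n)
        big_ly = ly[py][None, :, :].repeat(p, axis=0)
        big_ly = np.take_along_axis(
            big_ly, perms[:, None, :].repeat(px.size, axis=1), axis=2
        ).reshape(-1, n)
        values = ari_many(
            big_lx, big_ly, np.tile(kx, p), np.tile(ky, p)
        ).reshape(p, px.size)
        perm_ccc = np.maximum(values.max(axis=1), 0.0)
        exceed += int((perm_ccc >= observed).sum())
        done += p
    return (1 + exceed) / (1 + n_perm)


def _degenerate_result(x: FeatureVector, y: FeatureVector, n_used: int) -> CccResult:
    return CccResult(x.id, y.id, 0.0, None, None, None, n_used, True)


def ccc_pair(
    x: FeatureVector,
    y: FeatureVector,
    config: CccConfig = CccConfig(),
    pair_index: int = 0,
) -> CccResult:
    """CCC between two features on their pairwise-complete samples.

    Pairs with fewer than ``config.min_samples`` usable samples, or where
    either feature yields no non-degenerate partition (e.g. constant input),
    are reported degenerate with ccc = 0. ``pair_index`` seeds the
    permutation stream jointly with ``config.seed``; :func:`ccc_matrix`
    passes each pair's position so matrix rows and standalone calls agree.
    """
    if x.n_samples != y.n_samples:
        raise ValueError(
            f"feature length mismatch: {x.n_samples} vs {y.n_samples}"
        )
    keep = ~(x.missing_mask | y.missing_mask)
    n_used = int(keep.sum())
    if n_used < config.min_samples:
        return _degenerate_result(x, y, n_used)
    xr = FeatureVector(x.id, x.kind, x.values[keep], np.zeros(n_used, bool))
    yr = FeatureVector(y.id, y.kind, y.values[keep], np.zeros(n_used, bool))
    psx = build_partition_set(xr, config.k_range)
    psy = build_partition_set(yr, config.k_range)
    if len(psx) == 0 or len(psy) == 0:
        return _degenerate_result(x, y, n_used)
    raw, pxi, pyi = _max_ccc_tasks(psx, psy)
    ccc = max(0.0, raw)
    pvalue = None
    if config.n_perm > 0:
        rng = _pair_rng(config.seed, pair_index)
        pvalue = _permutation_pvalue(psx, psy, ccc, config.n_perm, rng)
    return CccResult(
        x.id,
        y.id,
        ccc,
        psx.partitions[pxi].source_k,
        psy.partitions[pyi].source_k,
        pvalue,
        n_used,
        False,
        raw_max_ari=raw,
    )


def ccc_matrix(
    features: Sequence[FeatureVector],
    config: CccConfig = CccConfig(),
) -> PairResultTable:
    """CCC for every unordered feature pair (i < j), in row order (i, j).

    Features without missing values are partitioned once and their pairs run
    through the batched ARI engine; pairs touching a feature with missing
    entries are re-partitioned on the joint non-missing subset, so every row
    equals the corresponding :func:`ccc_pair` call exactly.
    """
    m = len(features)
    if m < 2:
        raise ValueError("ccc_matrix requires at least 2 features")
    n = features[0].n_samples
    for f in features:
        if f.n_samples != n:
            raise ValueError("all features must share the sample count")

    complete = [not f.missing_mask.any() for f in features]
    psets: list[PartitionSet | None] = [
        build_partition_set(f, config.k_range) if c else None
        for f, c in zip(features, complete)
    ]

    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    engine_pairs = [
        (idx, ij) for idx, ij in enumerate(pairs)
        if complete[ij[0]] and complete[ij[1]]
    ]
    results: list[CccResult | None] = [None] * len(pairs)

    if engine_pairs:
        maxima = execute_tasks(
            [ps if ps is not None else PartitionSet("", (), 0) for ps in psets],
            [ij for _, ij in engine_pairs],
            config.engine,
        )
        for (idx, (i, j)), pm in zip(engine_pairs, maxima):
            results[idx] = _pairmax_to_result(
                features[i], features[j], psets[i], psets[j], pm, config, idx
            )

    for idx, (i, j) in enumerate(pairs):
        if results[idx] is None:
            results[idx] = ccc_pair(features[i], features[j], config, pair_index=idx)

    return PairResultTable(results, config.provenance())


def _pairmax_to_result(
    x: FeatureVector,
    y: FeatureVector,
    psx: PartitionSet,
    psy: PartitionSet,
    pm: PairMax,
    config: CccConfig,
    pair_index: int,
) -> CccResult:
    n_used = psx.n_effective if len(psx) else x.n_samples
    if pm.degenerate or n_used < config.min_samples:
        return _degenerate_result(x, y, n_used)
    ccc = max(0.0, pm.max_ari)
    pxi, pyi = pm.argmax
    pvalue = None
    if config.n_perm > 0:
        rng = _pair_rng(config.seed, pair_index)
        pvalue = _permutation_pvalue(psx, psy, ccc, config.n_perm, rng)
    return CccResult(
        x.id,
        y.id,
        ccc,
        psx.partitions[pxi].source_k,
        psy.partitions[pyi].source_k,
        pvalue,
        n_used,
        False,
        raw_max_ari=pm.max_ari,
    )
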