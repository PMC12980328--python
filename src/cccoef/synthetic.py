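"""Synthetic expression motifs for end-to-end testing without downloads.

Emulates the qualitative gene-pair patterns seen in large expression
compendia that motivate a clustering-based coefficient:

- ``linear``: y = x + noise.
- ``quadratic``: y = x^2 + noise on symmetric x, invisible to Pearson.
- ``cohort_shift``: two sample cohorts, each with a clean positive
  within-cohort slope, offset so the pooled least-squares slope is negative
  (the classical coefficients report the wrong sign).
- ``group_masked``: x is exactly zero in one group (think a Y-chromosome
  gene in female samples) and positive in the other, where y follows x
  linearly. In the silent group the partner gene sits tightly at its
  baseline — the centre of its active-group range — and the active-group
  (repressive) slope crosses that baseline, so the pooled linear trend is
  weak and wrong-signed: quantile partitions see the relationship, the
  classical coefficients rank it low.
- ``subset_masked``: one sample subset is linear, the other is independent
  noise over the same range, diluting the pooled linear signal.
- ``null``: independent draws.

Base values are uniform; noise is additive Gaussian. Everything is
deterministic under the spec's seed, and each dataset records the generating
pattern of every engineered pair in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["PATTERNS", "PatternSpec", "SyntheticDataset",
           "generate_pair_pattern", "generate_dataset"]

PATTERNS = ("linear", "quadratic", "cohort_shift", "group_masked",
            "subset_masked", "null")

#: Motif constants shipped with the package so runs are reproducible:
#: cohort offsets +/-2 around a within-cohort slope of +1; the group-masked
#: gene is expressed in a narrow band with a baseline-crossing slope.
COHORT_OFFSET = 2.0
GROUP_MASKED_X_LO = 1.0
GROUP_MASKED_X_HI = 1.4
GROUP_MASKED_SLOPE = -5.0


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one engineered pair."""

    pattern: str
    n_samples: int = 200
    noise_sd: float = 0.1
    group_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern: {self.pattern!r}")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.group_fraction < 1:
            raise ValueError("group_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticDataset:
    """Expression matrix + per-sample metadata + engineered-pair truth table."""

    expression: pd.DataFrame  # features x samples
    metadata: pd.DataFrame  # one row per sample
    truth: pd.DataFrame  # feature_x, feature_y, pattern
    provenance: Mapping[str, object] = field(default_factory=dict)


def _group_assignment(rng: np.random.Generator, n: int, fraction: float
                      ) -> np.ndarray:
    """Deterministic shuffled membership with exactly round(fraction*n) ones."""
    n_one = int(round(fraction * n))
    g = np.zeros(n, dtype=np.int64)
    g[:n_one] = 1
    rng.shuffle(g)
    return g


def generate_pair_pattern(
    spec: PatternSpec, group: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """One engineered (x, y) pair plus the metadata columns it depends on.

    ``group`` optionally supplies a shared binary membership (so several
    pairs in a dataset reference the same cohort/sex column); otherwise one
    is drawn from the spec's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_samples
    noise = spec.noise_sd
    meta: dict[str, np.ndarray] = {}

    if spec.pattern in ("cohort_shift", "group_masked", "subset_masked"):
        if group is None:
            group = _group_assignment(rng, n, spec.group_fraction)
        group = np.asarray(group, dtype=np.int64)
        meta["group"] = group

    if spec.pattern == "linear":
        x = rng.uniform(0.0, 1.0, n)
        y = x + rng.normal(0.0, noise, n)
    elif spec.pattern == "quadratic":
        x = rng.uniform(-1.0, 1.0, n)
        y = x ** 2 + rng.normal(0.0, noise, n)
    elif spec.pattern == "cohort_shift":
        # cohort 0 sits at low x / high y, cohort 1 at high x / low y; both
        # slopes are +1 within cohort, so the pooled fit slopes downward
        base = rng.uniform(0.0, 1.0, n)
        x = np.where(group == 0, base, base + COHORT_OFFSET)
        y = np.where(group == 0, base + COHORT_OFFSET, base) \
            + rng.normal(0.0, noise, n)
    elif spec.pattern == "group_masked":
        # group 0: x exactly zero (gene silent), y at its baseline; group 1:
        # x positive in a narrow band, y linear in x with a slope that
        # crosses the baseline so the pooled covariance cancels
        pos = rng.uniform(GROUP_MASKED_X_LO, GROUP_MASKED_X_HI, n)
        x = np.where(group == 1, pos, 0.0)
        mid = 0.5 * (GROUP_MASKED_X_LO + GROUP_MASKED_X_HI)
        y = np.where(group == 1, GROUP_MASKED_SLOPE * (pos - mid) + mid, mid) \
            + rng.normal(0.0, noise, n)
    elif spec.pattern == "subset_masked":
        x = rng.uniform(0.0, 1.0, n)
        y_indep = rng.uniform(0.0, 1.0, n)
        y = np.where(group == 1, x, y_indep) + rng.normal(0.0, noise, n)
    elif spec.pattern == "null":
        x = rng.uniform(0.0, 1.0, n)
        y = rng.uniform(0.0, 1.0, n)
    else:  # pragma: no cover - guarded by PatternSpec
        raise ValueError(spec.pattern)
    return x, y, meta


def generate_dataset(
    n_pairs_per_pattern: int | Mapping[str, int] = 1,
    n_null_features: int = 0,
    n_samples: int = 200,
    noise_sd: float = 0.1,
    group_fraction: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Assemble a reproducible feature x sample matrix with known truth.

    Engineered pairs are generated per pattern (feature ids encode the
    pattern, e.g. ``cohort_shift_0_x``); extra standalone null features pad
    the matrix. Metadata carries the shared binary ``group`` (used by the
    masked motifs), a binary ``cohort`` and a numerical ``age`` covariate
    unrelated to expression. Identical seeds give bit-identical outputs.
    """
    if isinstance(n_pairs_per_pattern, int):
        counts = {p: n_pairs_per_pattern for p in PATTERNS}
    else:
        unknown = set(n_pairs_per_pattern) - set(PATTERNS)
        if unknown:
            raise ValueError(f"unknown patterns: {sorted(unknown)}")
        counts = {p: int(n_pairs_per_pattern.get(p, 0)) for p in PATTERNS}
    if any(c < 0 for c in counts.values()) or n_null_features < 0:
        raise ValueError("counts must be >= 0")
    if sum(counts.values()) == 0 and n_null_features == 0:
        raise ValueError("dataset must contain at least one feature")

    root = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    group = _group_assignment(meta_rng, n_samples, group_fraction)
    cohort = _group_assignment(meta_rng, n_samples, 0.5)
    age = meta_rng.uniform(20.0, 70.0, n_samples)

    rows: dict[str, np.ndarray] = {}
    truth_rows = []
    pair_seed_iter = iter(
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in root.spawn(sum(counts.values()) + n_null_features + 1)[1:]
    )
    for pattern in PATTERNS:
        for r in range(counts[pattern]):
            spec = PatternSpec(pattern, n_samples, noise_sd, group_fraction,
                               seed=next(pair_seed_iter))
            shared = None
            if pattern == "cohort_shift":
                shared = cohort
            elif pattern in ("group_masked", "subset_masked"):
                shared = group
            x, y, _ = generate_pair_pattern(spec, group=shared)
            fx, fy = f"{pattern}_{r}_x", f"{pattern}_{r}_y"
            rows[fx], rows[fy] = x, y
            truth_rows.append((fx, fy, pattern))
    for r in range(n_null_features):
        rng = np.random.default_rng(next(pair_seed_iter))
        rows[f"nullfeat_{r}"] = rng.uniform(0.0, 1.0, n_samples)

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    expression = pd.DataFrame(rows, index=sample_ids).T
    expression.index.name = "feature_id"
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(group == 1, "M", "F"),
            "cohort": np.where(cohort == 1, "postmortem", "organ_donor"),
            "age": age,
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["feature_x", "feature_y",
                                              "pattern"])
    provenance = {
        "seed": seed,
        "n_samples": n_samples,
        "noise_sd": noise_sd,
        "group_fraction": group_fraction,
        "counts": dict(counts),
        "n_null_features": n_null_features,
    }
    return SyntheticDataset(expression, metadata, truth, provenance)
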