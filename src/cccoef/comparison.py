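"""Coefficient-agreement analysis: baselines, tiers, intersections, metadata.

The downstream question is where the clustering-based coefficient and the
classical ones disagree. Each coefficient's per-pair values are split into
percentile tiers — *high* (top q fraction), *low* (bottom q fraction),
*neither* — and every pair gets an intersection category, its tier triple
across (ccc, pearson, spearman). Categories where all three agree high or
low are "agreement"; categories mixing a high with a low are "disagreement";
among categories with ccc high, exactly five contain a Pearson-or-Spearman
low — the groups that surface candidate nonlinear pairs. Selected candidates
are then associated with sample metadata (sex, cohort, numerical covariates)
using the coefficient's mixed-type capability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coefficient import CccConfig, PairResultTable, ccc_pair
from .partitioning import FeatureVector

__all__ = [
    "TIERS",
    "baseline_coefficients",
    "classify_tiers",
    "intersect_categories",
    "category_class",
    "enumerate_ccc_high_disagreement",
    "select_candidate_pairs",
    "metadata_associations",
]

TIERS = ("high", "low", "neither")


def _pairwise_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    cols = {}
    for f in features:
        if f.kind != "numerical":
            raise ValueError(
                f"baseline coefficients require numerical features, got "
                f"{f.id!r} ({f.kind})"
            )
        v = f.values.astype(float).copy()
        v[f.missing_mask] = np.nan
        cols[f.id] = v
    return pd.DataFrame(cols)


def baseline_coefficients(
    features: Sequence[FeatureVector], method: str
) -> pd.DataFrame:
    """Pearson or Spearman for every unordered pair, in (i, j) row order.

    Uses pairwise-complete observations, mirroring the coefficient's missing
    policy. Returns columns feature_i, feature_j, value.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    df = _pairwise_frame(features)
    corr = df.corr(method=method, min_periods=2)
    ids = [f.id for f in features]
    rows = [
        (ids[i], ids[j], corr.iloc[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    return pd.DataFrame(rows, columns=["feature_i", "feature_j", "value"])


def classify_tiers(
    values: Sequence[float] | np.ndarray,
    q_high: float = 0.30,
    q_low: float = 0.30,
    magnitude: bool = True,
) -> np.ndarray:
    """Percentile tiers of per-pair coefficient values.

    The ``ceil(q_high * N)`` largest and ``ceil(q_low * N)`` smallest ranked
    values (over the N finite entries) become *high* and *low*; the rest
    *neither*. Signed coefficients rank by ``|value|`` (``magnitude=True``);
    the non-negative clustering coefficient ranks by value itself. Ties are
    broken by stable input order; non-finite entries are tiered *neither*.
    """
    if q_high < 0 or q_low < 0 or q_high + q_low > 1:
        raise ValueError("require q_high, q_low >= 0 and q_high + q_low <= 1")
    arr = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(arr))
    if finite.size == 0:
        raise ValueError("classify_tiers requires at least one finite value")
    key = np.abs(arr[finite]) if magnitude else arr[finite]
    n = finite.size
    n_high = math.ceil(q_high * n)
    n_low = math.ceil(q_low * n)
    tiers = np.full(arr.size, "neither", dtype=object)
    desc = np.argsort(-key, kind="stable")  # ties keep input order
    high_local = set(desc[:n_high].tolist())
    tiers[finite[desc[:n_high]]] = "high"
    asc = np.argsort(key, kind="stable")  # ties keep input order
    low_local = [i for i in asc.tolist() if i not in high_local][:n_low]
    if low_local:
        tiers[finite[np.array(low_local, dtype=int)]] = "low"
    return tiers


def category_class(tier_triple: tuple[str, str, str]) -> str:
    """agreement / disagreement / other for one (ccc, pearson, spearman) triple."""
    ts = set(tier_triple)
    if len(ts) == 1 and tier_triple[0] in ("high", "low"):
        return "agreement"
    if "high" in ts and "low" in ts:
        return "disagreement"
    return "other"


def intersect_categories(
    tiers_ccc: np.ndarray,
    tiers_pearson: np.ndarray,
    tiers_spearman: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each pair its tier triple; count occupied categories.

    Returns ``(per_pair, counts)``: per-pair columns ccc_tier, pearson_tier,
    spearman_tier, category_class; counts one row per occupied category with
    n_pairs, ordered by descending count then triple.
    """
    if not (len(tiers_ccc) == len(tiers_pearson) == len(tiers_spearman)):
        raise ValueError("tier tables must align on the same pair ordering")
    per_pair = pd.DataFrame(
        {
            "ccc_tier": tiers_ccc,
            "pearson_tier": tiers_pearson,
            "spearman_tier": tiers_spearman,
        }
    )
    per_pair["category_class"] = [
        category_class(t)
        for t in zip(tiers_ccc, tiers_pearson, tiers_spearman)
    ]
    counts = (
        per_pair.groupby(
            ["ccc_tier", "pearson_tier", "spearman_tier", "category_class"],
            observed=True,
        )
        .size()
        .reset_index(name="n_pairs")
        .sort_values(
            ["n_pairs", "ccc_tier", "pearson_tier", "spearman_tier"],
            ascending=[False, True, True, True],
            kind="stable",
        )
        .reset_index(drop=True)
    )
    return per_pair, counts


def enumerate_ccc_high_disagreement() -> list[tuple[str, str, str]]:
    """All tier triples with ccc high and a low among Pearson/Spearman.

    Enumerates {high, low, neither}^2 for the two classical coefficients;
    exactly five triples contain at least one low — the candidate groups for
    nonlinear pairs.
    """
    return [
        ("high", p, s)
        for p, s in itertools.product(TIERS, repeat=2)
        if "low" in (p, s)
    ]


def select_candidate_pairs(
    results: pd.DataFrame,
    per_pair_categories: pd.DataFrame,
    groups: Sequence[tuple[str, str, str]],
    top_n: int = 100,
) -> pd.DataFrame:
    """Top-n pairs by ccc within the given intersection categories.

    ``results`` must carry feature_i, feature_j, ccc aligned row-for-row with
    ``per_pair_categories``. Ties at the cut keep the lexicographically
    smaller (feature_i, feature_j).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(results) != len(per_pair_categories):
        raise ValueError("results and categories must align row-for-row")
    triples = list(
        zip(
            per_pair_categories["ccc_tier"],
            per_pair_categories["pearson_tier"],
            per_pair_categories["spearman_tier"],
        )
    )
    wanted = set(groups)
    eligible = results[[t in wanted for t in triples]].copy()
    eligible = eligible.sort_values(
        ["ccc", "feature_i", "feature_j"],
        ascending=[False, True, True],
        kind="stable",
    )
    return eligible.head(top_n).reset_index(drop=True)


@dataclass(frozen=True)
class MetadataAssociation:
    gene: str
    variable: str
    variable_kind: str
    ccc: float
    pvalue: float | None


def metadata_associations(
    candidate_pairs: pd.DataFrame,
    expression_features: Sequence[FeatureVector],
    metadata_features: Sequence[FeatureVector],
    config: CccConfig = CccConfig(),
) -> pd.DataFrame:
    """Associate every gene of the candidate pairs with every metadata variable.

    Categorical variables enter through their category partition, numerical
    ones through quantile partitions, exactly like genes. Output is sorted by
    ccc descending (ties by gene then variable).
    """
    by_id = {f.id: f for f in expression_features}
    genes: list[str] = []
    for _, row in candidate_pairs.iterrows():
        for g in (row["feature_i"], row["feature_j"]):
            if g not in genes:
                genes.append(g)
    rows = []
    for idx, (g, meta) in enumerate(
        (g, meta) for g in genes for meta in metadata_features
    ):
        res = ccc_pair(by_id[g], meta, config, pair_index=idx)
        rows.append(
            MetadataAssociation(g, meta.id, meta.kind, res.ccc, res.pvalue)
        )
    out = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "variable": [r.variable for r in rows],
            "variable_kind": [r.variable_kind for r in rows],
            "ccc": [r.ccc for r in rows],
            "pvalue": [r.pvalue for r in rows],
        }
    )
    return out.sort_values(
        ["ccc", "gene", "variable"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
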