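"""ARI closed form vs pair-counting oracle; batch planner; task executor."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from cccoef import (
    EngineConfig,
    Partition,
    PartitionSet,
    ari_from_table,
    ari_many,
    ari_pair_oracle,
    contingency_table,
    execute_tasks,
    plan_batches,
)


def part(labels):
    labels = np.asarray(labels, dtype=np.int64)
    k = int(labels.max()) + 1
    return Partition(labels=labels, k=k, source_k=k, degenerate=k < 2)


def test_contingency_table_tallies():
    t = contingency_table(part([0, 0, 0, 1, 1, 2]), part([0, 0, 1, 1, 2, 2]))
    assert t.counts.tolist() == [[2, 1, 0], [0, 1, 1], [0, 0, 1]]
    assert t.a.tolist() == [3, 2, 1] and t.b.tolist() == [2, 2, 2] and t.n == 6


def test_contingency_length_mismatch_raises():
    with pytest.raises(ValueError):
        contingency_table(part([0, 1]), part([0, 1, 0]))


@pytest.mark.parametrize(
    "p,q,expected",
    [
        ([0, 0, 1, 1], [0, 0, 1, 1], 1.0),
        ([0, 0, 1, 1], [0, 1, 0, 1], -0.5),  # crossing partitions
        ([0, 0, 0, 1, 1, 2], [0, 0, 1, 1, 2, 2], (1 - 0.8) / (3.5 - 0.8)),
    ],
)
def test_worked_ari_values(p, q, expected):
    t = contingency_table(part(p), part(q))
    assert ari_from_table(t) == pytest.approx(expected, abs=1e-12)
    assert ari_pair_oracle(part(p), part(q)) == pytest.approx(expected, abs=1e-12)


def test_label_permutation_invariance():
    p = part([0, 0, 1, 1, 2, 2])
    q = part([2, 2, 0, 0, 1, 1])  # same clustering, renamed clusters
    assert ari_from_table(contingency_table(p, q)) == 1.0
    assert ari_pair_oracle(p, q) == 1.0


@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=30),
    st.lists(st.integers(0, 3), min_size=2, max_size=30),
)
def test_closed_form_matches_oracle_and_sklearn(lp, lq):
    n = min(len(lp), len(lq))
    p, q = part(lp[:n]), part(lq[:n])
    ours = ari_from_table(contingency_table(p, q))
    assert ours == pytest.approx(ari_pair_oracle(p, q), abs=1e-12)
    skl = adjusted_rand_score(p.labels, q.labels)
    # sklearn returns 1.0 on the degenerate identical-trivial edge too
    assert ours == pytest.approx(skl, abs=1e-10)
    # symmetry
    assert ours == ari_from_table(contingency_table(q, p))


def test_expected_ari_under_independent_shuffles_is_near_zero():
    rng = np.random.default_rng(7)
    base = np.repeat(np.arange(4), 50)
    p = part(base)
    vals = [
        ari_from_table(contingency_table(p, part(rng.permutation(base))))
        for _ in range(1000)
    ]
    assert abs(float(np.mean(vals))) < 0.02


def test_ari_many_matches_scalar_path():
    rng = np.random.default_rng(3)
    tasks = []
    for _ in range(25):
        kx, ky = rng.integers(2, 6, size=2)
        tasks.append((rng.integers(0, kx, 40), rng.integers(0, ky, 40)))
    lx = np.vstack([np.asarray(t[0]) for t in tasks])
    ly = np.vstack([np.asarray(t[1]) for t in tasks])
    kx = lx.max(axis=1) + 1
    ky = ly.max(axis=1) + 1
    got = ari_many(lx, ly, kx, ky)
    for g, (a, b) in zip(got, tasks):
        want = ari_from_table(contingency_table(part(a), part(b)))
        assert g == want  # bit-identical, not approx


def test_plan_batches_shapes():
    plan = plan_batches(100, 100, 1000)
    assert plan.batch_boundaries == tuple((i, i + 10) for i in range(0, 100, 10))
    plan = plan_batches(7, 100, 300)
    assert [e - s for s, e in plan.batch_boundaries] == [3, 3, 1]
    # budget below one task clamps to one task per batch
    plan = plan_batches(3, 100, 10)
    assert [e - s for s, e in plan.batch_boundaries] == [1, 1, 1]
    assert plan_batches(0, 8, 8).batch_boundaries == ()


@given(st.integers(1, 500), st.integers(1, 64), st.integers(1, 4096))
def test_plan_batches_covers_tasks_exactly_once(n_tasks, per, budget):
    plan = plan_batches(n_tasks, per, budget)
    covered = [i for s, e in plan.batch_boundaries for i in range(s, e)]
    assert covered == list(range(n_tasks))
    cap = max(1, budget // per)
    assert all(e - s <= cap for s, e in plan.batch_boundaries)


def _pset(fid, parts, n):
    return PartitionSet(fid, tuple(parts), n)


def test_execute_tasks_identity_and_argmax():
    p = part([0, 0, 1, 1])
    ps = _pset("f", [p], 4)
    [res] = execute_tasks([ps, ps], [(0, 1)])
    assert res.max_ari == 1.0 and res.argmax == (0, 0)


def test_execute_tasks_returns_raw_negative_max():
    p = _pset("x", [part([0, 0, 1, 1])], 4)
    q = _pset("y", [part([0, 1, 0, 1]), part([0, 1, 1, 0])], 4)
    [res] = execute_tasks([p, q], [(0, 1)])
    # both combos give negative ARI; the engine must not clamp
    assert res.max_ari < 0
    combos = [
        ari_from_table(contingency_table(p.partitions[0], qq))
        for qq in q.partitions
    ]
    assert res.max_ari == max(combos)


def test_execute_tasks_argmax_ties_take_lowest_global_index():
    p = part([0, 0, 1, 1])
    ps = _pset("f", [p, p], 4)  # duplicate partitions: all four combos tie at 1
    [res] = execute_tasks([ps, ps], [(0, 1)])
    assert res.argmax == (0, 0)


def test_execute_tasks_empty_partition_set_reports_degenerate():
    p = _pset("x", [part([0, 0, 1, 1])], 4)
    empty = _pset("c", [], 4)
    [res] = execute_tasks([p, empty], [(0, 1)])
    assert res.degenerate


def _random_psets(seed, n_feat=6, n=60):
    rng = np.random.default_rng(seed)
    psets = []
    for f in range(n_feat):
        parts = []
        for k in range(2, rng.integers(3, 7)):
            labels = rng.integers(0, k, n)
            labels[:k] = np.arange(k)  # ensure every cluster occupied
            parts.append(part(labels))
        psets.append(_pset(f"f{f}", parts, n))
    return psets


@pytest.mark.parametrize("workers", [1, 4])
@pytest.mark.parametrize("budget", [1, 10_000, 4 << 30])
@pytest.mark.parametrize("backend", ["reference", "vectorized"])
def test_execute_tasks_bit_identical_across_configs(workers, budget, backend):
    psets = _random_psets(11)
    pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
    baseline = execute_tasks(psets, pairs, EngineConfig())
    got = execute_tasks(
        psets, pairs,
        EngineConfig(budget_bytes=budget, workers=workers, backend=backend),
    )
    for a, b in zip(baseline, got):
        assert a.max_ari == b.max_ari and a.argmax == b.argmax
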