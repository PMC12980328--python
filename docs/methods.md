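# Methods

## The coefficient

CCC(x, y) is the clamped maximum Adjusted Rand Index over all pairings of
the two features' internal clusterings. A numerical feature is clustered by
empirical quantiles at i/k for each cluster count k in a sweep; a
categorical feature has exactly one clustering, its categories. Because
partitions are the common currency, numerical–numerical,
numerical–categorical and categorical–categorical comparisons all reduce to
the same ARI computation, and the coefficient inherits the ARI's chance
correction: identical partitions score 1, independent ones 0 in expectation.

Assumptions worth stating plainly: the coefficient sees only the partition
structure, so it is invariant under strictly increasing transforms of either
feature and blind to the *direction* of an association (no sign). It detects
any dependence that aligns some quantile binning of x with some binning of
y; dependences confined to a small sample subset are diluted in proportion
to that subset (see the subset-masked motif below).

## Partitioning details

Quantile cut points use linear interpolation of order statistics with
plotting positions (j−1)/(n−1) — the "type-7" convention of `np.quantile`.
A sample whose value equals a cut point goes to the lower cluster. Labels
are assigned in rank space: the interpolation position h = (n−1)·i/k is
split into integer and fractional parts exactly (integer arithmetic), and a
sample is above cut i iff its value exceeds the j-th order statistic (γ = 0
or tied neighbours) or reaches the (j+1)-th (γ > 0). This is algebraically
identical to materialising the interpolated cut values and comparing, but
makes monotone invariance exact in floating point rather than approximate —
the bit-exact invariance law in the tests relies on it. Ties always share a
label; empty bins are compacted away; a partition with fewer than two
non-empty clusters is degenerate and dropped. Duplicate partitions arising
at different k are retained — the max-reduction is unaffected.

## ARI computation

The Hubert–Arabie form is evaluated from integer pair-count sums with a
single float division at the end:

    ARI = 2·(C(n,2)·S − A·B) / (C(n,2)·(A+B) − 2·A·B)

with S = Σ_ij C(n_ij,2), A = Σ_i C(a_i,2), B = Σ_j C(b_j,2). Both backends
(pure-Python reference loop; vectorized numpy over stacked label matrices)
produce the same exact integers, are cast to float64 identically, and hence
agree bit for bit — the backend contract is equality, not tolerance. A
vanishing denominator (both partitions trivial and identical) returns 1.0.
int64 accumulation is exact up to roughly 50,000 samples; beyond that the
engine would need object/128-bit arithmetic. The brute-force pair-confusion
oracle (N11/N10/N01/N00 over all C(n,2) sample pairs) is implemented
independently and compared exhaustively in the tests; `sklearn`'s
`adjusted_rand_score` serves as a third, external cross-check.

## Execution architecture

Every partition combination of every feature pair is a task with a unique
global index (pair-major, then row-major over the partition grid). A batch
planner splits the global range into contiguous batches of
max(1, floor(budget_bytes / per_task_bytes)) tasks, where per_task_bytes is
the declared footprint of one k_max × k_max contingency table plus scratch;
the default budget is 4 GiB. Batches may be evaluated by worker threads;
each batch writes a disjoint slice of the task-value array, and the per-pair
max-reduction (first argmax in global-index order, i.e. lowest k pair on
ties) runs afterwards in a fixed order — so results are independent of
workers, budget and backend by construction, not by luck. The engine returns
the raw, possibly negative maximum; clamping to [0, 1] is the coefficient
layer's job, which keeps the engine directly testable against the oracle.

## Missing data

Pairs are evaluated on pairwise-complete samples with a floor
(`min_samples`, default 10) below which the pair is reported degenerate
(ccc = 0, flagged) rather than estimated. In `ccc_matrix`, features without
missing values are partitioned once and run through the batched engine;
pairs touching a feature with missing entries are re-partitioned on the
joint non-missing subset, because quantiles of a subset are not the
restriction of full-sample quantiles. Both routes return exactly what the
corresponding `ccc_pair` call returns.

## Permutation p-values

The null reshuffles the second feature's values n_perm times with x fixed;
p = (1 + #{CCC_perm ≥ CCC_obs}) / (1 + n_perm), the add-one estimator, so
p ≥ 1/(1+n_perm) and the test never reports zero. Permuting a feature's
values and re-partitioning is *exactly* equivalent to permuting its
partition labels (quantile cuts depend only on the value multiset), so the
implementation permutes label matrices and evaluates whole permutation
blocks vectorized. Each pair's permutation stream is seeded from
(seed, pair_index) via `SeedSequence`, making p-values reproducible and
independent of execution order or parallelism. p-values default to off
(n_perm = 0): coefficient screening over many pairs is the common first
pass, and permutations multiply its cost by ~n_perm.

## Agreement analysis

Per-coefficient percentile tiers label the top q_high fraction of pairs
"high", the bottom q_low "low" (ceiling counts, stable-order tie-breaks),
the rest "neither". The non-negative CCC is ranked by value. For
Pearson/Spearman the pipeline ranks by *signed* value: a strongly negative
coefficient is a "low correlation" in the agreement analysis, which is how
pairs whose pooled slope has the wrong sign (the cohort-shift motif) land in
the CCC-high/classical-low disagreement groups. `classify_tiers` also
offers magnitude ranking for uses where |r| is the right scale. Enumerating
{high, low, neither}² for the two classical coefficients under CCC-high
yields exactly five categories containing a "low" — the candidate groups for
nonlinear pairs. Candidate selection sorts those pairs by CCC descending
(ties by pair id) and truncates; no multiple-testing correction is applied,
since selection is by rank, and p-values are reported raw with their n_perm
provenance.

## Synthetic motifs

The generator emulates the qualitative pair patterns that motivate the
coefficient; defaults (n = 200 samples, additive Gaussian noise sd 0.1 on
uniform base values, 50/50 group split) are fixed constants shipped with
the package.

- *linear*: y = x + ε.
- *quadratic*: y = x² + ε on x ~ U(−1, 1).
- *cohort_shift*: within each of two cohorts y = x + ε with slope +1, but
  cohort offsets ±2 place one cohort at low-x/high-y and the other at
  high-x/low-y, so the pooled slope is negative.
- *group_masked*: x is exactly 0 in one group and U(1.0, 1.4) in the other;
  in the active group y = 1.2 − 5(x − 1.2) (a repressive, baseline-crossing
  slope), in the silent group y sits at the 1.2 baseline. The pooled linear
  trend is weak and negative, while quantile partitions see both the exact
  zero block and the within-group line (ccc ≈ 0.4–0.5). The silent-group
  baseline is a design choice: with the partner instead drawn independently
  over the active range, the motif's ARI is provably capped near 0.25 at a
  50/50 split and Pearson exceeds it — a pattern no coefficient here would
  rank as a disagreement.
- *subset_masked*: half the samples follow y = x + ε, half are independent
  noise over the same range. At a 50/50 split the best attainable ARI is
  ≈ 0.25 (the independent half contributes random co-assignment), so this
  motif is *expected* to score low — it documents the coefficient's
  dilution behaviour rather than a detection success.
- *null*: independent uniforms.

What the generator does not emulate: RNA-seq count distributions,
library-size and batch effects, gene–gene correlation backbones. Passing
tests therefore demonstrate the statistic's behaviour on clean geometric
motifs, not end-to-end robustness on real sequencing artefacts.

One suite-size caveat: the quadratic motif's sample Pearson is a mean-zero
noise draw indistinguishable from the null pairs', so its percentile tier
inside a 66-pair suite is a coin flip; tier-level assertions are made only
where they are almost-sure (cohort-shift, group-masked, linear), and the
quadratic claim is value-level (|pearson| at noise floor, ccc tier high).

## Problem sizes

The test and acceptance workloads use 6-sample exhaustive partition
enumeration (122 partitions, all ordered pairs) for the oracle check, n =
50–200 samples for coefficient laws and calibration (500 null pairs × 100
permutations), and a 500-feature × 200-sample full pairwise run (124,750
pairs, k = 2..10, ~10 million ARI tasks) for the scale smoke test, which
completes in well under a minute per 100k pairs on one CPU.

## Known limitations

- k_range defaults to 2..10; very small samples (n < ~20) make the larger
  k uninformative, and the coefficient's null level rises as k_range grows
  (maximum over more combinations), which is why null ccc at n = 100 sits
  near 0.05–0.15 rather than 0.
- The engine's int64 arithmetic bounds n at ~50,000 samples.
- Tier cutoffs are within-dataset percentiles; comparing tier labels across
  datasets of very different pair counts compares different absolute scales.
- No analytic p-values; permutation cost scales linearly in n_perm.
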