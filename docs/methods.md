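# Methods

## Data model and sufficient statistics

A typed bipartite network is a triple (agents U, events V, incidence B)
where `B[i, t]` is one of n declared link types or absent.  Everything the
null models consume reduces to sufficient statistics per unordered agent
pair: the event count N, degrees `N_i`, `N_j`, joint-event count `N_ij`,
same-type overlap `Ñ_ij` (events where both are connected *and* the types
are equal — events missing from both never count), per-type overlaps
`N_ij(a_k)`, opposing-type overlap `N^d_ij` over declared opposing pairs,
and the chance probabilities `p_ij = Σ_k p_i(a_k) p_j(a_k)` and
`q_ij = Σ_{(a+,a−)} p_i(a+)p_j(a−) + p_i(a−)p_j(a+)`.

Preference vectors `p_i` are estimated empirically as per-type link counts
divided by `N_i`; a population-pooled variant is available
(`preference_mode="population"`).  After degree/attendance filtering,
preferences are re-estimated on the filtered network.  Zero-degree agents
stay in the network but are excluded from pairwise validation (logged).

A subtlety worth recording: the pigeonhole lower bound
`max(N_i + N_j − N, 0)` constrains the joint-event count `N_ij`, not the
same-type overlap — two agents forced onto a common event can still use
different types there, so `Ñ_ij` can fall below that bound.  Tests assert
`max(N_i+N_j−N, 0) ≤ N_ij ≤ min(N_i, N_j)` and `0 ≤ Ñ_ij ≤ N_ij`.

## Null models

**Reference (per-type hypergeometric).**  For each type a_k the upper tail
of `N_ij(a_k)` under a hypergeometric law with the per-type degrees
`N_i(a_k)`, `N_j(a_k)` and the full event count N; per-pair aggregation by
min, mean, or max.  A type unused by either agent contributes p = 1.

**Hypergeometric-binomial mixture.**  The joint-event count X is
hypergeometric in (N, N_i, N_j); conditional on X, the number of same-type
(or opposing-type) matches is binomial(X, p).  The upper tail sums
`H(X)·B(Y ≥ k | X, p)` over X from k to min(N_i, N_j).  Both factors come
from scipy's log-space implementations (log-gamma based); the summands are
non-negative, so straight accumulation loses no precision — values down to
1e-12 and parameters up to N = 1e4 round-trip without underflow (property
tested).  Queries with k > min(N_i, N_j), which filtered empirical data
can produce, return 0 with a warning rather than raising.

Numerical conventions: probabilities are clipped to [0, 1]; the pair's
degrees are sorted before building parameters so validation is bit-for-bit
symmetric in (i, j); k = 0 returns exactly 1; p = 1 reduces the mixture to
the plain hypergeometric tail (asserted to 1e-9 relative).

A Monte-Carlo oracle (`monte_carlo_null`) simulates the null directly —
two uniformly drawn event sets, an independent success coin per joint
event — and an exhaustive enumeration oracle in the test suite (exact
Fraction arithmetic over all event choices) pins the implementation down
to 1e-12 relative for N ≤ 8.

## Projection and multiple testing

All unordered pairs of positive-degree agents are tested, in lexicographic
identifier order.  An edge is recorded when the raw p-value is at most the
corrected threshold; Bonferroni correction uses m = number of eligible
pairs, applied *independently* per sign family (the positive and negative
tests answer different questions per pair); a joint family (m doubled) is
available via `bonferroni_family="joint"`.  The reference model yields
positive links only.  A pair significant in both directions keeps both
edges; the triad census resolves such pairs to the sign with the smaller
p-value (configurable).  Triangle stability follows the sign-product rule.

Rolling-window projection orders events by their declared (input) order —
timestamps are not part of the data model — and re-estimates profiles
within each window; windows start at 0, step, 2·step, … while a full
window fits.  Network comparison uses the Jaccard index over signed
unordered pairs; two empty networks compare as identical (warned).

Trading records are discretized by net-scaled volume
v = (B − S)/(B + S) with threshold θ (default 0.1): b above θ, s below −θ,
bs otherwise.  The neutral band is closed — v = ±θ maps to bs — keeping
the mapping total.

## Influence-model simulator

The synthetic benchmark generates bipartite networks from a ground-truth
graph (bundled: Zachary karate club, 34 nodes, 78 edges) so that adjacent
agents co-attend events with correlated types.  Per realization each agent
draws fixed attributes: connect probability n_i ~ U[0, 1], mimic
probability c_i ~ U[0, 1], and a preference vector from a symmetric
Dirichlet whose concentration is drawn per agent as 10^U(−2, 2) — spanning
near one-hot to near uniform.  Presets restrict these ranges
(concentrated / mixed / diffuse; a one-hot preset emits exact unit
vectors), and n_i, c_i ranges are configurable for restricted ensembles.

Each of the 100 events runs an independent cascade: a uniform seed agent
always connects, with a type from its preferences; breadth-first from the
seed, each not-yet-decided neighbor of a connected agent decides once —
connect with probability n_i, and on connecting copy the type of a
uniformly chosen already-connected graph neighbor with probability c_i,
else draw from its own preferences.  Agents outside the seed's component
never connect.  Two details are deliberate choices where the procedure is
open: an agent that declines is not re-asked later in the same cascade
(relaxing this would raise effective connectivity), and mimicry copies a
single uniformly chosen connected neighbor rather than the neighborhood
majority.  A single seeded generator drives attribute sampling then
cascades in a documented order, making every realization a pure function
of (graph, config, seed).

What the simulator does *not* emulate: real voting or trading data have
temporally autocorrelated events, agenda-driven event heterogeneity
(violating the interchangeable-events assumption of both nulls), and
preference drift.  Passing benchmarks here shows correct recovery under
the model's own assumptions, not robustness to such violations.

## Evaluation

Reconstruction is scored over all C(|U|, 2) pairs (TP/FP/FN/TN, precision,
recall, F1, accuracy).  Empty predictions have precision defined as 0 and
flagged, so ensemble averages stay defined; consumers that want the
conditional quantity can filter on the flag — trend summaries in the test
suite average precision over runs with non-empty predictions, since the
flagged zeros are an encoding convention, not an estimate.  AUC is the
rank-based (Mann-Whitney) probability that a true edge receives a smaller
p-value than a non-edge, ties averaged; pairs without a p-value score
p = 1; degenerate label sets yield NaN with a warning.  Paired comparisons
use the paired two-sample t-test; zero-variance differences return p = 1
(identical samples) or p = 0 (constant non-zero difference) instead of NaN.

The ensemble experiment simulates networks with fresh attributes per run
(seeds spawned from a master seed; bit-reproducible), computes per-pair
p-values under the mixture and all three reference aggregations, AUCs, and
Bonferroni-thresholded scores per significance level.  The default
benchmark size in the acceptance script is 200 simulations of 100 events,
which stabilizes the mean AUCs to well under the comparison tolerances
while keeping the run in the minutes range.

## Two-agent configuration study

The exhaustive study of a two-agent system (default 20 events, 3 types)
enumerates *sufficient-statistic classes*: the per-type degree
compositions of both agents plus per-type same-type overlaps.  All
computed quantities (mixture p, per-type reference p, Herfindahl-Hirschman
concentration `HH = Σ_k N_ij(a_k)² / Ñ_ij²`, overlap fraction Ñ_ij/N)
depend only on these, so enumerating classes is exact while visiting
~9.7e7 rows instead of ~3.2e9 labeled contingency tables.  A class is
emitted only if a realizing table exists: beyond `s_k ≤ min(x_k, y_k)`,
the `N_i + N_j − Ñ_ij − N` joint events forced by pigeonhole must be
coverable by cross-type pairings, i.e. `≤ min(U, V, U + V − max_k(u_k +
v_k))` with `u = x − s`, `v = y − s`, `U = ΣU_k`, `V = Σv_k` (validated
against brute-force enumeration of labeled assignments at small sizes).
The implementation is blocked numpy with precomputed tail lookup tables
and completes in roughly a minute.

Outputs: mean mixture p and the fraction of classes where the mixture
beats the min-aggregated reference, per (HH bin × overlap-fraction bin)
cell (bin edges configurable; classes with zero same-type overlap have
undefined HH and are excluded from cells but counted elsewhere); the
fraction of classes validated per alpha per method; and each method's
global minimum p-value.  Classes are counted unweighted by default;
`weighting="multiplicity"` weights each class by its number of labeled
event assignments via brute-force table enumeration, which is only
tractable (and only offered) at small event counts.

## Known limitations

- The mixture null assumes events are interchangeable; strongly
  heterogeneous event attendance (e.g. quorum effects) violates it.  A
  per-batch validation stratified by event connectivity is out of scope.
- Negative-link validation requires declared opposing type pairs and is
  undefined without them.
- The influence model is one concrete cascade among several the verbal
  description admits; reconstruction figures should be read with the
  benchmark tolerances in mind, not as exact constants.
- Degree sequences are fixed only on the agent side (preferences enter as
  expectations); doubly-constrained or maximum-entropy ensembles are
  deliberately not implemented.
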