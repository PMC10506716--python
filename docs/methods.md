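# Methods

## Graph model and preprocessing

All computations run on undirected simple graphs stored as symmetric
0/1 sparse adjacency matrices with zero diagonal. Any input — Matrix
Market (general or symmetric coordinate), whitespace edge lists, or a
generator — is binarized (any nonzero weight becomes 1), symmetrized,
and stripped of self-loops on load. Analyses operate on the largest
connected component; `extract_lcc` breaks size ties by the smallest
minimum original node id so results are reproducible.

Node removal is *logical*: the node's row and column are zeroed and
its id enters a removed-set, keeping the matrix dimension fixed. A
zeroed row contributes to no walk, so every walk-based centrality of a
surviving node is identical to its value on the compacted induced
subgraph (asserted as a test to 1e-10 relative); the fixed dimension
keeps ids stable across an attack trajectory.

## Centralities

Total communicability `TC = e^A 1` is evaluated as the action of the
matrix exponential on the masked all-ones vector via
`scipy.sparse.linalg.expm_multiply` (scaling plus truncated Taylor
series), never forming `e^A`. Subgraph centrality `SC_i = [e^A]_ii`
uses the dense exponential up to 2000 nodes (configurable cap) and
per-node Lanczos/Gauss quadrature with 40 steps above it; both caps
are far below the 1e-8 relative-accuracy contract that the test suite
enforces against an independent truncated-Taylor oracle with a
rigorous remainder bound. No experiment here needs SC above the dense
cap; the estimator exists so the API has no size cliff.

A process-global counter increments on every centrality-vector
evaluation (TC, SC or degree alike). The *number of evaluations* is
the cost unit for all strategy comparisons, because for
matrix-function measures one evaluation dominates everything else an
attack step does; degree is counted identically so comparisons remain
consistent across measures.

## Attack strategies

All four strategies remove M nodes, always the argmax of the working
score vector among present nodes, ties to the smallest id (needed for
determinism; the choice is visible on vertex-transitive graphs, where
the removal order is simply 0, 1, 2, …).

- *simultaneous*: one evaluation; the initial descending ranking is
  the removal order.
- *sequential*: recompute after every removal; M evaluations.
- *threshold(γ)*: the working vector is masked to zero on removed
  nodes and normalized to sum 1 over present nodes. After each removal
  the removed node's share accrues to a running mass; when the mass
  exceeds γ the next step recomputes, renormalizes and resets the
  mass. The mass accrued within a window therefore never exceeds γ
  before the step that triggers the recomputation. Masking before
  normalization matters: on the zeroed matrix a removed node would
  otherwise re-enter with TC = SC = 1. With γ = 0 any removal triggers,
  reproducing the sequential order exactly (tested, exact equality on
  50 seeded graphs); with γ close to 1 no removal of a small prefix
  triggers, reproducing the simultaneous order with one evaluation.
- *correlation(l)*: after choosing the victim i\* and reading the
  runner-up j\* from the (possibly stale) scores, the strategy tests
  whether j\* is joined to i\* by a walk of length ≤ l **on the matrix
  state before the removal**; if so, the next step recomputes. The
  test for l = 1 is the entry `A[i*, j*]`; for l > 1 it propagates the
  indicator vector of i\* through l sparse matvecs, never forming a
  matrix power. With fewer than two present nodes there is no
  runner-up and the flag stays off. Evaluations are bounded by
  `M + 1 − m*`, with m\* the position of the first adjacent pair along
  the initial ranking (tested on random instances). Raising l makes
  the per-state test strictly more sensitive and moves the *first*
  recomputation weakly earlier; total counts over a whole attack are
  not monotone in l, because an earlier recomputation changes the
  downstream trajectory — the tests assert the two true monotone
  properties, not the global one.

Fraction-to-count conversion rounds up: removing a fraction δ of n
nodes removes `ceil(δ·n)` nodes.

## Walk-count oracle

The locality argument behind correlation attacks is checked exactly:
removing i lowers TC(j) by `Σ_{k≥s} C_k(i,j)/k!` with `C_k(i,j)` the
number of length-k walks from j through i and `s = dist(i,j)`. The
oracle counts walks by integer dynamic programming (Python
arbitrary-precision ints, so exact at any length) as (all walks) −
(walks avoiding i), and compares the observed TC drop — dense
exponentials on both sides, independent of the sparse action path —
with the truncated series. Since every node has at most n−1 neighbors,
`C_k ≤ (n−1)^k` (attained on complete graphs, where
`C_k = (n−1)^k − (n−2)^k` exactly), so the truncation tail is bounded
by `Σ_{k>K} n^k/k!`; K is chosen adaptively so this bound is below
1e-10 (K ≈ 50 for n = 12). The closed-walk analogue validates the
same identity for subgraph centrality. The module caps itself at 30
present nodes: it is a diagnostic oracle, not a scalable algorithm.

## Synthetic ensembles

The generators define the study conditions for the replicated
experiments:

- `erdrey(n, m)` draws uniformly over simple graphs with exactly m
  edges (networkx `gnm_random_graph`) and redraws until connected; the
  experiments use m = 4n, mean degree 8, where a connected draw is
  almost immediate.
- `pref(n, d)` is the Bollobás linearized-chord-diagram form of
  preferential attachment: nodes arrive one at a time and draw d
  endpoints each, with probability proportional to current degree
  including the arriving node's own half-edges, so self-loops and
  duplicate pairs occur and are dropped in the simple-graph cleanup;
  instances are redrawn until connected. This dialect was chosen over
  the seeded without-replacement variant because it is the standard
  rigorous formulation of the Barabási–Albert model, it matches the
  classic toolbox behaviour of producing self-loops that must be
  stripped, and side-by-side calibration of the two dialects showed it
  yields the stronger hub dominance characteristic of these ensembles
  (larger simultaneous-vs-sequential ranking drift). For d = 2
  the edge count is just under 2n and the degree tail is heavy
  (max degree ≫ mean).

Replicate seeds are `base_seed + replicate`, so any experiment spec
re-run with the same base seed reproduces its table bit-for-bit.

What the synthetic ensembles do *not* emulate: real networks'
clustering, degree correlations, community structure and geographic
constraints (road networks are near-planar; AS graphs are far more
skewed than LCD graphs). Passing the synthetic checks therefore
validates the algorithms and their relative behaviour across
homogeneous vs scale-free degree structure, not quantitative
predictions for any particular real network; real inputs enter through
the Matrix Market/edge-list loaders.

## Robustness metrics

`sigma_curve` replays a removal order backwards with a union-find:
re-inserting nodes in reverse order only ever grows the largest
component, so one sweep yields `σ` after every forward prefix in
near-linear time; the result is contractually identical to
recomputing the largest component from scratch after each step
(tested against that naive oracle). σ after removing all nodes is 0
(an empty graph has no component). `R = mean(σ)` is only reported for
full-removal trajectories — its `[~1/N, (1/2)(1−1/N)]` range and
comparability across networks presuppose full removal — and
`V = 1/2 − R` always.

The intersection distance is computed incrementally: equal-depth
prefixes have equal size, so `|X Δ Y| = 2(i − |X ∩ Y|)` and the
overlap updates in O(1) per depth. Strategy comparisons use prefix
depth k = M, the full removal list.

## Experiment scales and defaults

The replicated comparisons use ensembles of n = 2000 nodes
(pref d = 2; erdrey m = 8000) with top-10% removal (M = 200), 20
replicates, threshold grid γ ∈ {0.001, 0.01}; the vulnerability
ensembles use n = 10000 with full removal under the simultaneous
strategy, 20 replicates. The acceptance script recomputes all of this
from scratch in a few minutes on one core; the dominant cost is the
~17k actions of the matrix exponential in the sequential references.
The default threshold is γ = 0.01 — a working value that balances
fidelity and cost on both families, though scale-free ensembles
tolerate (and Poisson-like ensembles need) smaller γ for a close match
to the sequential order. The default measure is TC, the cheapest
matrix-function centrality at scale; the default walk order is l = 1.

## Degenerate inputs and edge cases

- All-zero centrality vectors (degree after heavy removal) normalize
  to uniform over present nodes with a warning, so the argmax falls
  back to the smallest-id rule instead of crashing.
- Removing a node from one component leaves TC/SC in other components
  unchanged (≤ 1e-10 relative, tested): no walk crosses components.
- The threshold and correlation strategies accept M up to full
  removal; the correlation flag degrades gracefully when no runner-up
  exists.
- Isolated present nodes score TC = SC = 1 (the empty walk only);
  removed nodes score 0 in every measure.

## Known limitations

- The strategies are deterministic given the graph; all stochasticity
  lives in the generators.
- Edge-removal attacks and edge centralities are out of scope, as are
  directed graphs and weighted centralities.
- Exact tie behaviour differs across floating-point exponential
  backends; graphs with nontrivial automorphisms can produce genuinely
  tied scores whose order then depends on the tie rule, which is why
  the smallest-id rule is part of the contract.
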