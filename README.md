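# netattack

Simulation of targeted node-removal ("attack") processes on undirected
networks ranked by matrix-function centralities, with **selective
recomputation** of the ranking.

## The problem

To probe the robustness of a complex network — a protein-interaction
net, a power grid, an Internet AS graph — one removes nodes in
descending order of a centrality measure and watches the structure
degrade. Two classic protocols bracket the design space:

- **simultaneous** attacks rank the nodes once, before the first
  removal, and never look again (1 centrality evaluation);
- **sequential** attacks re-rank after *every* removal (M evaluations
  for M removals), which tracks the evolving network faithfully but is
  expensive for walk-based measures.

For centralities built from the matrix exponential the two protocols
can disagree badly, yet recomputing `e^A`-based scores after every
single removal is often overkill. This package implements two
strategies that recompute the ranking *only when the network has
changed enough to warrant it*:

- **threshold attacks**: keep removing from the stale ranking until the
  cumulative normalized centrality mass removed since the last
  (re)computation exceeds a threshold γ, then recompute. γ = 0 recovers
  the sequential attack; γ near 1 recovers the simultaneous one.
- **correlation attacks**: recompute only when the runner-up in the
  stale ranking is adjacent to the node just removed (or joined to it
  by a walk of length ≤ l). Removing a node only perturbs the
  communicability of *nearby* nodes, so a distant runner-up keeps its
  rank. No tuning parameter is needed.

## Centralities and metrics

With `A` the symmetric 0/1 adjacency matrix of a simple graph:

- **total communicability** `TC_i = [e^A 1]_i` (row sums of `e^A`) — a
  walk count from node *i* with length-*k* walks discounted by `1/k!`,
  computed as one action of the matrix exponential on a vector;
- **subgraph centrality** `SC_i = [e^A]_ii` — the closed-walk analogue;
- **degree** `d_i = [A 1]_i`.

Removal orders are compared with the intersection distance

    isim_k(x, y) = (1/k) Σ_{i=1..k} |x_{1..i} Δ y_{1..i}| / (2i)

(0 for identical lists, → 1 for disjoint ones). Structural damage is
tracked by `σ(ρ)`, the fraction of nodes in the largest connected
component after removing a fraction ρ, summarized over full removal by
the robustness index `R = (1/N) Σ_i σ(i/N)` and the vulnerability index
`V = 1/2 − R`. `R` is maximal, `(1/2)(1 − 1/N)`, for complete graphs
and ≈ `1/N` for stars attacked hub-first.

The theory behind correlation attacks is also in the package as a test
surface (`netattack.walks_oracle`): removing node *i* lowers `TC(j)` by
exactly `Σ_{k≥s} C_k(i,j)/k!`, where `C_k(i,j)` counts length-*k* walks
from *j* through *i* and `s = dist(i, j)` — verified by exact integer
walk counting on small graphs.

## Worked example

```python
import netattack as na
from netattack import metrics

g = na.pref(500, 2, seed=7)          # scale-free graph, 500 nodes
M = 50                               # remove the top 10% by TC
seq = na.sequential_attack(g, "tc", M)
for name, res in [
    ("simultaneous", na.simultaneous_attack(g, "tc", M)),
    ("threshold", na.threshold_attack(g, "tc", M, gamma=0.01)),
    ("correlation", na.correlation_attack(g, "tc", M)),
]:
    d = metrics.intersection_distance(res.order, seq.order).value
    print(f"{name:12s} isim={d:.4f} evaluations={res.evaluations}")
```

prints

```
simultaneous isim=0.4124 evaluations=1
threshold    isim=0.0053 evaluations=34
correlation  isim=0.0933 evaluations=8
```

The simultaneous order drifts far from the sequential reference
(isim 0.41), while the threshold attack reproduces it almost exactly
with a third of the evaluations, and the correlation attack gets
within isim 0.09 for just 8 evaluations instead of 50.

The same runs from the shell; `--network` accepts a Matrix Market
file, an edge list, or a generator spec:

```bash
netattack attack --network pref:n=500,d=2 --strategy threshold \
    --gamma 0.01 --count 5 --seed 7
netattack robustness --network power.mtx --strategy sequential
netattack experiment --config grid.yaml --out rows.csv
netattack generate --network erdrey:n=2000,m=8000 --seed 1 --out g.mtx
```

Input files are reduced to their largest connected component, weights
binarized and self-loops dropped before any attack.

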