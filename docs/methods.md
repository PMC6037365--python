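# Methods

This note documents the models implemented in `ocrank`, the numerical
choices behind them, and what the synthetic benchmark does and does not
establish.

## Graph model

All inputs are coerced to undirected simple graphs: self-loops and
duplicate edges (in either orientation) are dropped at load time and
counted in a `load_report`. The constraint coefficient, k-shell and the
OC score are defined for undirected unweighted graphs, so directed or
weighted semantics are deliberately out of scope. Node labels are opaque
strings; all computation uses contiguous internal indices assigned by
first appearance, which fixes a deterministic order for every output.
Isolated nodes are retained: every ranking covers all of V (required for
rank correlation), with degenerate scores — constraint 0, Nb 0, OC 0.

## Affiliation model (BIGCLAM)

Edge probability `1 − exp(−F_u·F_v)` with nonnegative F; the
log-likelihood sums over unordered pairs. Numerical choices:

- **Optimizer.** Full-batch projected gradient ascent with backtracking
  line search under an Armijo sufficient-increase rule (σ = 0.05).
  Updating all rows simultaneously keeps the fit equivariant under node
  relabeling and guarantees a non-decreasing likelihood trace. The
  non-edge part of the gradient uses the cached column sum Σ_v F_v, so a
  sweep costs O(mK + nK).
- **Safeguards.** Entries are projected to a floor of 1e−10 (no edge ever
  has probability exactly 0 during the ascent); edge dot products are
  clamped below at 1e−10 inside the fit; the edge-gradient ratio
  `exp(−d)/(1−exp(−d))` grows like 1/d at that clamp, so gradient
  coordinates are capped at ±1e3 — a positive per-coordinate rescaling
  that preserves the ascent property while preventing one near-orthogonal
  edge from stalling the line search.
- **Initialization and restarts.** Entries uniform in (0, 1/√K] from a
  seeded generator; `n_init = 5` restarts keep the fit with the highest
  final likelihood. The likelihood surface is non-concave and single runs
  at a mismatched K were observed to land in clearly inferior optima
  (hundreds of nats below the best restart); best-of-restarts removes
  most of that variance while remaining deterministic given
  `random_state`.
- **Stopping.** `max_iter = 500` sweeps or relative likelihood
  improvement below `tol = 1e−6`. The tolerance is deliberately tight:
  with batch ascent the per-sweep improvement becomes small relative to
  |L| well before memberships stabilize, and a 500-sweep fit on the
  benchmark costs ~0.3 s per restart.
- **Membership threshold.** `δ = sqrt(−log(1−ε))` with
  `ε = 2m/(n(n−1))` by default — a community weight is kept only when two
  nodes sharing it would be linked more probably than a uniformly random
  pair. δ is configurable; the number of communities K is a required user
  choice (the robustness sweep `tau_vs_K` is provided to justify it).

`log_likelihood` (the public function) is exact and returns −inf when an
edge has probability zero; `row_gradient` matches finite differences of
it (property-tested) away from the clamp.

## Constraint coefficient

Burt's constraint with uniform energy `p_ij = 1/deg(i)`, the common-
neighbor term summed over q adjacent to both endpoints. Degree-0 nodes
get C = 0 by convention (the sum is empty) and are excluded from any
"fast spreader" reading. The implementation is checked exactly against a
naive triple-loop evaluation.

## OC score

`raw_i = Σ_{j∈Γ(i)} Σ_{k∈Γ(j)} 10^(−C_k)·Nb(k)` is read as a sum over
length-2 walks: the endpoint k is counted once per walk i–j–k, including
walks returning to i — no de-duplication, which makes the score
computable as A(A s) with s_k = 10^(−C_k)·Nb(k). Normalization divides
by the network maximum of `raw`, so the top node scores exactly 1; an
all-zero raw vector (edgeless graph) yields all-zero scores. The base 10
in the constraint transform is configurable in principle but fixed at 10
by default. When no node clears the membership threshold every Nb is 0
and the raw scores vanish; `OCRanker` then falls back, explicitly flagged
via `degraded_to_nc_`, to ranking by negated constraint — the documented
"no overlapping communities" degeneration.

## SIR simulation

Synchronous discrete time: each infected node attempts to infect each
currently susceptible neighbor with probability β (independent draws;
simultaneous attempts on one target are each evaluated), then recovers
with probability γ; new infections become infectious the next step. With
γ = 1 every node gets exactly one round of attempts. For γ < 1 a node
that fails to recover keeps attempting with fresh independent draws.
Influence of a node = mean final outbreak size over `reps` runs; the
default β is 1.5× the mean-field threshold ⟨k⟩/⟨k²⟩ — above threshold so
outbreaks differentiate nodes, but not so high that every seed infects
everything. Randomness uses one master seed expanded into independent
`SeedSequence([seed, node, rep])` substreams, so results are independent
of execution order and exactly reproducible; top-k curves use
`[seed, rep]` streams so methods with identical seed sets get identical
trajectories. The simulator is cross-validated against an independently
coded set-based simulator on several fixtures (agreement within
Monte-Carlo error).

## Kendall tau-b

Computed from raw scores (not pre-ranked integers) by O(n²) sign
comparison with explicit tie corrections; tie terms make the two choices
equivalent. A vanishing denominator (an entirely tied list) is reported
as a flagged undefined result, never coerced to 0. The implementation is
exact against brute-force pair enumeration (property-tested with ties)
and against `scipy.stats.kendalltau(variant="b")`.

## Synthetic benchmark

The generator plants an affiliation model: F_uc = w on the planted
memberships, pairs linked with probability `1 − (1−ε)exp(−F_u·F_v)`.
The background rate ε is unioned in because pure disjoint communities
produce disconnected graphs on which spreading-based rankings degenerate.
The default benchmark uses n = 120 nodes in K = 4 equal communities,
15% of nodes additionally joining a second (cyclically adjacent)
community, w = 2, ε = 0.005, seed 42. Influence ground truth on it uses
100 repetitions per seed node — the convention for networks of this size —
at β = 1.5 β_th, γ = 1. These sizes keep the full pipeline (fit +
influence estimation + sweeps) around ten seconds.

What the benchmark emulates: overlapping communities whose overlap nodes
are denser than single-community nodes (verified distributionally), the
regime where community-aware ranking helps. What it does not emulate:
heavy-tailed degree distributions, degree assortativity, local clustering
beyond what the affiliation model induces, or the scale of real social
networks — so a passing benchmark shows internal consistency of the
pipeline and the expected qualitative ordering (OC above degree and
constraint alone), not performance claims transferable to any particular
real network.

## Known limitations

- K must be supplied; no model-selection criterion is built in.
- With K far below the number of planted communities the fitted
  memberships merge groups and Nb loses resolution; the tau-vs-K sweep
  shows visibly lower correlation at such K, which is inherent to the
  score, not an optimizer artifact.
- Betweenness/closeness use exact all-pairs shortest paths (via
  networkx) and are not intended for networks beyond ~10⁴ nodes.
- The SIR simulator is a plain Python loop over infected nodes — ample
  for desk-scale studies (millions of short runs per minute), not for
  million-node graphs.
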