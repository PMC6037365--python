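# ocrank

Ranking influential spreader nodes in complex networks by combining
**overlapping community structure** with **structural holes**.

Many centrality measures (degree, betweenness, k-shell, ...) rank nodes by
raw topology and ignore that real networks organize into overlapping
communities. Nodes sitting in community overlaps act as bridges: anything
they spread reaches several communities at once. `ocrank` implements the
OC score, which quantifies exactly that, together with the full apparatus
needed to evaluate any spreader ranking: eight baseline centralities, a
discrete-time SIR epidemic simulator, Kendall tau-b correlation against
simulated influence, and a planted-community synthetic benchmark. It is
aimed at network scientists and epidemiologists who need reproducible
spreader rankings and a harness to compare them.

## The method

1. **Overlapping communities.** Fit the BIGCLAM affiliation model: a
   nonnegative matrix F ∈ R^(N×K) where F_uc is node u's weight in
   community c, and an edge (u, v) appears with probability
   1 − exp(−F_u · F_v). F is found by projected gradient ascent on the
   log-likelihood

       L(F) = Σ_{(u,v)∈E} log(1 − exp(−F_u·F_v)) − Σ_{(u,v)∉E} F_u·F_v.

   Node u belongs to community c iff F_uc > δ; one node can belong to
   several communities.

2. **Structural holes.** Burt's network constraint coefficient

       C_i = Σ_{j∈Γ(i)} ( p_ij + Σ_{q∈Γ(i)∩Γ(j)} p_iq p_qj )²,  p_ij = 1/deg(i),

   is small for brokers whose contacts are many and mutually unconnected —
   positions that spread information fast.

3. **The OC score.** With Nb(k) = number of distinct communities held by
   k's neighbors (propagation capacity) and 10^(−C_k) rewarding brokerage
   (propagation speed),

       OC_i = ( Σ_{j∈Γ(i)} Σ_{k∈Γ(j)} 10^(−C_k) · Nb(k) ) / maxOC,

   summed over all length-2 walk endpoints and normalized by the network
   maximum, so OC ∈ [0, 1].

Rankings are scored against ground truth from the SIR model: seed one node
infected, infect each susceptible neighbor with probability β per step,
recover with probability γ (γ = 1 by default: one shot to infect); a node's
influence is its mean final outbreak size over repeated simulations, with
β set a little above the epidemic threshold β_th = ⟨k⟩/⟨k²⟩. Agreement
between a centrality ranking and the influence ranking is measured with
tie-corrected Kendall tau-b.

## Worked example

```python
import ocrank as oc

g, truth = oc.planted_benchmark()          # 120 nodes, 4 planted communities
print('n =', g.n, ' m =', g.m)

ranker = oc.OCRanker(n_communities=4, random_state=0).fit(g)
cm = ranker.membership_
print('C =', cm.num_communities, ' MLC =', cm.mlc)

beta = 1.5 * oc.epidemic_threshold(g)
p = oc.SIRParams(beta=beta, gamma=1.0, reps=100, seed=0)
truth_rank = oc.influence_ranking(g, p)

methods = [ranker.scores_, oc.degree_centrality(g), oc.nc_scores(g)]
for name, tr in oc.method_table(g, methods, p, influence=truth_rank).items():
    print(f'tau_{name} = {tr.tau:.3f}')
```

prints

```
n = 120  m = 2268
C = 4  MLC = 2
tau_OC = 0.624
tau_DC = 0.584
tau_NC = 0.603
```

The fit finds the 4 planted communities (C = 4) with nodes in at most two
of them (MLC = 2), and the OC ranking tracks simulated influence more
closely (τ = 0.624) than either of its ingredients alone — degree
(τ = 0.584) or the constraint coefficient (τ = 0.603).

The same pipeline is available from the shell:

```sh
ocrank synth -n 120 -k 4 --seed 42 -o out      # sample a planted graph
ocrank rank out/synthetic_edges.tsv -k 4 -o out     # OC scores + memberships
ocrank evaluate out/synthetic_edges.tsv -k 4 --k-grid 2,3,4,5,6 -o out
```

## Layout

- `ocrank.graph` — undirected simple graph container, edge-list/Pajek IO
- `ocrank.bigclam` — affiliation-model fitting and membership thresholds
- `ocrank.centrality` — constraint coefficient and baseline centralities
- `ocrank.ranking` — Nb counts, OC scores, `OCRanker`
- `ocrank.sir` — SIR simulator, epidemic threshold, influence estimation
- `ocrank.evaluation` — Kendall tau-b and evaluation sweeps
- `ocrank.synthetic` — planted-community generator and toy fixtures
- `ocrank.cli` — `ocrank` command-line entry point

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
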