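"""Centrality baselines and Burt's network constraint coefficient.

All rankers return a :class:`RankScores` with a deterministic total order:
descending score, ties broken by ascending internal node index.  Only the
rank order of these scores enters the downstream tau comparisons, so
normalization choices (unnormalized betweenness, per-component closeness,
unit-sum eigenvector) are rank-invariant conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import Graph

__all__ = [
    "RankScores",
    "constraint",
    "degree_centrality",
    "betweenness",
    "closeness",
    "eigenvector",
    "k_shell",
    "cnc",
    "cnc_plus",
    "nc_scores",
]


@dataclass
class RankScores:
    """Per-node scores for one ranking method plus the induced node order."""

    method: str
    values: np.ndarray
    ranking: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        # descending score, ties by ascending index
        self.ranking = np.lexsort((np.arange(len(self.values)), -self.values))

    def top(self, k: int) -> np.ndarray:
        if k > len(self.values):
            raise ValueError(f"k={k} exceeds n={len(self.values)}")
        return self.ranking[:k]


def constraint(g: Graph) -> np.ndarray:
    """Burt's network constraint coefficient per node.

    C_i = sum_{j in G(i)} ( 1/deg(i) + sum_{q in G(i) & G(j)} (1/deg(i)) (1/deg(q)) )^2

    A node whose contacts are few and mutually connected is highly
    constrained; low constraint marks a brokerage (structural-hole) position.
    Isolated nodes get C_i = 0 by convention (the sum is empty).
    """
    n = g.n
    deg = g.degrees.astype(np.float64)
    out = np.zeros(n)
    inv_deg = np.zeros(n)
    nz = deg > 0
    inv_deg[nz] = 1.0 / deg[nz]
    for i in range(n):
        nbrs_i = g.neighbors(i)
        if len(nbrs_i) == 0:
            continue
        p_i = inv_deg[i]
        total = 0.0
        for j in nbrs_i:
            common = np.intersect1d(nbrs_i, g.neighbors(j), assume_unique=True)
            term = p_i + p_i * inv_deg[common].sum()
            total += term * term
        out[i] = total
    return out


def degree_centrality(g: Graph) -> RankScores:
    return RankScores("DC", g.degrees.astype(np.float64))


def betweenness(g: Graph) -> RankScores:
    """Unnormalized shortest-path betweenness."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return RankScores("BC", np.array([bc[i] for i in range(g.n)]))


def closeness(g: Graph) -> RankScores:
    """Per-component closeness: (n_comp - 1) / sum of distances within the component."""
    cc = nx.closeness_centrality(g.to_networkx(), wf_improved=False)
    return RankScores("CC", np.array([cc[i] for i in range(g.n)]))


def eigenvector(g: Graph, max_iter: int = 10000, tol: float = 1e-10) -> RankScores:
    """Dominant-eigenvector centrality on the largest component, unit-sum scaled.

    Nodes outside the largest connected component score 0.
    """
    vals = np.zeros(g.n)
    if g.m > 0:
        G = g.to_networkx()
        comp = max(nx.connected_components(G), key=len)
        ec = nx.eigenvector_centrality(G.subgraph(comp), max_iter=max_iter, tol=tol)
        for i, v in ec.items():
            vals[i] = v
        vals /= vals.sum()
    return RankScores("EC", vals)


def coreness(g: Graph) -> np.ndarray:
    """Shell index (k-core number) per node from iterative degree pruning."""
    core = nx.core_number(g.to_networkx())
    return np.array([core[i] for i in range(g.n)], dtype=np.float64)


def k_shell(g: Graph) -> RankScores:
    return RankScores("KS", coreness(g))


def cnc(g: Graph) -> RankScores:
    """Neighborhood coreness: Cnc(i) = sum of coreness over i's neighbors."""
    ks = coreness(g)
    vals = np.array([ks[g.neighbors(i)].sum() for i in range(g.n)])
    return RankScores("Cnc", vals)


def cnc_plus(g: Graph) -> RankScores:
    """Extended neighborhood coreness: Cnc+(i) = sum of Cnc over i's neighbors."""
    base = cnc(g).values
    vals = np.array([base[g.neighbors(i)].sum() for i in range(g.n)])
    return RankScores("Cnc+", vals)


def nc_scores(g: Graph) -> RankScores:
    """Network constraint ranking: low constraint (broker) ranks first."""
    return RankScores("NC", -constraint(g))
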