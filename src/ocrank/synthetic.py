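"""Synthetic graphs with planted overlapping communities, plus toy fixtures.

The planted generator samples from the affiliation model: each node gets a
community set, every within-community pair (u, v) is linked with
probability ``1 - exp(-F_u . F_v)`` where ``F_uc = w`` iff ``c`` is in
``u``'s planted set, and a small background probability ``epsilon`` is
unioned in so fixtures stay connected (pure disjoint communities would
yield disconnected components, which makes spreading-based rankings
degenerate).  Nodes planted in two communities accumulate edge probability
to both, so overlap nodes are denser than single-community nodes — the
structural premise the OC ranking relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = [
    "PlantedModel",
    "default_benchmark_model",
    "sample_graph",
    "toy_fixtures",
    "planted_benchmark",
]


@dataclass
class PlantedModel:
    """Planted affiliation model: ``n`` nodes, ``K`` communities, per-node
    planted community sets, within-community weight ``w`` and background
    edge probability ``epsilon``."""

    n: int
    K: int
    membership_plan: list[set[int]]
    weight: float = 2.0
    epsilon: float = 0.005
    seed: int = 42

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        if len(self.membership_plan) != self.n:
            raise ValueError("membership_plan must cover all nodes")
        populated = set().union(*self.membership_plan) if self.membership_plan else set()
        if self.weight > 0 and populated != set(range(self.K)):
            raise ValueError("every planted community must be non-empty")

    def planted_F(self) -> np.ndarray:
        F = np.zeros((self.n, self.K))
        for u, comms in enumerate(self.membership_plan):
            for c in comms:
                F[u, c] = self.weight
        return F


def make_membership_plan(
    n: int, K: int, overlap_fraction: float, rng: np.random.Generator
) -> list[set[int]]:
    """Equal-size base communities; a random ``overlap_fraction`` of nodes
    additionally joins the next community (cyclically)."""
    plan = [{u * K // n} for u in range(n)]
    n_overlap = int(round(overlap_fraction * n))
    for u in rng.choice(n, size=n_overlap, replace=False):
        base = next(iter(plan[u]))
        plan[u].add((base + 1) % K)
    return plan


def default_benchmark_model(seed: int = 42) -> PlantedModel:
    """The default planted benchmark: 120 nodes, 4 communities, 15% of nodes
    overlapping two communities, weight 2, background 0.005."""
    rng = np.random.default_rng(seed)
    n, K = 120, 4
    plan = make_membership_plan(n, K, 0.15, rng)
    return PlantedModel(n=n, K=K, membership_plan=plan, weight=2.0, epsilon=0.005, seed=seed)


def sample_graph(
    model: PlantedModel, rng: np.random.Generator | None = None
) -> tuple[Graph, list[set[int]]]:
    """Sample a graph from the planted model; returns (graph, ground truth).

    Each unordered pair (u, v) is linked with probability
    ``1 - (1 - epsilon) * exp(-F_u . F_v)``.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    F = model.planted_F()
    D = F @ F.T
    iu, jv = np.triu_indices(model.n, k=1)
    p = 1.0 - (1.0 - model.epsilon) * np.exp(-D[iu, jv])
    hit = rng.random(len(p)) < p
    edges = list(zip(iu[hit].tolist(), jv[hit].tolist()))
    g = Graph([str(i) for i in range(model.n)], edges)
    return g, [set(s) for s in model.membership_plan]


def planted_benchmark(seed: int = 42) -> tuple[Graph, list[set[int]]]:
    """Sample the default benchmark (deterministic given the seed)."""
    return sample_graph(default_benchmark_model(seed))


def _clique_edges(nodes: list[int]) -> list[tuple[int, int]]:
    return [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]


def toy_fixtures() -> dict[str, Graph]:
    """Deterministic small graphs used across the test-suite and examples.

    star: center 0 with 4 leaves. ring: 6-cycle. path: a-b-c.
    triangle_pendant: triangle 0-1-2 with leaf 3 on node 0.
    two_clique_bridge: two 6-cliques whose only contact is node 0, a member
    of both. planted_default: the sampled default benchmark graph.
    """
    lab = [str(i) for i in range(13)]
    star = Graph(lab[:5], [(0, i) for i in range(1, 5)])
    ring = Graph(lab[:6], [(i, (i + 1) % 6) for i in range(6)])
    path = Graph(["a", "b", "c"], [(0, 1), (1, 2)])
    tri_pend = Graph(lab[:4], [(0, 1), (1, 2), (0, 2), (0, 3)])
    bridge = Graph(
        lab, _clique_edges([0, 1, 2, 3, 4, 5, 6]) + _clique_edges([0, 7, 8, 9, 10, 11, 12])
    )
    return {
        "star": star,
        "ring": ring,
        "path": path,
        "triangle_pendant": tri_pend,
        "two_clique_bridge": bridge,
        "planted_default": planted_benchmark()[0],
    }
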