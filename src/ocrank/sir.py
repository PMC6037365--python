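"""Discrete-time SIR spreading simulator and Monte-Carlo influence estimation.

Dynamics are synchronous: at each timestep every infected node attempts,
independently with probability ``beta``, to infect each currently
susceptible neighbor; newly infected nodes become infectious the next step;
after attempting, each infected node recovers with probability ``gamma``.
With ``gamma = 1`` a node gets exactly one round of infection attempts.

The influence of a seed node is the mean final outbreak size (recovered
count at absorption) over repeated simulations.  Reproducibility: one
master seed, with an independent substream per (seed-set, repetition), so
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centrality import RankScores
from .graph import Graph, degree_stats

__all__ = [
    "SIRParams",
    "SIRResult",
    "epidemic_threshold",
    "sir_run",
    "influence",
    "influence_ranking",
    "topk_spread_curve",
]


@dataclass
class SIRParams:
    """Epidemic parameters: per-contact infection probability ``beta``,
    per-step recovery probability ``gamma`` (default 1: one shot to infect),
    Monte-Carlo repetitions and master seed."""

    beta: float
    gamma: float = 1.0
    reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class SIRResult:
    """Outcome of one or more runs: cumulative infected-or-recovered counts
    per timestep and the final outbreak size."""

    trajectory: np.ndarray
    final_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=np.int64)
        self.final_size = int(self.trajectory[-1])


def epidemic_threshold(g: Graph) -> float:
    """Heterogeneous mean-field epidemic threshold ``<k> / <k^2>``."""
    if g.m == 0:
        raise ValueError("epidemic threshold undefined for an edgeless graph")
    k1, k2 = degree_stats(g)
    return k1 / k2


def sir_run(g: Graph, seeds, beta: float, gamma: float, rng: np.random.Generator) -> SIRResult:
    """One synchronous SIR realization from the given seed set."""
    seeds = np.asarray(list(seeds), dtype=np.int64)
    if len(seeds) == 0:
        raise ValueError("seed set must be non-empty")
    n = g.n
    # 0 susceptible, 1 infected, 2 recovered
    status = np.zeros(n, dtype=np.int8)
    status[seeds] = 1
    infected = list(np.unique(seeds))
    cum = len(infected)
    traj = [cum]
    while infected:
        newly: list[int] = []
        for u in infected:
            nbrs = g.neighbors(u)
            sus = nbrs[status[nbrs] == 0]
            if len(sus):
                hit = sus[rng.random(len(sus)) < beta]
                for v in hit:
                    if status[v] == 0:
                        status[v] = 3  # infected this step; infectious next step
                        newly.append(int(v))
        recover = rng.random(len(infected)) < gamma
        still = []
        for u, r in zip(infected, recover):
            if r:
                status[u] = 2
            else:
                still.append(u)
        status[status == 3] = 1
        infected = still + newly
        cum += len(newly)
        traj.append(cum)
    return SIRResult(trajectory=np.array(traj))


def _rep_rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def influence(g: Graph, node: int, p: SIRParams) -> tuple[float, float]:
    """Mean and standard error of the final outbreak size seeding from ``node``."""
    sizes = np.empty(p.reps)
    for rep in range(p.reps):
        rng = _rep_rng(p.seed, node, rep)
        sizes[rep] = sir_run(g, [node], p.beta, p.gamma, rng).final_size
    mean = float(sizes.mean())
    stderr = float(sizes.std(ddof=1) / np.sqrt(p.reps)) if p.reps > 1 else 0.0
    return mean, stderr


def influence_ranking(g: Graph, p: SIRParams) -> RankScores:
    """SIR ground-truth ranking: mean final size per single-node seed."""
    means = np.array([influence(g, u, p)[0] for u in range(g.n)])
    return RankScores("SIR", means)


def topk_spread_curve(
    g: Graph, methods: list[RankScores], k: int, p: SIRParams
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean cumulative-infection trajectory (and stderr) seeding each
    method's top-k nodes.

    The random substream depends only on (master seed, repetition), so two
    methods with identical top-k sets produce identical curves.
    """
    if k > g.n:
        raise ValueError(f"k={k} exceeds n={g.n}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rs in methods:
        seeds = rs.top(k)
        trajs = []
        for rep in range(p.reps):
            rng = _rep_rng(p.seed, rep)
            trajs.append(sir_run(g, seeds, p.beta, p.gamma, rng).trajectory)
        tmax = max(len(t) for t in trajs)
        padded = np.array(
            [np.pad(t, (0, tmax - len(t)), mode="edge") for t in trajs], dtype=np.float64
        )
        mean = padded.mean(axis=0)
        stderr = (
            padded.std(axis=0, ddof=1) / np.sqrt(p.reps) if p.reps > 1 else np.zeros(tmax)
        )
        out[rs.method] = (mean, stderr)
    return out
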