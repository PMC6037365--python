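"""Kendall tau-b rank correlation and ranking-evaluation harnesses.

tau-b handles ties explicitly:

    tau = (n_c - n_d) / sqrt((n_t - n_t1)(n_t - n_t2))

with ``n_t = n(n-1)/2`` total pairs, ``n_c``/``n_d`` concordant/discordant
pair counts, and ``n_t1``, ``n_t2`` the tied-pair counts of each list.  A
pair tied in either list is neither concordant nor discordant.  When a list
is entirely tied the denominator vanishes; such results are flagged
undefined rather than coerced to zero.

The harnesses reproduce the standard evaluation designs for spreader
rankings: correlation of each method with SIR influence, sweeps over the
infection and recovery probabilities, restriction to the top-L fraction of
true spreaders, and robustness to the assumed number of communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import RankScores
from .graph import Graph
from .ranking import rank_oc
from .sir import SIRParams, influence_ranking

__all__ = [
    "TauResult",
    "kendall_tau",
    "method_table",
    "tau_vs_beta",
    "tau_vs_gamma",
    "top_L_tau",
    "tau_vs_K",
]


@dataclass
class TauResult:
    tau: float
    n_c: int
    n_d: int
    n_t: int
    n_t1: int
    n_t2: int
    undefined: bool = False


def _tie_pairs(x: np.ndarray) -> int:
    _, counts = np.unique(x, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def kendall_tau(x, y) -> TauResult:
    """Kendall tau-b between two equal-length score lists."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(n, k=1)
    pu = prod[iu]
    n_c = int((pu > 0).sum())
    n_d = int((pu < 0).sum())
    n_t = n * (n - 1) // 2
    n_t1 = _tie_pairs(x)
    n_t2 = _tie_pairs(y)
    denom_sq = (n_t - n_t1) * (n_t - n_t2)
    if denom_sq <= 0:
        return TauResult(float("nan"), n_c, n_d, n_t, n_t1, n_t2, undefined=True)
    tau = (n_c - n_d) / np.sqrt(denom_sq)
    return TauResult(float(tau), n_c, n_d, n_t, n_t1, n_t2)


def method_table(
    g: Graph,
    methods: list[RankScores],
    p: SIRParams,
    influence: RankScores | None = None,
) -> dict[str, TauResult]:
    """tau between each method's scores and SIR mean influence over all nodes.

    ``influence`` may be passed to reuse a precomputed ground-truth ranking.
    """
    if influence is None:
        influence = influence_ranking(g, p)
    return {rs.method: kendall_tau(rs.values, influence.values) for rs in methods}


def _sweep(g, methods, grid, grid_name, make_params) -> pd.DataFrame:
    rows = []
    for val in grid:
        table = method_table(g, methods, make_params(val))
        for name, tr in table.items():
            rows.append(
                {grid_name: val, "method": name, "tau": tr.tau, "undefined": tr.undefined}
            )
    return pd.DataFrame(rows)


def tau_vs_beta(g: Graph, methods: list[RankScores], betas, p: SIRParams) -> pd.DataFrame:
    """tau of each method against SIR influence across infection probabilities.

    The conventional grid spans the epidemic threshold to twice the
    threshold; any grid is accepted.
    """
    return _sweep(
        g, methods, betas, "beta",
        lambda b: SIRParams(beta=b, gamma=p.gamma, reps=p.reps, seed=p.seed),
    )


def tau_vs_gamma(g: Graph, methods: list[RankScores], gammas, p: SIRParams) -> pd.DataFrame:
    """tau of each method across recovery probabilities (typically 0.5 to 1)."""
    return _sweep(
        g, methods, gammas, "gamma",
        lambda gm: SIRParams(beta=p.beta, gamma=gm, reps=p.reps, seed=p.seed),
    )


def top_L_tau(
    g: Graph,
    methods: list[RankScores],
    p: SIRParams,
    L_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    influence: RankScores | None = None,
) -> pd.DataFrame:
    """tau restricted to the top ``ceil(L * n)`` true spreaders for each L.

    The subset is selected by SIR influence order (ties broken by node
    index); at L = 1.0 this coincides with :func:`method_table`.
    """
    if influence is None:
        influence = influence_ranking(g, p)
    rows = []
    for L in L_grid:
        top = influence.ranking[: int(np.ceil(L * g.n))]
        for rs in methods:
            if len(top) < 2:
                rows.append({"L": L, "method": rs.method, "tau": float("nan"), "undefined": True})
                continue
            tr = kendall_tau(rs.values[top], influence.values[top])
            rows.append({"L": L, "method": rs.method, "tau": tr.tau, "undefined": tr.undefined})
    return pd.DataFrame(rows)


def tau_vs_K(
    g: Graph,
    K_grid,
    p: SIRParams,
    seed: int = 0,
    delta: float | str = "auto",
    influence: RankScores | None = None,
) -> tuple[pd.DataFrame, float]:
    """Robustness of the OC ranking to the assumed number of communities.

    Runs the full OC pipeline at each K, correlates with SIR influence, and
    reports the curve plus the max-minus-min fluctuation of tau.
    """
    if influence is None:
        influence = influence_ranking(g, p)
    rows = []
    for K in K_grid:
        if K < 1:
            raise ValueError("community counts must be >= 1")
        rs = rank_oc(g, K, seed=seed, delta=delta)
        tr = kendall_tau(rs.values, influence.values)
        rows.append({"K": K, "tau": tr.tau, "undefined": tr.undefined})
    df = pd.DataFrame(rows)
    defined = df.loc[~df["undefined"], "tau"]
    fluctuation = float(defined.max() - defined.min()) if len(defined) else float("nan")
    return df, fluctuation
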