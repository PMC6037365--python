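"""Affiliation-model community detection (BIGCLAM).

The affiliation graph model assigns each node ``u`` a nonnegative weight
vector ``F_u`` over ``K`` communities; an edge between ``u`` and ``v``
appears with probability ``1 - exp(-F_u . F_v)``.  Fitting maximizes the
log-likelihood

    sum_{(u,v) in E} log(1 - exp(-F_u . F_v)) - sum_{(u,v) not in E} F_u . F_v

over unordered node pairs by projected gradient ascent.  Thresholding the
fitted matrix at ``delta`` gives overlapping community memberships: node
``u`` belongs to community ``c`` iff ``F_uc > delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .graph import Graph

__all__ = [
    "BigClam",
    "CommunityMembership",
    "edge_probability",
    "log_likelihood",
    "row_gradient",
    "fit_affiliations",
    "memberships",
    "auto_delta",
]

# Dot products below this are treated as exactly this in the edge terms, so
# the gradient ratio exp(-d)/(1-exp(-d)) stays finite (~1e10 at the clamp).
_DOT_FLOOR = 1e-10
# Projection floor for entries of F: strictly positive so no edge ever has
# literally zero probability during the ascent.
_ENTRY_FLOOR = 1e-10
# Per-coordinate cap on the fitting gradient (see BigClam.fit).
_GRAD_CAP = 1e3


def edge_probability(fu: np.ndarray, fv: np.ndarray) -> float:
    """Probability ``1 - exp(-<fu, fv>)`` of an edge under the affiliation model."""
    fu = np.asarray(fu, dtype=np.float64)
    fv = np.asarray(fv, dtype=np.float64)
    if fu.shape != fv.shape:
        raise ValueError(f"shape mismatch: {fu.shape} vs {fv.shape}")
    if (fu < 0).any() or (fv < 0).any():
        raise ValueError("affiliation weights must be nonnegative")
    return float(-np.expm1(-float(fu @ fv)))


def log_likelihood(g: Graph, F: np.ndarray) -> float:
    """Model log-likelihood of graph ``g`` given affiliation matrix ``F``.

    Sums run over unordered node pairs.  An edge whose endpoint vectors are
    orthogonal has probability zero; the result is then ``-inf``.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.shape[0] != g.n:
        raise ValueError("F must have one row per node")
    sum_f = F.sum(axis=0)
    # Total dot-product mass over unordered pairs u < v.
    sq = np.einsum("ij,ij->i", F, F)
    total_pairs = (float(sum_f @ sum_f) - float(sq.sum())) / 2.0
    edge_dots = np.array([F[u] @ F[v] for u, v in g.edges()])
    if edge_dots.size and edge_dots.min() <= 0.0:
        return float("-inf")
    edge_term = float(np.log(-np.expm1(-edge_dots)).sum()) if edge_dots.size else 0.0
    nonedge_term = total_pairs - float(edge_dots.sum())
    return edge_term - nonedge_term


def row_gradient(g: Graph, F: np.ndarray, u: int) -> np.ndarray:
    """Gradient of the log-likelihood with respect to row ``F_u``.

    Edge dot products are clamped below at a small floor so the gradient
    stays finite for (near-)orthogonal connected pairs.
    """
    F = np.asarray(F, dtype=np.float64)
    nbrs = g.neighbors(u)
    sum_f = F.sum(axis=0)
    s_nbr = F[nbrs].sum(axis=0) if len(nbrs) else np.zeros(F.shape[1])
    grad = -(sum_f - F[u] - s_nbr)
    if len(nbrs):
        d = np.clip(F[nbrs] @ F[u], _DOT_FLOOR, None)
        ratio = np.exp(-d) / (-np.expm1(-d))
        grad = grad + ratio @ F[nbrs]
    return grad


def auto_delta(g: Graph) -> float:
    """Default membership threshold ``sqrt(-log(1 - eps))``.

    ``eps = 2m / (n(n-1))`` is the background edge density: a community
    weight is kept only if, shared by two nodes, it would make their edge
    more likely than an edge between two random nodes.
    """
    if g.n < 2:
        return 0.0
    eps = 2.0 * g.m / (g.n * (g.n - 1))
    if eps >= 1.0:
        return 0.0
    return math.sqrt(-math.log1p(-eps))


@dataclass
class CommunityMembership:
    """Thresholded overlapping memberships derived from an affiliation matrix."""

    delta: float
    communities: list[set[int]]
    num_communities: int = field(init=False)
    mlc: int = field(init=False)

    def __post_init__(self) -> None:
        nonempty: set[int] = set()
        for s in self.communities:
            nonempty |= s
        self.num_communities = len(nonempty)
        self.mlc = max((len(s) for s in self.communities), default=0)


def memberships(F: np.ndarray, delta: float | str = "auto", g: Graph | None = None) -> CommunityMembership:
    """Threshold ``F`` into per-node community sets: ``c in communities[u]`` iff ``F_uc > delta``.

    With ``delta="auto"`` the graph is required to compute the background
    density rule (:func:`auto_delta`).
    """
    F = np.asarray(F, dtype=np.float64)
    if delta == "auto":
        if g is None:
            raise ValueError('delta="auto" requires the graph')
        delta = auto_delta(g)
    delta = float(delta)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    comms = [set(np.flatnonzero(row > delta).tolist()) for row in F]
    return CommunityMembership(delta=delta, communities=comms)


class BigClam(BaseEstimator):
    """Overlapping community detection by affiliation-matrix maximum likelihood.

    Projected gradient ascent on all rows of ``F`` simultaneously with
    backtracking line search, so the fitted matrix is equivariant under node
    relabeling and the likelihood trace is non-decreasing.

    Parameters
    ----------
    n_communities : int
        Number of communities ``K``.
    delta : float or "auto"
        Membership threshold; "auto" uses the background edge density rule.
    max_iter : int
        Maximum number of full gradient sweeps per restart.
    tol : float
        Relative log-likelihood improvement below which the ascent stops.
    n_init : int
        Number of random restarts; the fit with the highest final
        log-likelihood is kept (the likelihood surface is non-concave and
        restarts are the standard guard against poor local optima).
    random_state : int
        Seed for the uniform ``(0, 1/sqrt(K)]`` initializations; restart
        seeds are derived from it, so the whole fit is deterministic.

    Attributes
    ----------
    F_ : ndarray of shape (n_nodes, n_communities)
        Fitted nonnegative affiliation matrix.
    log_likelihood_ : float
        Log-likelihood at the final iterate.
    log_likelihood_trace_ : ndarray
        Log-likelihood after each accepted sweep (non-decreasing).
    membership_ : CommunityMembership
        Thresholded overlapping memberships.
    n_iter_ : int
        Number of sweeps performed.
    """

    def __init__(
        self,
        n_communities: int = 2,
        delta: float | str = "auto",
        max_iter: int = 500,
        tol: float = 1e-6,
        n_init: int = 5,
        random_state: int = 0,
    ):
        self.n_communities = n_communities
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, g: Graph, y=None, F_init: np.ndarray | None = None) -> "BigClam":
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if g.m == 0:
            raise ValueError("cannot fit an edgeless graph (likelihood trivially maximized at 0)")
        n, K = g.n, self.n_communities
        A = g.adjacency_csr()
        edges = np.array(list(g.edges()), dtype=np.int64)
        eu, ev = edges[:, 0], edges[:, 1]

        def loglik(F: np.ndarray) -> float:
            sum_f = F.sum(axis=0)
            sq = np.einsum("ij,ij->i", F, F)
            total_pairs = (float(sum_f @ sum_f) - float(sq.sum())) / 2.0
            d = np.clip(np.einsum("ij,ij->i", F[eu], F[ev]), _DOT_FLOOR, None)
            return float(np.log(-np.expm1(-d)).sum()) - (total_pairs - float(d.sum()))

        def gradient(F: np.ndarray) -> np.ndarray:
            sum_f = F.sum(axis=0)
            d = np.clip(np.einsum("ij,ij->i", F[eu], F[ev]), _DOT_FLOOR, None)
            w = np.exp(-d) / (-np.expm1(-d))
            Aw = sparse.csr_matrix((w, (eu, ev)), shape=(n, n))
            Aw = Aw + Aw.T
            # edge term + correction removing neighbors from the non-edge sum
            grad = Aw @ F + A @ F - sum_f[None, :] + F
            # Edges between currently near-orthogonal rows make w blow up
            # (~1/d at the clamp); cap coordinates so one pathological term
            # cannot dominate the step.  A per-coordinate positive rescaling
            # keeps the direction an ascent direction.
            return np.clip(grad, -_GRAD_CAP, _GRAD_CAP)

        def ascend(F: np.ndarray):
            ll = loglik(F)
            trace = [ll]
            step = 1.0
            n_iter = 0
            armijo = 0.05
            for n_iter in range(1, self.max_iter + 1):
                grad = gradient(F)
                accepted = False
                t = step * 2.0
                for _ in range(40):
                    F_new = np.maximum(F + t * grad, _ENTRY_FLOOR)
                    ll_new = loglik(F_new)
                    # Armijo sufficient increase along the projected step
                    if ll_new >= ll + armijo * float(np.sum(grad * (F_new - F))):
                        accepted = True
                        break
                    t *= 0.5
                if not accepted:
                    break
                improved = ll_new - ll
                F, ll, step = F_new, ll_new, t
                trace.append(ll)
                if improved <= self.tol * max(1.0, abs(ll)):
                    break
            return F, ll, np.array(trace), n_iter

        if F_init is not None:
            F0 = np.array(F_init, dtype=np.float64)
            if F0.shape != (n, K):
                raise ValueError("F_init has wrong shape")
            inits = [F0]
        else:
            rng = np.random.default_rng(self.random_state)
            # Uniform in (0, 1/sqrt(K)]
            inits = [
                (1.0 - rng.random((n, K))) / math.sqrt(K) for _ in range(self.n_init)
            ]

        best = None
        for F0 in inits:
            result = ascend(F0)
            if best is None or result[1] > best[1]:
                best = result
        F, ll, trace, n_iter = best

        self.F_ = F
        self.log_likelihood_ = ll
        self.log_likelihood_trace_ = trace
        self.n_iter_ = n_iter
        self.membership_ = memberships(F, self.delta, g=g)
        return self

    def fit_transform(self, g: Graph, y=None) -> np.ndarray:
        """Fit and return the affiliation matrix ``F_``."""
        return self.fit(g).F_


def write_affiliations(F: np.ndarray, path, labels: list[str] | None = None) -> None:
    """Write F as TSV: one row per node, header of community ids."""
    F = np.asarray(F, dtype=np.float64)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\t" + "\t".join(str(c) for c in range(F.shape[1])) + "\n")
        for i, row in enumerate(F):
            lab = labels[i] if labels is not None else str(i)
            fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def write_memberships(cm: CommunityMembership, path, labels: list[str] | None = None) -> None:
    """Write memberships as TSV: label, comma-separated community ids."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(cm.communities):
            lab = labels[i] if labels is not None else str(i)
            fh.write(f"{lab}\t{','.join(map(str, sorted(s)))}\n")


def fit_affiliations(
    g: Graph,
    K: int,
    seed: int = 0,
    max_iters: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Functional wrapper: fit the affiliation model and return ``F``."""
    return BigClam(
        n_communities=K, max_iter=max_iters, tol=tol, random_state=seed
    ).fit(g).F_
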