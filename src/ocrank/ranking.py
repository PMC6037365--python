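"""The OC influential-spreader score.

OC combines two node properties derived from overlapping communities and
structural holes:

* ``Nb(k)`` — the number of distinct communities represented among node
  ``k``'s neighbors, a proxy for how many communities ``k`` can reach
  (propagation capacity);
* ``10^(-C_k)`` — a decreasing transform of Burt's constraint coefficient,
  so brokers (low constraint) contribute more (propagation speed).

The unnormalized score of node ``i`` sums ``10^(-C_k) * Nb(k)`` over all
length-2 walk endpoints ``k`` (each walk i-j-k counted once, ``k = i``
allowed), and is divided by the network maximum so scores lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .bigclam import BigClam, CommunityMembership
from .centrality import RankScores, constraint, nc_scores
from .graph import Graph

__all__ = ["OCScoreTable", "OCRanker", "nb_counts", "oc_scores", "rank_oc"]


@dataclass
class OCScoreTable:
    """Per-node Nb counts, raw and normalized OC scores."""

    nb: np.ndarray
    raw: np.ndarray
    max_oc: float = field(init=False)
    oc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.max_oc = float(self.raw.max()) if len(self.raw) else 0.0
        self.oc = self.raw / self.max_oc if self.max_oc > 0 else np.zeros_like(self.raw)


def nb_counts(g: Graph, cm: CommunityMembership) -> np.ndarray:
    """Number of distinct communities held by each node's neighbors.

    ``Nb(k) = | union_{j in G(k)} communities[j] |``.  Node ``k``'s own
    memberships enter only if a neighbor shares them; an isolated node has
    ``Nb = 0``.
    """
    if len(cm.communities) != g.n:
        raise ValueError("membership does not cover all nodes")
    out = np.zeros(g.n, dtype=np.int64)
    for k in range(g.n):
        union: set[int] = set()
        for j in g.neighbors(k):
            union |= cm.communities[j]
        out[k] = len(union)
    return out


def oc_scores(g: Graph, C: np.ndarray, nb: np.ndarray) -> OCScoreTable:
    """Evaluate the OC score given constraint values and Nb counts.

    raw_i = sum_{j in G(i)} sum_{k in G(j)} 10^(-C_k) * Nb(k)

    The inner sum runs over the multiset of second-hop endpoints: ``k`` is
    counted once per walk i-j-k, including walks returning to ``i``.
    """
    C = np.asarray(C, dtype=np.float64)
    nb = np.asarray(nb, dtype=np.float64)
    if (C < 0).any():
        raise ValueError("constraint values must be nonnegative")
    s = np.power(10.0, -C) * nb
    A = g.adjacency_csr()
    raw = A @ (A @ s)
    return OCScoreTable(nb=nb.astype(np.int64), raw=raw)


class OCRanker(BaseEstimator):
    """End-to-end OC ranking of influential spreaders.

    Fitting runs the three-stage pipeline: detect overlapping communities
    with the affiliation model, compute the network constraint coefficient,
    then combine them into the normalized OC score.

    Parameters
    ----------
    n_communities : int
        Number of communities ``K`` for the affiliation-model fit.
    delta : float or "auto"
        Membership threshold passed to :class:`~ocrank.bigclam.BigClam`.
    max_iter, tol : see :class:`~ocrank.bigclam.BigClam`.
    random_state : int
        Seed; the whole pipeline is deterministic given it.

    Attributes
    ----------
    scores_ : RankScores
        Normalized OC scores with the induced deterministic ranking.
    table_ : OCScoreTable
        Nb counts, raw sums and normalization factor.
    constraint_ : ndarray
        Per-node constraint coefficients.
    membership_ : CommunityMembership
        Thresholded communities from the affiliation fit.
    degraded_to_nc_ : bool
        True when no node cleared the membership threshold (all Nb = 0);
        the ranking then falls back to the negated constraint coefficient,
        honoring the intent that without communities OC reduces to the
        structural-hole ranking.
    """

    def __init__(
        self,
        n_communities: int = 2,
        delta: float | str = "auto",
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_communities = n_communities
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, g: Graph, y=None) -> "OCRanker":
        bc = BigClam(
            n_communities=self.n_communities,
            delta=self.delta,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(g)
        self.bigclam_ = bc
        self.membership_ = bc.membership_
        self.constraint_ = constraint(g)
        nb = nb_counts(g, bc.membership_)
        self.table_ = oc_scores(g, self.constraint_, nb)
        self.degraded_to_nc_ = bool((nb == 0).all())
        if self.degraded_to_nc_:
            self.scores_ = RankScores("OC", nc_scores(g).values)
        else:
            self.scores_ = RankScores("OC", self.table_.oc)
        return self

    def fit_predict(self, g: Graph, y=None) -> np.ndarray:
        """Fit and return the node order, most influential first."""
        return self.fit(g).scores_.ranking


def rank_oc(
    g: Graph,
    K: int,
    seed: int = 0,
    delta: float | str = "auto",
    max_iters: int = 500,
    tol: float = 1e-6,
) -> RankScores:
    """Functional wrapper around :class:`OCRanker`."""
    return OCRanker(
        n_communities=K, delta=delta, max_iter=max_iters, tol=tol, random_state=seed
    ).fit(g).scores_
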