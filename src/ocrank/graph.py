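"""Undirected simple graph container and plain-text readers/writers.

Graphs are stored with contiguous internal indices ``0..n-1`` in CSR-like
arrays; original node labels are kept as opaque strings.  All inputs are
coerced to undirected simple graphs: self-loops and duplicate edges are
silently dropped and counted in a load report.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "read_edge_list",
    "read_pajek",
    "write_edge_list",
    "degree_stats",
]


class Graph:
    """Undirected simple graph with string labels and integer indices.

    Parameters
    ----------
    labels : sequence of str
        Original node identifiers; position defines the internal index.
    edges : iterable of (int, int)
        Edges as index pairs.  Self-loops and duplicates are dropped and
        recorded in :attr:`load_report`.
    """

    __slots__ = ("labels", "indptr", "indices", "m", "load_report")

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[int, int]]):
        self.labels: list[str] = [str(x) for x in labels]
        n = len(self.labels)
        seen: set[tuple[int, int]] = set()
        n_loops = 0
        n_dups = 0
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) out of range for n={n}")
            if u == v:
                n_loops += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in seen:
            adj[u].append(v)
            adj[v].append(u)
        degs = np.array([len(a) for a in adj], dtype=np.int64)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(degs, out=self.indptr[1:])
        self.indices = np.empty(int(self.indptr[-1]), dtype=np.int64)
        for i, a in enumerate(adj):
            a.sort()
            self.indices[self.indptr[i]: self.indptr[i + 1]] = a
        self.m = len(seen)
        self.load_report = {"self_loops_dropped": n_loops, "duplicates_dropped": n_dups}

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Per-node sorted arrays of neighbor indices."""
        return [self.neighbors(i) for i in range(self.n)]

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]: self.indptr[i + 1]]

    def edges(self) -> Iterable[tuple[int, int]]:
        """Yield each undirected edge once as (u, v) with u < v."""
        for u in range(self.n):
            for v in self.neighbors(u):
                if u < v:
                    yield u, int(v)

    def has_edge(self, u: int, v: int) -> bool:
        nb = self.neighbors(u)
        pos = np.searchsorted(nb, v)
        return pos < len(nb) and nb[pos] == v

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def adjacency_csr(self):
        """Adjacency as a scipy CSR matrix (0/1, symmetric)."""
        from scipy import sparse

        data = np.ones(len(self.indices), dtype=np.float64)
        return sparse.csr_matrix(
            (data, self.indices, self.indptr), shape=(self.n, self.n)
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_labeled_edges(
        cls, pairs: Iterable[tuple[str, str]], extra_labels: Iterable[str] = ()
    ) -> "Graph":
        """Build a graph from label pairs; indices assigned by first appearance."""
        index: dict[str, int] = {}
        labels: list[str] = []

        def idx(lab: str) -> int:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            return index[lab]

        edges = [(idx(a), idx(b)) for a, b in pairs]
        for lab in extra_labels:
            idx(lab)
        return cls(labels, edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n}, m={self.m})"


def read_edge_list(path: str | os.PathLike, comment_prefix: str = "#") -> Graph:
    """Read a whitespace-delimited edge list.

    Each non-comment line carries at least two tokens (extra tokens, e.g.
    weights, are ignored).  Duplicate edges and self-loops are dropped and
    counted in the returned graph's ``load_report``.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 tokens, got {len(toks)}")
            pairs.append((toks[0], toks[1]))
    return Graph.from_labeled_edges(pairs)


def read_pajek(path: str | os.PathLike) -> Graph:
    """Read a Pajek-style .net file (*Vertices / *Edges sections)."""
    labels: dict[int, str] = {}
    pairs: list[tuple[str, str]] = []
    section = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                section = "edges"
                continue
            if low.startswith("*"):
                section = None
                continue
            toks = line.split()
            if section == "vertices":
                vid = int(toks[0])
                lab = toks[1].strip('"') if len(toks) > 1 else str(vid)
                labels[vid] = lab
            elif section == "edges":
                if len(toks) < 2:
                    raise ValueError(f"{path}: line {lineno}: bad edge line")
                a, b = int(toks[0]), int(toks[1])
                pairs.append((labels.get(a, str(a)), labels.get(b, str(b))))
    return Graph.from_labeled_edges(pairs, extra_labels=labels.values())


def write_edge_list(g: Graph, path: str | os.PathLike) -> None:
    """Write one line per undirected edge using original labels."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in g.edges():
            fh.write(f"{g.labels[u]}\t{g.labels[v]}\n")


def degree_stats(g: Graph) -> tuple[float, float]:
    """Return (<k>, <k^2>): mean degree and mean squared degree."""
    if g.n == 0:
        raise ValueError("degree_stats undefined for the empty graph")
    d = g.degrees.astype(np.float64)
    return float(d.mean()), float((d**2).mean())
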