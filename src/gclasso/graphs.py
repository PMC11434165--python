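"""Predictor graphs and their Laplacians.

Auxiliary information about the predictors of a linear model — e.g. which
genes are connected in a KEGG pathway — enters the model through an
undirected weighted graph over the p predictor columns.  This module builds
the combinatorial graph Laplacian

    L[u, u] = d_u = sum of weights of edges at u,
    L[u, v] = -w(u, v) for edges u ~ v,  0 otherwise,

and the per-node neighborhoods D_j = {k : L[j, k] != 0, k != j} that the
node-wise precision regressions are restricted to.

The order of the design matrix's columns is canonical: edge lists are
mapped onto it by label, in whatever order the rows arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import InputError

__all__ = [
    "PredictorGraph",
    "LaplacianMatrix",
    "Neighborhoods",
    "build_laplacian",
    "neighborhoods",
]


@dataclass
class PredictorGraph:
    """Undirected weighted graph over named predictors.

    Nodes are predictor names in design-column order; the edge container is
    a :class:`networkx.Graph`.  Duplicate edges in the input have their
    weights summed (pathway exports commonly repeat edges); zero-weight
    edges are dropped so that graph neighborhoods coincide with the nonzero
    off-diagonal pattern of the Laplacian.
    """

    node_labels: list[str]
    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        node_labels: Sequence[str],
        edges: Iterable[tuple],
    ) -> "PredictorGraph":
        """Build a graph from (u, v) or (u, v, weight) tuples.

        Raises
        ------
        InputError
            On unknown labels, self loops, or negative weights.
        """
        labels = [str(x) for x in node_labels]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate predictor labels")
        known = set(labels)
        g = nx.Graph()
        g.add_nodes_from(labels)
        for row in edges:
            if len(row) == 2:
                u, v, w = str(row[0]), str(row[1]), 1.0
            elif len(row) == 3:
                u, v = str(row[0]), str(row[1])
                try:
                    w = float(row[2])
                except (TypeError, ValueError) as exc:
                    raise InputError(f"non-numeric edge weight in {row!r}") from exc
            else:
                raise InputError(f"edge rows need 2 or 3 fields, got {row!r}")
            if u not in known or v not in known:
                raise InputError(f"edge ({u}, {v}) references unknown predictor")
            if u == v:
                raise InputError(f"self loop on node {u!r} not allowed")
            if w < 0:
                raise InputError(f"negative weight {w} on edge ({u}, {v})")
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
        # zero-weight edges (possibly from summed zeros) would put k into D_j
        # while L[j, k] == 0; drop them
        dead = [(u, v) for u, v, w in g.edges(data="weight") if w == 0]
        g.remove_edges_from(dead)
        return cls(node_labels=labels, graph=g)

    @classmethod
    def empty(cls, node_labels: Sequence[str]) -> "PredictorGraph":
        return cls.from_edges(node_labels, [])

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_weights(self) -> dict[frozenset, float]:
        return {
            frozenset((u, v)): w for u, v, w in self.graph.edges(data="weight")
        }


@dataclass
class LaplacianMatrix:
    """Combinatorial Laplacian L with node degrees.

    Symmetric PSD with zero row sums; the all-ones vector spans part of its
    null space.  A square-root factor Q with L = Q.T @ Q (rows = nonzero
    eigendirections) is computed lazily and cached, since the penalized fit
    reuses it across many calls on the same graph.
    """

    matrix: np.ndarray
    degrees: np.ndarray
    _sqrt_factor: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def sqrt_factor(self) -> np.ndarray:
        """An m x p matrix Q with Q.T @ Q = L, m = rank(L).

        Built from the eigendecomposition, keeping only strictly positive
        eigenvalues; for sparse pathway graphs m is typically much smaller
        than p, which keeps the augmented design small.
        """
        if self._sqrt_factor is None:
            w, v = np.linalg.eigh(self.matrix)
            keep = w > 1e-10 * max(w[-1], 1.0)
            self._sqrt_factor = np.sqrt(w[keep])[:, None] * v[:, keep].T
        return self._sqrt_factor


@dataclass
class Neighborhoods:
    """Graph neighborhoods D_j of each predictor, with sizes d_j and d."""

    sets: list[np.ndarray]
    d_j: np.ndarray
    d: int


def build_laplacian(graph: PredictorGraph) -> LaplacianMatrix:
    """Assemble the combinatorial Laplacian of a predictor graph."""
    p = graph.p
    L = np.zeros((p, p))
    index = {lab: i for i, lab in enumerate(graph.node_labels)}
    for u, v, w in graph.graph.edges(data="weight"):
        i, j = index[u], index[v]
        L[i, j] -= w
        L[j, i] -= w
        L[i, i] += w
        L[j, j] += w
    return LaplacianMatrix(matrix=L, degrees=np.diag(L).copy())


def neighborhoods(L: LaplacianMatrix) -> Neighborhoods:
    """Nonzero off-diagonal pattern of L, row by row."""
    p = L.p
    sets = []
    for j in range(p):
        row = L.matrix[j].copy()
        row[j] = 0.0
        sets.append(np.flatnonzero(row != 0))
    d_j = np.array([len(s) for s in sets])
    return Neighborhoods(sets=sets, d_j=d_j, d=int(d_j.max()) if p else 0)
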