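"""Global clustering coefficient of an undirected simple graph.

The coefficient is computed from powers of the adjacency matrix G:

    phi = trace(G^3) / (||G^2|| - trace(G^2)),

where ``||.||`` sums all matrix entries.  trace(G^3) is six times the number
of triangles and ||G^2|| - trace(G^2) is twice the number of connected triples
(open and closed), so phi is the usual "transitivity" of the graph.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence, Union

import networkx as nx
import numpy as np

from .params import ValidationError

__all__ = ["clustering_coefficient", "read_edge_list"]

GraphLike = Union[nx.Graph, np.ndarray, Sequence[tuple[int, int]], str, os.PathLike]


def read_edge_list(path: Union[str, os.PathLike]) -> nx.Graph:
    """Read a whitespace-separated, 0-based integer edge list into a graph.

    Duplicate edges and self-loops are rejected: the formula assumes a simple
    undirected graph.  Blank lines and ``#`` comments are ignored.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected two node indices, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer node index in {line!r}") from exc
            if u < 0 or v < 0:
                raise ValidationError(f"{path}:{lineno}: node indices must be >= 0")
            if u == v:
                raise ValidationError(f"{path}:{lineno}: self-loop at node {u}")
            if graph.has_edge(u, v):
                raise ValidationError(f"{path}:{lineno}: duplicate edge ({u}, {v})")
            graph.add_edge(u, v)
    return graph


def _as_adjacency(graph: GraphLike) -> np.ndarray:
    if isinstance(graph, (str, os.PathLike)):
        graph = read_edge_list(graph)
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, dtype=float)
    arr = np.asarray(graph, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and arr.shape[0] > 2:
        return arr
    if arr.ndim == 2 and arr.shape[1] == 2:
        # edge list as an array of pairs
        g = nx.Graph()
        g.add_edges_from((int(u), int(v)) for u, v in arr)
        return nx.to_numpy_array(g, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        return arr
    raise ValidationError("graph must be a networkx Graph, square 0/1 adjacency matrix, edge list or path")


def clustering_coefficient(graph: GraphLike) -> float:
    """Global clustering coefficient (transitivity) of an undirected graph.

    Parameters
    ----------
    graph
        A :class:`networkx.Graph`, a symmetric 0/1 adjacency matrix with zero
        diagonal, an iterable of integer edge pairs, or a path to an edge-list
        file (see :func:`read_edge_list`).

    Returns
    -------
    float
        trace(G^3) / (||G^2|| - trace(G^2)) in [0, 1].

    Raises
    ------
    ValidationError
        If the adjacency matrix is asymmetric, has self-loops or non-binary
        entries, or if the graph contains no connected triple at all (the
        denominator vanishes and phi is undefined).
    """
    G = _as_adjacency(graph)
    if G.shape[0] != G.shape[1]:
        raise ValidationError("adjacency matrix must be square")
    if np.any(np.diag(G) != 0):
        raise ValidationError("adjacency matrix must have zero diagonal (no self-loops)")
    if not np.array_equal(G, G.T):
        raise ValidationError("adjacency matrix must be symmetric (undirected graph)")
    if not np.all(np.isin(G, (0.0, 1.0))):
        raise ValidationError("adjacency matrix entries must be 0 or 1")
    G2 = G @ G
    G3 = G2 @ G
    closed = np.trace(G3)  # 6 x number of triangles
    triples = G2.sum() - np.trace(G2)  # 2 x number of triples
    if triples <= 0:
        raise ValidationError("graph has no connected triples; clustering coefficient undefined")
    return float(closed / triples)
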