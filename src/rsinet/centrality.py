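"""Node centrality indices on the weighted partial-correlation network.

Strength is the sum of absolute incident edge weights — the primary
importance index here, since a high-Strength item has strong direct
associations with many other items. Closeness and Betweenness are
shortest-path indices computed on edge lengths 1/|w| (stronger association
= shorter distance), the convention of the network-psychometrics ecosystem:
closeness is the inverse of the total distance from a node to all others,
betweenness the (tie-splitting) count of geodesics passing through a node.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd


def _check_w(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.abs(np.diag(W)).max() > 1e-12:
        raise ValueError("W must have a zero diagonal")
    return W


def _graph(W: np.ndarray) -> nx.Graph:
    """Weighted graph over nonzero edges, with length = 1/|w|."""
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(i, j, weight=W[i, j], length=1.0 / abs(W[i, j]))
    return G


def strength(W: np.ndarray, node: int | None = None):
    """Sum of absolute incident edge weights, per node or for one node."""
    W = _check_w(W)
    s = np.abs(W).sum(axis=1)
    return s if node is None else float(s[node])


def closeness(W: np.ndarray, node: int | None = None):
    """1 / (total shortest-path distance to all other nodes); 0 if any
    node is unreachable (disconnection convention)."""
    W = _check_w(W)
    G = _graph(W)
    p = W.shape[0]
    out = np.zeros(p)
    for v in range(p):
        dist = nx.single_source_dijkstra_path_length(G, v, weight="length")
        if len(dist) < p:  # some node unreachable
            out[v] = 0.0
        else:
            total = sum(d for u, d in dist.items() if u != v)
            out[v] = 1.0 / total if total > 0 else 0.0
    return out if node is None else float(out[node])


def betweenness(W: np.ndarray, node: int | None = None):
    """Number of shortest s-t paths through each node (Brandes, unordered
    pairs, tied geodesics split equally), with edge length 1/|w|."""
    W = _check_w(W)
    G = _graph(W)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    out = np.array([bc[v] for v in range(W.shape[0])])
    return out if node is None else float(out[node])


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def centrality_table(
    W: np.ndarray,
    node_labels=None,
    network_id: str = "network",
) -> pd.DataFrame:
    """Strength/Closeness/Betweenness per node, raw and min-max rescaled.

    The rescaled columns put the most important node at 1 and the least at
    0 (the presentation scale); group comparisons operate on the raw
    values. When all nodes are tied the rescaled value is 0 for every node.
    """
    W = _check_w(W)
    p = W.shape[0]
    labels = list(node_labels) if node_labels is not None else [
        f"Q{i + 1}" for i in range(p)
    ]
    s, c, b = strength(W), closeness(W), betweenness(W)
    return pd.DataFrame(
        {
            "network_id": network_id,
            "node": labels,
            "strength": s,
            "closeness": c,
            "betweenness": b,
            "strength_scaled": _minmax(s),
            "closeness_scaled": _minmax(c),
            "betweenness_scaled": _minmax(b),
        }
    )
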