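"""Interaction-network topology and the hub-gene screen.

Nodes of the DEG interaction network are scored by four topological
indices: degree (direct neighbors), shortest-path betweenness
(sum over unordered node pairs s,t of the fraction of s-t shortest paths
through v, endpoints excluded, unnormalized), eigenvector centrality
(principal adjacency eigenvector, unit Euclidean norm, non-negative) and
eccentricity centrality (reciprocal of the longest shortest path to any
reachable node). The hub screen takes the top ``n_degree`` nodes by
degree, ranks those by eigenvector centrality and by betweenness, and
intersects the two top-``n_secondary`` lists — the surviving nodes are
the hub genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["centralities", "hub_screen", "degree_filter", "HubScreenResult"]


def _eigenvector_power(g: nx.Graph, nodes: list, tol: float = 1e-10,
                       max_iter: int = 10_000) -> np.ndarray:
    """Non-negative principal adjacency eigenvector, unit Euclidean norm."""
    A = nx.to_numpy_array(g, nodelist=nodes)
    n = A.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    if not A.any():
        return x  # edgeless graph: uniform by convention
    # iterate on A + I: same eigenvectors, but the Perron root is strictly
    # dominant, so bipartite graphs (eigenvalues +-lambda) cannot oscillate
    A = A + np.eye(n)
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x, lam = y, norm
            break
        x, lam = y, norm
    x = np.abs(x)
    nrm = np.linalg.norm(x)
    return x / nrm if nrm > 0 else x


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Topological score table for every node of an undirected simple graph.

    Returns a DataFrame indexed by node with columns ``degree``,
    ``betweenness``, ``eigenvector`` and ``eccentricity_centrality``.
    On disconnected graphs, betweenness skips unreachable pairs and
    eccentricity uses only reachable peers (isolated node -> 0).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(u == v for u, v in g.edges()):
        raise ValueError("graph must be simple (self-loop found)")
    nodes = list(g.nodes())

    degree = dict(g.degree())
    betw = nx.betweenness_centrality(g, normalized=False)
    eig = _eigenvector_power(g, nodes)

    ecc = {}
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        reach = [d for w, d in dist.items() if w != v]
        ecc[v] = 1.0 / max(reach) if reach else 0.0

    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betw[v] for v in nodes],
            "eigenvector": eig,
            "eccentricity_centrality": [ecc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass(frozen=True)
class HubScreenResult:
    """Hub screen outcome plus the audit trail of the ranked lists."""

    hub_ids: frozenset
    top_degree: list
    top_secondary_a: list  # eigenvector (or chosen secondary metric)
    top_secondary_b: list  # betweenness
    tie_warning: bool


def _top(table: pd.DataFrame, metric: str, n: int) -> tuple[list, bool]:
    """First ``n`` nodes by decreasing metric; ties by node id (lexicographic).

    Flags whether the cut falls inside a tie (the 'first n' is then a
    convention, not forced by the data).
    """
    ordered = (
        table.assign(_id=table.index.astype(str))
        .sort_values(by=[metric, "_id"], ascending=[False, True], kind="stable")
        .drop(columns="_id")
    )
    picked = list(ordered.index[:n])
    tie = False
    if len(ordered) > n:
        boundary = ordered[metric].iloc[n - 1]
        tie = bool(ordered[metric].iloc[n] == boundary)
    return picked, tie


def hub_screen(
    table: pd.DataFrame,
    n_degree: int = 40,
    n_secondary: int = 20,
    secondary: str = "eigenvector",
) -> HubScreenResult:
    """Top-``n_degree``-by-degree, then top-``n_secondary`` by the secondary
    metric and by betweenness; hubs are the intersection of the two lists.

    ``secondary`` defaults to eigenvector centrality (the ranking actually
    used for the reported screen); ``eccentricity_centrality`` is accepted
    for the variant defined in the methods.
    """
    if n_secondary > n_degree:
        raise ValueError("n_secondary cannot exceed n_degree")
    if len(table) < n_degree:
        raise ValueError(f"need at least {n_degree} nodes, got {len(table)}")
    if secondary not in ("eigenvector", "eccentricity_centrality"):
        raise ValueError("secondary metric must be eigenvector or eccentricity_centrality")

    top_deg, tie_d = _top(table, "degree", n_degree)
    sub = table.loc[top_deg]
    top_a, tie_a = _top(sub, secondary, n_secondary)
    top_b, tie_b = _top(sub, "betweenness", n_secondary)
    return HubScreenResult(
        hub_ids=frozenset(top_a) & frozenset(top_b),
        top_degree=top_deg,
        top_secondary_a=top_a,
        top_secondary_b=top_b,
        tie_warning=tie_d or tie_a or tie_b,
    )


def degree_filter(table: pd.DataFrame, min_degree: int = 30) -> set:
    """Nodes whose degree strictly exceeds ``min_degree``."""
    if table.empty:
        return set()
    return set(table.index[table["degree"] > min_degree])
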