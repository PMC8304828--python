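"""Gene-interaction graph filtering, clustering and path reporting.

Edges come from a local interaction-score table with per-channel
confidence scores in [0, 1] (``coexpression``, ``experimental``,
``combined``).  Tables exported on the common 0-1000 integer scale are
normalized on read.  An edge is kept when *any* of the requested
evidence channels reaches the minimum score; the resulting graph is
clustered by k-means on a spectral embedding, and candidate-to-known
gene connections are reported as unweighted shortest paths.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

CHANNELS = ("coexpression", "experimental", "combined")
EDGE_COLUMNS = ("gene_a", "gene_b") + CHANNELS


def normalize_scores(edges: pd.DataFrame) -> pd.DataFrame:
    """Bring channel scores onto [0, 1], dividing by 1000 when needed."""
    edges = edges.copy()
    present = [c for c in CHANNELS if c in edges.columns]
    if not present:
        raise ValueError(f"edge table has none of the channels {CHANNELS}")
    if max(edges[c].max() for c in present) > 1.0:
        for c in present:
            edges[c] = edges[c] / 1000.0
    for c in present:
        if (edges[c] < 0).any() or (edges[c] > 1).any():
            raise ValueError(f"channel {c!r} scores outside [0, 1] after normalization")
    return edges


def filter_edges(
    edges: pd.DataFrame,
    min_score: float = 0.15,
    channels=("coexpression", "experimental"),
    seed_genes=(),
) -> nx.Graph:
    """Build the graph of edges whose score clears ``min_score``.

    An edge survives when ANY named channel is at least ``min_score``
    (an interaction supported by coexpression evidence alone is as
    admissible as an experimentally validated one).  Nodes are the
    endpoints of surviving edges plus any explicitly seeded genes,
    which may end up isolated.
    """
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}; expected one of {CHANNELS}")
    edges = normalize_scores(edges)
    g = nx.Graph()
    g.add_nodes_from(map(str, seed_genes))
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            raise ValueError(f"self-interaction for {a!r}")
        scores = {ch: float(getattr(row, ch)) for ch in CHANNELS
                  if hasattr(row, ch)}
        if any(scores.get(ch, 0.0) >= min_score for ch in channels):
            g.add_edge(a, b, **scores)
    return g


def cluster_kmeans(graph: nx.Graph, k: int = 3, seed: int = 0) -> dict[str, int]:
    """Partition nodes into ``k`` groups by spectral embedding + k-means.

    Nodes are embedded with the leading ``k`` eigenvectors of the
    symmetric-normalized adjacency matrix (D^-1/2 A D^-1/2); k-means
    with a fixed seed and 10 restarts assigns clusters.  Deterministic
    for a given seed.  Cluster ids are relabelled so that the first
    node in alphabetical order gets cluster 0, the next new cluster 1,
    and so on.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes())
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds node count {len(nodes)}")
    if k == 1:
        return {n: 0 for n in nodes}

    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    sym = d_isqrt[:, None] * a * d_isqrt[None, :]
    vals, vecs = np.linalg.eigh(sym)
    embedding = vecs[:, np.argsort(vals)[::-1][:k]]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(embedding)

    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for node, lab in zip(nodes, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out[node] = relabel[lab]
    return out


def path(graph: nx.Graph, a: str, b: str) -> list[str] | None:
    """Shortest path from ``a`` to ``b`` by edge count, or None.

    Breadth-first search expanding neighbors in alphabetical order, so
    among equal-length paths the lexicographically earliest is
    returned; ``None`` when the endpoints are disconnected.
    """
    for node in (a, b):
        if node not in graph:
            raise ValueError(f"node {node!r} not in graph")
    if a == b:
        return [a]
    parent: dict[str, str] = {a: a}
    queue = deque([a])
    while queue:
        u = queue.popleft()
        for v in sorted(graph.neighbors(u)):
            if v in parent:
                continue
            parent[v] = u
            if v == b:
                out = [v]
                while out[-1] != a:
                    out.append(parent[out[-1]])
                return out[::-1]
            queue.append(v)
    return None


def clusters_frame(assignment: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(assignment.items()), columns=["gene", "cluster"]
    )
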