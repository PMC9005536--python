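"""Co-abundance network of deregressed host genomic effects.

Nodes are microbial traits; edges connect traits whose deregressed GEBVs
have a Pearson correlation above a threshold (0.70 by default, signed — an
absolute-value mode is available). Low-degree nodes are removed, edges are
pruned by a k-nearest-neighbour ranking keeping the top 80 %, and the graph
is clustered with the Markov Clustering algorithm (flow expansion +
inflation) with a minimum cluster granularity of 2 nodes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_graph", "prune_knn_edges", "mcl_cluster", "write_graph"]


def build_graph(
    dgebv: pd.DataFrame,
    threshold: float = 0.70,
    min_degree: int = 2,
    use_abs: bool = False,
    two_core: bool = False,
) -> nx.Graph:
    """Threshold the Pearson correlation matrix of dGEBV columns into a graph.

    Edges require r > threshold (|r| > threshold with ``use_abs``). Nodes
    with degree < ``min_degree`` are removed in one pass, then nodes left
    isolated by that pass are dropped; ``two_core`` iterates the degree
    filter to a fixed point instead. Constant columns are excluded up front.
    """
    if dgebv.shape[1] < 3:
        raise ValueError("need at least 3 traits to build a network")
    variances = dgebv.var(axis=0)
    constant = variances[variances == 0].index
    if len(constant):
        warnings.warn(f"constant dGEBV column(s) excluded: {list(constant)}")
        dgebv = dgebv.drop(columns=constant)
    corr = dgebv.corr().to_numpy()
    names = list(dgebv.columns)
    g = nx.Graph()
    g.add_nodes_from(names)
    strength = np.abs(corr) if use_abs else corr
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if strength[i, j] > threshold:
                g.add_edge(names[i], names[j], weight=float(corr[i, j]))
    if two_core:
        while True:
            low = [v for v, deg in g.degree if deg < min_degree]
            if not low:
                break
            g.remove_nodes_from(low)
    else:
        low = [v for v, deg in g.degree if deg < min_degree]
        g.remove_nodes_from(low)
        g.remove_nodes_from([v for v, deg in g.degree if deg == 0])
    return g


def prune_knn_edges(g: nx.Graph, keep_fraction: float = 0.80, k: int = 10) -> nx.Graph:
    """Rank edges by a k-nearest-neighbour criterion and keep the top fraction.

    Each node marks its k strongest incident edges (by |weight|) as
    preferred; edges are ranked by (number of endpoints preferring them,
    |weight|) and the globally top ``keep_fraction`` are retained. Every kept
    edge therefore ranks at or above every dropped edge.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    edges = list(g.edges(data="weight"))
    if keep_fraction == 1 or not edges:
        return g.copy()
    preferred: dict[tuple, int] = {}
    for node in g.nodes:
        inc = sorted(g.edges(node, data="weight"),
                     key=lambda e: abs(e[2]), reverse=True)[:k]
        for u, v, _ in inc:
            key = (u, v) if u <= v else (v, u)
            preferred[key] = preferred.get(key, 0) + 1
    ranked = sorted(
        edges,
        key=lambda e: (preferred.get((min(e[0], e[1]), max(e[0], e[1])), 0),
                       abs(e[2])),
        reverse=True,
    )
    n_keep = int(np.floor(keep_fraction * len(edges) + 1e-9))
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    for u, v, w in ranked[:n_keep]:
        out.add_edge(u, v, weight=w)
    return out


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    min_cluster_size: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[nx.Graph, dict]:
    """Markov Clustering by alternating flow expansion and inflation.

    The weighted adjacency matrix (|weights|) gets self-loops with loop
    weight equal to each node's maximum incident weight (standard MCL
    regularisation), is column-normalized, then iterated: matrix power
    ``expansion``, elementwise power ``inflation``, renormalize, prune tiny
    entries — until the maximum change falls below ``tol``. Clusters are read
    off the attractor rows of the converged matrix; clusters smaller than
    ``min_cluster_size`` are dissolved to unclustered (label -1).

    Returns the graph with a ``cluster`` node attribute and a dict
    node -> cluster label. Non-convergence yields a warning and the partial
    result.
    """
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, w in g.edges(data="weight", default=1.0):
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = abs(w)
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < 1e-12] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations; "
                      "returning partial clustering")

    # attractors are nodes with flow on their own row; each attractor row
    # spans one cluster; overlapping rows are merged
    attractors = np.where(np.diag(m) > 1e-8)[0]
    clusters: list[set] = []
    for a in attractors:
        members = set(np.where(m[a] > 1e-8)[0]) | {a}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    assigned = set()
    labels = {}
    label = 0
    for c in sorted(clusters, key=len, reverse=True):
        c = c - assigned
        if len(c) >= min_cluster_size:
            for i in c:
                labels[nodes[i]] = label
            assigned |= c
            label += 1
    for v in nodes:
        labels.setdefault(v, -1)
    nx.set_node_attributes(g, labels, "cluster")
    return g, labels


def write_graph(g: nx.Graph, graphml_path=None, edgelist_path=None,
                clusters_path=None) -> None:
    """Persist the graph as GraphML and/or an edge-list TSV plus cluster TSV."""
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        pd.DataFrame(
            [(u, v, w) for u, v, w in g.edges(data="weight", default=np.nan)],
            columns=["node_a", "node_b", "weight"],
        ).to_csv(edgelist_path, sep="\t", index=False)
    if clusters_path is not None:
        labels = nx.get_node_attributes(g, "cluster")
        pd.Series(labels, name="cluster").rename_axis("node").to_csv(
            clusters_path, sep="\t"
        )
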