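"""Spearman correlation networks over model-selected metabolites.

Edges are pairwise Spearman correlations whose Bonferroni-adjusted P-values
(denominator = number of feature pairs tested) pass a threshold (default
0.01); edge weight is |rho| with the sign kept as an attribute. Node
importance is unnormalized shortest-path betweenness centrality and the
display layout is Fruchterman-Reingold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

__all__ = [
    "build_network",
    "betweenness_centrality",
    "layout_fr",
    "export_edge_list",
    "export_node_table",
]


def build_network(
    X_sel, threshold: float = 0.01, labels: dict | None = None
) -> nx.Graph:
    """Bonferroni-thresholded Spearman correlation graph.

    ``X_sel`` is samples x features. Every node carries a ``label``
    (membership tag from ``labels``, default 'none'); every edge carries
    ``weight`` (=|rho|), ``rho``, ``sign`` and ``p_adj``.
    """
    Xf = X_sel if isinstance(X_sel, pd.DataFrame) else pd.DataFrame(np.asarray(X_sel, float))
    m = Xf.shape[1]
    if m < 2:
        raise ValueError("need at least 2 features to build a network")
    features = [str(c) for c in Xf.columns]
    g = nx.Graph()
    for f in features:
        g.add_node(f, label=(labels or {}).get(f, "none"))
    n_pairs = m * (m - 1) // 2
    vals = Xf.to_numpy(float)
    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = vals[:, i], vals[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            rho, p = stats.spearmanr(xi, xj)
            p_adj = min(1.0, p * n_pairs)
            if p_adj <= threshold:
                g.add_edge(
                    features[i], features[j],
                    weight=float(abs(rho)), rho=float(rho),
                    sign=int(np.sign(rho)), p_adj=float(p_adj),
                )
    return g


def betweenness_centrality(graph: nx.Graph, weighted: bool = False) -> dict[str, float]:
    """Unnormalized betweenness; with ``weighted=True`` shortest paths use
    distance 1/|rho|."""
    if graph.number_of_nodes() == 0:
        return {}
    if weighted:
        for _, _, d in graph.edges(data=True):
            d["distance"] = 1.0 / max(d["weight"], 1e-12)
        return nx.betweenness_centrality(graph, normalized=False, weight="distance")
    return nx.betweenness_centrality(graph, normalized=False)


def layout_fr(graph: nx.Graph, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Seeded Fruchterman-Reingold (spring) layout; a single node sits at the
    origin."""
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): (0.0, 0.0)}
    pos = nx.spring_layout(graph, seed=seed)
    return {n: (float(xy[0]), float(xy[1])) for n, xy in pos.items()}


def export_edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p_adj": d["p_adj"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj"])


def export_node_table(
    graph: nx.Graph, layout: dict | None = None, betweenness: dict | None = None
) -> pd.DataFrame:
    betweenness = betweenness or betweenness_centrality(graph)
    layout = layout or layout_fr(graph)
    rows = [
        {
            "id": n,
            "label": graph.nodes[n].get("label", "none"),
            "betweenness": betweenness.get(n, 0.0),
            "x": layout.get(n, (np.nan, np.nan))[0],
            "y": layout.get(n, (np.nan, np.nan))[1],
        }
        for n in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["id", "label", "betweenness", "x", "y"])
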