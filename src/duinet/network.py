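"""Interactome integration: edge enrichment, components, node metrics.

The differentially expressed (DE) and convergently evolving (CE) gene
sets are projected onto a scored protein-protein interaction network
(edges below the medium-confidence score 0.400 are dropped at load).  The
number of edges inside a node set is compared with uniformly resampled
node sets of the same size; the induced subgraph is decomposed into
connected components; and per-node Degree, Stress and neighborhood
connectivity are contrasted between groups with Wilcoxon rank-sum and
Kolmogorov-Smirnov tests.

Stress centrality is Shimbel stress: the number of shortest paths between
unordered node pairs (s, t), s != v != t, passing through v, counting all
co-optimal paths.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_interactome",
    "edge_enrichment",
    "components",
    "node_metrics",
    "stress_centrality",
    "compare_groups",
]

MIN_SCORE = 0.400


def load_interactome(path, min_score: float = MIN_SCORE) -> nx.Graph:
    """Edge-list TSV (node_a, node_b, score); keeps edges with
    score >= min_score, drops self-loops and duplicate edges."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        a, b, w = row["node_a"], row["node_b"], float(row["score"])
        if a == b or w < min_score:
            continue
        g.add_edge(a, b, score=w)
    return g


def edge_enrichment(
    graph: nx.Graph,
    node_set: Iterable,
    n_resample: int = 999,
    seed: int = 0,
) -> dict:
    """Observed vs resampled induced edge count for a node set.

    ``expected`` is the mean induced edge count over uniformly drawn node
    sets of equal size; ``p = (1 + #{null >= observed}) / (n_resample+1)``.
    """
    node_set = set(node_set)
    missing = node_set - set(graph.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)[:5]}")
    if len(node_set) < 2:
        warnings.warn("node set smaller than 2: no edges possible")
        return {"observed": 0, "expected": 0.0, "p": 1.0, "n_resample": n_resample}
    observed = graph.subgraph(node_set).number_of_edges()

    nodes = sorted(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    rng = np.random.default_rng(seed)
    k = len(node_set)
    null = np.empty(n_resample)
    for i in range(n_resample):
        idx = rng.choice(len(nodes), size=k, replace=False)
        null[i] = adj[np.ix_(idx, idx)].sum() / 2.0
    p = (1.0 + np.sum(null >= observed)) / (n_resample + 1.0)
    return {
        "observed": int(observed),
        "expected": float(null.mean()),
        "p": float(p),
        "n_resample": n_resample,
    }


def components(
    graph: nx.Graph, node_set: Iterable | None = None
) -> tuple[list[set], set]:
    """Connected components of the induced subgraph, largest first.

    Isolated nodes (degree zero in the induced subgraph) are reported
    separately, not as singleton components.
    """
    sub = graph if node_set is None else graph.subgraph(set(node_set))
    isolated = {n for n in sub.nodes if sub.degree(n) == 0}
    comps = [
        set(c)
        for c in nx.connected_components(sub)
        if len(c) > 1
    ]
    comps.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return comps, isolated


def stress_centrality(graph: nx.Graph) -> dict:
    """Shimbel stress: co-optimal shortest paths through each node.

    All-pairs BFS with path counting; pairs are unordered and every
    distinct shortest path is counted once.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = [sorted(index[u] for u in graph.neighbors(v)) for v in nodes]
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if np.isinf(dist[s, u]):
                        dist[s, u] = d + 1
                        nxt.append(u)
                    if dist[s, u] == d + 1:
                        sigma[s, u] += sigma[s, v]
            frontier = nxt
            d += 1
    stress = {}
    for vi, v in enumerate(nodes):
        on_path = (dist[:, vi][:, None] + dist[vi, :][None, :]) == dist
        contrib = sigma[:, vi][:, None] * sigma[vi, :][None, :] * on_path
        contrib[vi, :] = 0.0
        contrib[:, vi] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = float(contrib.sum() / 2.0)
    return stress


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, Stress, neighborhood connectivity per node.

    Neighborhood connectivity is the mean degree of a node's neighbors
    (NaN for isolated nodes).
    """
    deg = dict(graph.degree)
    stress = stress_centrality(graph)
    nc = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        nc[v] = float(np.mean([deg[u] for u in nbrs])) if nbrs else np.nan
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "stress": [stress[v] for v in nodes],
            "neighborhood_connectivity": [nc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def compare_groups(
    metrics: pd.DataFrame,
    group_labels: Mapping,
    tests: Sequence[str] = ("wilcoxon", "ks"),
) -> pd.DataFrame:
    """Two-sided group contrasts of each metric.

    ``group_labels`` maps node -> group; exactly two groups must be
    present among the metrics' index.  Reports the p-value per metric and
    test plus the sign of the median difference (first group minus
    second, by sorted group name).
    """
    labels = pd.Series(
        {n: group_labels[n] for n in metrics.index if n in group_labels}
    )
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    rows = []
    for metric in metrics.columns:
        xa = metrics.loc[labels[labels == ga].index, metric].dropna()
        xb = metrics.loc[labels[labels == gb].index, metric].dropna()
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"empty group for metric {metric}")
        if min(len(xa), len(xb)) < 3:
            warnings.warn(
                f"group of size < 3 for {metric}: small-sample p-values",
                stacklevel=2,
            )
        med_diff = float(xa.median() - xb.median())
        for test in tests:
            if test == "wilcoxon":
                # method="auto" uses the exact distribution at small n
                # without ties and the normal approximation otherwise
                _, p = stats.mannwhitneyu(
                    xa, xb, alternative="two-sided", method="auto"
                )
            elif test == "ks":
                _, p = stats.ks_2samp(xa, xb)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {
                    "metric": metric,
                    "test": test,
                    "p": float(p),
                    "median_diff": med_diff,
                    "higher_group": ga if med_diff > 0 else (gb if med_diff < 0 else "tie"),
                }
            )
    return pd.DataFrame(rows)
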