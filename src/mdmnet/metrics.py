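"""Node centralities, edge composition and hub-removal fragmentation.

Conventions match the igraph functions the field uses for these graphs:
degree is the incident-edge count; betweenness is the unnormalized sum
of shortest-path fractions through a node (endpoints excluded);
closeness is ``1 / sum(d(v, u))`` over nodes reachable from ``v``
(computed within each connected component, undefined for isolated
nodes); the hub score is the principal eigenvector of the adjacency
matrix scaled so its maximum entry is 1 (hub == authority on an
undirected graph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .inference import CooccurrenceNetwork

__all__ = [
    "CentralityTable",
    "EdgeComposition",
    "centralities",
    "hub_scores",
    "edge_composition",
    "within_class_enrichment",
    "hub_removal_fragmentation",
    "write_centrality_tsv",
]


@dataclass
class CentralityTable:
    """Per-node centralities for one network.

    ``table`` is indexed by node id with columns ``degree``,
    ``betweenness``, ``closeness`` (NaN for isolated nodes) and
    ``hub_score``.
    """

    table: pd.DataFrame
    network: CooccurrenceNetwork

    def metric(self, name: str) -> pd.Series:
        return self.table[name]

    def split_by_unknown(self, metric: str, rank: str) -> tuple[pd.Series, pd.Series]:
        """(known_values, unknown_values) of ``metric`` at ``rank``."""
        flags = self.network.unknown_flags(rank).reindex(self.table.index)
        vals = self.table[metric]
        return vals[~flags], vals[flags]


def hub_scores(graph: nx.Graph, tol: float = 1e-10, max_iter: int = 2000) -> pd.Series:
    """Kleinberg hub score by power iteration on the adjacency matrix.

    The all-ones start vector converges to the principal eigenvector for
    any graph with at least one edge; if the iteration fails to settle
    (e.g. oscillation on degenerate spectra) a dense symmetric
    eigensolver is used instead.  Scores are scaled to max 1; an
    edgeless graph gets all-zero scores.
    """
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        return pd.Series(0.0, index=nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)  # unweighted
    x = np.ones(len(nodes))
    converged = False
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            converged = True
            break
        x = y
    if not converged:
        eigvals, eigvecs = np.linalg.eigh(a)
        x = np.abs(eigvecs[:, np.argmax(eigvals)])
    x = np.abs(x)
    return pd.Series(x / x.max(), index=nodes)


def centralities(net: CooccurrenceNetwork) -> CentralityTable:
    """Degree, betweenness, closeness and hub score for every node."""
    if not net.nodes:
        raise ValueError("empty graph")
    g = net.to_networkx()
    degree = pd.Series(dict(g.degree()), dtype=float)
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=False))
    closeness = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        total = sum(lengths.values())  # own distance is 0
        closeness[node] = 1.0 / total if total > 0 else np.nan
    hub = hub_scores(g)
    table = pd.DataFrame(
        {
            "degree": degree,
            "betweenness": betweenness,
            "closeness": pd.Series(closeness),
            "hub_score": hub,
        }
    ).loc[net.nodes]
    return CentralityTable(table, net)


@dataclass
class EdgeComposition:
    """Edge counts by endpoint Known/Unknown status and by class pair."""

    kk: int
    ku: int
    uu: int
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.kk + self.ku + self.uu


def edge_composition(net: CooccurrenceNetwork, rank: str) -> EdgeComposition:
    """Classify every edge as K-K, K-U or U-U at ``rank``.

    Also tallies edges per (label, label) pair at that rank, with
    Unknown endpoints collapsed under the label ``"Unknown"`` - the data
    behind per-class co-occurrence bar graphs.
    """
    flags = net.unknown_flags(rank)
    labels = net.labels(rank)
    kk = ku = uu = 0
    pair_counts: dict[tuple[str, str], int] = {}
    for a, b in net.edges:
        fa, fb = bool(flags[a]), bool(flags[b])
        if fa and fb:
            uu += 1
        elif fa or fb:
            ku += 1
        else:
            kk += 1
        key = tuple(sorted((labels[a], labels[b])))
        pair_counts[key] = pair_counts.get(key, 0) + 1
    return EdgeComposition(kk, ku, uu, pair_counts)


def within_class_enrichment(
    net: CooccurrenceNetwork,
    rank: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of within-class edge frequency per class.

    For each class (rank label, Unknowns as one class) with >= 2 nodes,
    the observed fraction of its incident edges that stay within the
    class is compared to a null built by shuffling node labels with the
    graph fixed; ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.  Classes
    with fewer than 2 nodes are excluded (noted in the ``note`` column).
    """
    labels = net.labels(rank)
    classes = sorted(labels.unique())
    if not classes:
        raise ValueError("graph has no nodes")
    edges = list(net.edges)
    rng = np.random.default_rng(seed)

    def fractions(lab: pd.Series) -> dict[str, float]:
        within: dict[str, int] = {}
        incident: dict[str, int] = {}
        for a, b in edges:
            la, lb = lab[a], lab[b]
            incident[la] = incident.get(la, 0) + 1
            if lb != la:
                incident[lb] = incident.get(lb, 0) + 1
            else:
                within[la] = within.get(la, 0) + 1
        return {
            c: (within.get(c, 0) / incident[c]) if incident.get(c) else np.nan
            for c in classes
        }

    observed = fractions(labels)
    counts = labels.value_counts()
    exceed = {c: 0 for c in classes}
    values = labels.to_numpy().copy()
    index = labels.index
    for _ in range(n_perm):
        rng.shuffle(values)
        perm = pd.Series(values, index=index)
        frac = fractions(perm)
        for c in classes:
            if not np.isnan(observed.get(c, np.nan)) and not np.isnan(frac.get(c, np.nan)):
                if frac[c] >= observed[c] - 1e-12:
                    exceed[c] += 1
    rows = []
    for c in classes:
        if counts.get(c, 0) < 2:
            rows.append((c, counts.get(c, 0), np.nan, np.nan, "excluded: <2 nodes"))
            continue
        obs = observed[c]
        if np.isnan(obs):
            rows.append((c, counts[c], np.nan, np.nan, "no incident edges"))
            continue
        p = (1 + exceed[c]) / (n_perm + 1)
        if len(classes) == 1:
            p = 1.0
        rows.append((c, counts[c], obs, p, ""))
    return pd.DataFrame(
        rows, columns=["class", "n_nodes", "within_fraction", "p_value", "note"]
    )


def hub_removal_fragmentation(
    net: CooccurrenceNetwork, nodes_to_remove: Sequence[str]
) -> pd.DataFrame:
    """Fragmentation curve under successive node deletions.

    After each removal (simple subgraph deletion, no re-inference) the
    number of connected components, the size of the largest component
    and the remaining edge count are recorded.
    """
    g = net.to_networkx()
    missing = [n for n in nodes_to_remove if n not in g]
    if missing:
        raise KeyError(f"nodes not in network: {missing}")
    rows = []
    for i, node in enumerate(nodes_to_remove, start=1):
        g.remove_node(node)
        comps = list(nx.connected_components(g)) if g.number_of_nodes() else []
        rows.append(
            {
                "n_removed": i,
                "removed": node,
                "n_components": len(comps),
                "largest_component": max((len(c) for c in comps), default=0),
                "n_edges": g.number_of_edges(),
            }
        )
    return pd.DataFrame(rows)


def write_centrality_tsv(
    cent: CentralityTable, path, rank: str = "genus", header_lines: Sequence[str] = ()
) -> None:
    flags = cent.network.unknown_flags(rank)
    labels = cent.network.labels(rank)
    df = cent.table.copy()
    df.insert(0, "label", labels.reindex(df.index))
    df.insert(1, "unknown", flags.reindex(df.index).astype(int))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="otu_id", float_format="%.10g")
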