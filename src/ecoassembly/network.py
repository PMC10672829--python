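"""Co-occurrence network construction and the topology-metric panel.

Networks are built per sample group from filtered OTU relative abundances:
all pairwise Spearman correlations are computed, p-values are adjusted with
Benjamini-Hochberg across every tested pair of the network, and edges are
kept where |r| > 0.6 and adjusted p < 0.05 (both configurable). The topology
panel reports nodes, edges, average degree, transitivity, mean local
clustering, average path length and diameter (largest component), greedy
modularity, density, and the percentage of positive edges.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable, ValidationError


def filter_otus(table: OtuTable, min_relative_abundance: float = 0.001) -> OtuTable:
    """Keep OTUs whose share of all reads in the sample set exceeds the
    threshold (default 0.1%)."""
    totals = table.counts.sum(axis=0)
    share = totals / totals.sum()
    keep = share.index[share > min_relative_abundance]
    if len(keep) == 0:
        raise ValidationError(
            f"no OTU exceeds total relative abundance {min_relative_abundance:g}; "
            "lower the threshold")
    return OtuTable(table.counts[keep])


@dataclass
class EdgeCandidates:
    """All surviving correlation edges plus bookkeeping counts."""

    edges: pd.DataFrame  # otu_a, otu_b, spearman_r, p_value, q_value, sign
    n_tested: int
    n_constant_excluded: int


def correlation_edges(
    table: OtuTable,
    r_threshold: float = 0.6,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> EdgeCandidates:
    """Spearman correlations between all OTU pairs with BH-FDR filtering.

    Correlations are computed on relative abundances. Pairs involving a
    constant OTU (undefined rank correlation) are excluded and counted. BH
    adjustment spans all tested pairs of this network; set
    ``use_adjusted=False`` to threshold on raw p-values instead.
    """
    if table.shape[0] < 5:
        raise ValidationError("need at least 5 samples for rank correlations")
    if table.shape[1] < 2:
        raise ValidationError("need at least 2 OTUs")
    rel = table.relative_abundance()
    data = rel.to_numpy()
    otus = table.otu_ids
    variable = data.std(axis=0) > 0
    n_constant = int((~variable).sum())
    idx = np.flatnonzero(variable)
    if idx.size < 2:
        return EdgeCandidates(
            pd.DataFrame(columns=["otu_a", "otu_b", "spearman_r", "p_value", "q_value", "sign"]),
            0, n_constant)
    sub = data[:, idx]
    if idx.size == 2:  # spearmanr returns scalars for two columns
        r2, p2 = sps.spearmanr(sub[:, 0], sub[:, 1])
        rmat = np.array([[1.0, r2], [r2, 1.0]])
        pmat = np.array([[0.0, p2], [p2, 0.0]])
    else:
        rmat, pmat = sps.spearmanr(sub)
    iu, ju = np.triu_indices(idx.size, k=1)
    r = rmat[iu, ju]
    p = pmat[iu, ju]
    q = multipletests(p, method="fdr_bh")[1]
    crit = q if use_adjusted else p
    keep = (np.abs(r) > r_threshold) & (crit < alpha)
    edges = pd.DataFrame(
        {
            "otu_a": [otus[idx[i]] for i in iu[keep]],
            "otu_b": [otus[idx[j]] for j in ju[keep]],
            "spearman_r": r[keep],
            "p_value": p[keep],
            "q_value": q[keep],
            "sign": np.where(r[keep] > 0, "positive", "negative"),
        }
    )
    return EdgeCandidates(edges=edges, n_tested=int(r.size), n_constant_excluded=n_constant)


def build_network(
    candidates: EdgeCandidates | pd.DataFrame,
    table: OtuTable | None = None,
    phylum: dict[str, str] | None = None,
) -> nx.Graph:
    """Assemble the simple undirected co-occurrence graph.

    Nodes are OTUs with at least one surviving edge; duplicate pairs and
    self-loops are dropped. Node attributes carry mean relative abundance
    (when the source table is given) and an optional phylum annotation.
    """
    edges = candidates.edges if isinstance(candidates, EdgeCandidates) else candidates
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.otu_a == row.otu_b:
            continue
        graph.add_edge(
            row.otu_a, row.otu_b,
            weight=float(row.spearman_r),
            q_value=float(getattr(row, "q_value", np.nan)),
            sign=row.sign,
        )
    mean_rel = None
    if table is not None:
        mean_rel = table.relative_abundance().mean(axis=0)
    for node in graph.nodes:
        graph.nodes[node]["phylum"] = (phylum or {}).get(node, "unknown")
        if mean_rel is not None and node in mean_rel.index:
            graph.nodes[node]["mean_relative_abundance"] = float(mean_rel[node])
    return graph


@dataclass
class TopologySummary:
    """The network topology panel, in the conventional reporting order."""

    nodes: int
    edges: int
    average_degree: float
    average_transitivity: float
    average_clustering_coefficient: float
    average_path_length: float
    diameter: float
    modularity: float
    graph_density: float
    positive_relationship_pct: float
    connected: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{f.name: getattr(self, f.name) for f in fields(self)}])


def topology(graph: nx.Graph, modularity_seed: int = 0) -> TopologySummary:
    """Compute the topology panel for one co-occurrence network.

    Path length and diameter are evaluated on the largest connected
    component (flagged via ``connected``); modularity scores the partition
    found by greedy modularity maximisation, which is deterministic — the
    seed is accepted for interface stability.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, *(float("nan"),) * 8, connected=True)
    avg_degree = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    transitivity = nx.transitivity(graph)
    clustering = nx.average_clustering(graph)
    components = list(nx.connected_components(graph))
    giant = graph.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        apl, diam = float("nan"), float("nan")
    if e > 0:
        communities = nx.community.greedy_modularity_communities(graph)
        mod = nx.community.modularity(graph, communities)
        pos = sum(1 for _, _, d in graph.edges(data=True) if d.get("weight", 0) > 0)
        pos_pct = 100.0 * pos / e
    else:
        mod, pos_pct = float("nan"), float("nan")
    return TopologySummary(
        nodes=n,
        edges=e,
        average_degree=avg_degree,
        average_transitivity=transitivity,
        average_clustering_coefficient=clustering,
        average_path_length=apl,
        diameter=diam,
        modularity=mod,
        graph_density=density,
        positive_relationship_pct=pos_pct,
        connected=len(components) == 1,
    )


def keystone_nodes(graph: nx.Graph, top_fraction: float = 0.01) -> list[str]:
    """Nodes in the top fraction by degree — a reporting convention only."""
    if graph.number_of_nodes() == 0:
        return []
    k = max(1, int(np.ceil(top_fraction * graph.number_of_nodes())))
    ranked = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return [node for node, _ in ranked[:k]]
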