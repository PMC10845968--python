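"""Spearman co-occurrence network construction and the centrality-threshold
hub (core) microbiome classifier.

Edges connect taxon pairs whose tie-corrected Spearman correlation across
samples is strong (|rho| > 0.6) and significant (P < 0.05, two-sided t
approximation), the screening rule used for genus co-occurrence networks.
Hub taxa are nodes strictly exceeding degree centrality 0.2, closeness
centrality 0.35 and betweenness centrality 0.35 simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import EXACT_PERM_MAX_N, spearman_with_p
from .io import AbundanceTable, relative_abundance


@dataclass
class EdgeRule:
    """Correlation screening rule: |rho| > rho_threshold and p < p_threshold."""

    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    fdr: bool = False  # Benjamini-Hochberg across pairs before screening

    def __post_init__(self):
        if not 0 < self.rho_threshold < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("thresholds must lie in (0,1)")


@dataclass
class HubRule:
    """Centrality thresholds defining the hub microbiome (all strict)."""

    degree_centrality_min: float = 0.2
    closeness_min: float = 0.35
    betweenness_min: float = 0.35

    def __post_init__(self):
        for v in (self.degree_centrality_min, self.closeness_min, self.betweenness_min):
            if not 0 < v < 1:
                raise ValueError("hub thresholds must lie in (0,1)")


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    avgK: float
    avgCC: float
    avg_path: float
    modularity: float
    pct_positive_edges: float
    pct_negative_edges: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def spearman_matrix(
    table: AbundanceTable, min_prevalence: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tie-corrected Spearman rho and two-sided p over taxa.

    Computed on per-sample relative abundances, restricted to taxa present
    in at least ``min_prevalence`` samples.  Constant vectors yield NaN
    (recorded as missing, never an edge).
    """
    if len(table.sample_ids) < 4:
        raise ValueError("Spearman screening needs at least 4 samples")
    prevalent = (table.counts > 0).sum(axis=0) >= min_prevalence
    taxa = list(prevalent.index[prevalent])
    if len(taxa) < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence filter")
    rel = relative_abundance(table)[taxa].to_numpy()
    n = rel.shape[0]
    if n <= EXACT_PERM_MAX_N:
        # small designs: exact permutation p per pair
        k = len(taxa)
        rho = np.eye(k)
        p = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                r_ij, p_ij = spearman_with_p(rel[:, i], rel[:, j])
                rho[i, j] = rho[j, i] = r_ij
                p[i, j] = p[j, i] = p_ij
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns produce NaN rho
            rho, p = stats.spearmanr(rel, axis=0)
        if np.ndim(rho) == 0:  # exactly two taxa: scipy returns scalars
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


def build_network(
    rho: pd.DataFrame, p: pd.DataFrame, rule: EdgeRule = EdgeRule()
) -> nx.Graph:
    """Screen taxon pairs into an undirected signed graph.

    Edge iff |rho| > rho_threshold and p < p_threshold; isolated taxa are
    excluded (nodes are the endpoints of surviving edges).
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices are not aligned")
    taxa = list(rho.index)
    pvals = p.to_numpy().copy()
    if rule.fdr:
        iu = np.triu_indices(len(taxa), k=1)
        flat = pvals[iu]
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
        pvals[iu] = adj
        pvals[(iu[1], iu[0])] = adj
    g = nx.Graph()
    r = rho.to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            rij, pij = r[i, j], pvals[i, j]
            if np.isnan(rij) or np.isnan(pij):
                continue
            if abs(rij) > rule.rho_threshold and pij < rule.p_threshold:
                g.add_edge(
                    taxa[i], taxa[j], rho=float(rij), p=float(pij),
                    sign=1 if rij > 0 else -1,
                )
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per node.

    Degree centrality k/(N-1); betweenness normalized by (N-1)(N-2)/2;
    closeness with the Wasserman-Faust within-component scaling, matching
    Gephi's conventions on disconnected graphs.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("centralities need at least 2 nodes")
    deg = nx.degree_centrality(net)
    btw = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net, wf_improved=True)
    return pd.DataFrame(
        {
            "degree_centrality": pd.Series(deg),
            "betweenness_centrality": pd.Series(btw),
            "closeness_centrality": pd.Series(clo),
        }
    ).sort_index()


def topology(net: nx.Graph, seed: int = 0) -> NetworkTopology:
    """Network-level summary: average degree 2E/N, average clustering
    (degree<2 nodes contribute 0), mean shortest path over connected
    pairs, Louvain modularity (seeded), and edge-sign percentages."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        warnings.warn("empty network; topology is all zeros", stacklevel=2)
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    avg_k = 2.0 * e / n
    avg_cc = nx.average_clustering(net) if n > 0 else 0.0
    total, pairs = 0, 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    avg_path = total / pairs if pairs else 0.0
    if e > 0:
        communities = nx.community.louvain_communities(net, seed=seed)
        q = nx.community.modularity(net, communities)
        signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
        pct_pos = 100.0 * sum(s > 0 for s in signs) / e
        pct_neg = 100.0 * sum(s < 0 for s in signs) / e
    else:
        q, pct_pos, pct_neg = 0.0, 0.0, 0.0
    return NetworkTopology(n, e, avg_k, avg_cc, avg_path, q, pct_pos, pct_neg)


def hubs_from_centralities(cent: pd.DataFrame, rule: HubRule = HubRule()) -> list[str]:
    """Apply the strict triple threshold to a centrality table."""
    mask = (
        (cent["degree_centrality"] > rule.degree_centrality_min)
        & (cent["closeness_centrality"] > rule.closeness_min)
        & (cent["betweenness_centrality"] > rule.betweenness_min)
    )
    hubs = cent[mask]
    return sorted(hubs.index, key=lambda t: (-hubs.at[t, "degree_centrality"], t))


def hub_core(net: nx.Graph, rule: HubRule = HubRule()) -> list[str]:
    """Hub microbiome: nodes strictly exceeding all three centrality
    thresholds, sorted by degree centrality descending (ties by id)."""
    if net.number_of_nodes() < 2:
        return []
    return hubs_from_centralities(centralities(net), rule)


def mean_relative_abundance(table: AbundanceTable) -> pd.Series:
    """Node attribute helper: mean per-sample relative abundance per taxon."""
    return relative_abundance(table).mean(axis=0)


def annotate_network(net: nx.Graph, table: AbundanceTable) -> nx.Graph:
    """Attach centralities and mean relative abundance as node attributes."""
    if net.number_of_nodes() >= 2:
        cent = centralities(net)
        for col in cent.columns:
            nx.set_node_attributes(net, cent[col].to_dict(), col)
    mra = mean_relative_abundance(table)
    nx.set_node_attributes(
        net, {t: float(mra.get(t, 0.0)) for t in net.nodes}, "mean_relative_abundance"
    )
    return net
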