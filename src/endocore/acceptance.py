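"""Reusable desk-scale reproduction measurements.

These functions recompute, from the package's own machinery, the
quantities that can be checked without the original sequencing data:
average-degree accounting from published node/edge counts, rarefaction
read totals from published per-sample depths, compound fold changes from
published group means, brute-force oracle agreement on randomized small
instances, planted-structure recovery, and null calibration of the
permutation machinery.  Both the acceptance tests and
``scripts/acceptance.py`` drive them.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import synth
from .association import core_compound_spearman, fold_change, spearman_with_p
from .beta import anosim, upgma, weighted_unifrac
from .io import AbundanceTable, CompoundTable, SampleMetadata, normalize_to_min_depth
from .network import build_network, centralities, hub_core, spearman_matrix, topology

# Published network sizes and per-sample rarefaction depths for the two
# surveys (developmental stages; organs at maturity).
STAGE_NETWORK = (225, 4065)
ORGAN_NETWORK = (191, 1970)
STAGE_DEPTH = 39_814
ORGAN_DEPTH = 37_821
N_SAMPLES = 12

# Published compound group means (mg/g) behind the reported fold changes.
REPORTED_FOLDS = {
    "fold_oma_mature_vs_flowering": ("OMA", 52.5, 12.6),
    "fold_osc_adult_vs_podding": ("OSC", 46.2, 25.9),
    "fold_sc_mature_vs_flowering": ("SC", 18.6, 8.4),
    "fold_osc_seeds_vs_leaves": ("OSC", 143.1, 6.3),
}


def avgk_from_published_counts(n_nodes: int, n_edges: int, seed: int = 0) -> float:
    """Average degree via the topology stage on a graph of the published size."""
    graph = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    return topology(graph, seed=seed).avgK


def effective_reads_after_rarefaction(per_sample_depth: int, seed: int = 0) -> int:
    """Total reads left after rarefying 12 unequal libraries to the
    published minimum per-sample depth."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(N_SAMPLES):
        extra = 0 if i == 0 else int(rng.integers(1, 20_000))
        total = per_sample_depth + extra
        a = int(rng.integers(0, total + 1))
        rows.append([a, total - a])
    table = AbundanceTable(
        pd.DataFrame(rows, index=[f"s{i+1}" for i in range(N_SAMPLES)], columns=["x", "y"])
    )
    normalized = normalize_to_min_depth(table, seed=seed)
    return int(normalized.sample_sums().sum())


def fold_from_published_means(compound: str, mean_a: float, mean_b: float) -> float:
    """Rounded fold change recomputed from published group means via the
    association stage (three identical replicates per group)."""
    cols = ["OMA", "MA", "SC", "OSC"]
    samples, groups = [], {}
    rows = []
    for g, m in (("X", mean_a), ("Y", mean_b)):
        for r in range(3):
            rows.append([m if c == compound else 1.0 for c in cols])
            sid = f"{g}{r+1}"
            samples.append(sid)
            groups[sid] = g
    values = pd.DataFrame(rows, index=samples, columns=cols)
    values["TOTAL"] = values.sum(axis=1)
    compounds = CompoundTable(values)
    meta = SampleMetadata(
        pd.DataFrame({"group": [groups[s] for s in samples], "replicate": range(6)},
                     index=samples)
    )
    _, rounded = fold_change(compounds, meta, compound, "X", "Y")
    return rounded


# --------------------------------------------------------------------------
# Brute-force oracle agreement on randomized small instances


def _oracle_centralities(net):
    nodes = sorted(net.nodes)
    n = len(nodes)
    deg = {v: net.degree[v] / (n - 1) for v in nodes}
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(net, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v not in (s, t):
                btw[v] += sum(v in p for p in paths) / len(paths)
    scale = (n - 1) * (n - 2) / 2
    clo = {}
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(net, v)
        reach = len(lengths) - 1
        clo[v] = 0.0 if reach == 0 else (reach / sum(lengths.values())) * (reach / (n - 1))
    return deg, {v: b / scale for v, b in btw.items()}, clo


def centrality_oracle_agreement(n_cases: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    agree = total = 0
    while total < n_cases:
        net = nx.gnp_random_graph(int(rng.integers(4, 10)), float(rng.uniform(0.25, 0.7)),
                                  seed=int(rng.integers(2**31)))
        net.remove_nodes_from(list(nx.isolates(net)))
        if net.number_of_nodes() < 3:
            continue
        total += 1
        cent = centralities(net)
        deg, btw, clo = _oracle_centralities(net)
        ok = all(
            np.isclose(cent.at[v, "degree_centrality"], deg[v])
            and np.isclose(cent.at[v, "betweenness_centrality"], btw[v])
            and np.isclose(cent.at[v, "closeness_centrality"], clo[v])
            for v in net.nodes
        )
        agree += ok
    return agree / total


def _oracle_upgma_heights(data):
    clusters = [[i] for i in range(data.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([data[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return np.array(heights)


def upgma_oracle_agreement(n_cases: int, seed: int) -> float:
    from skbio import DistanceMatrix

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(4, 7))
        pts = rng.normal(size=(n, 3))
        data = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dendro = upgma(DistanceMatrix(data, ids=[f"s{i}" for i in range(n)]))
        agree += np.allclose(dendro.merges[:, 2], _oracle_upgma_heights(data))
    return agree / n_cases


def _oracle_wunifrac(counts, taxa, tree):
    rel = counts / counts.sum(axis=1, keepdims=True)
    col = {t: k for k, t in enumerate(taxa)}
    branches = []
    for node in tree.traverse(include_self=False):
        below = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if node.length:
            branches.append((node.length, below))
    out = np.zeros((len(counts), len(counts)))
    for i, j in itertools.combinations(range(len(counts)), 2):
        num = den = 0.0
        for length, below in branches:
            pa = sum(rel[i, col[t]] for t in below)
            pb = sum(rel[j, col[t]] for t in below)
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        out[i, j] = out[j, i] = num / den if den else 0.0
    return out


def wunifrac_oracle_agreement(n_cases: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_cases):
        n_leaves = int(rng.integers(3, 7))
        taxa = [f"t{i}" for i in range(n_leaves)]
        tree = synth.generate_tree(taxa, seed=int(rng.integers(2**31)))
        counts = rng.integers(1, 60, size=(4, n_leaves))
        table = AbundanceTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(4)], columns=taxa)
        )
        dm = weighted_unifrac(table, tree)
        agree += np.allclose(dm.data, _oracle_wunifrac(counts, taxa, tree), atol=1e-12)
    return agree / n_cases


def spearman_oracle_agreement(n_cases: int, seed: int) -> float:
    """rho vs Pearson-on-midranks; p vs naive exhaustive permutation."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(5, 7))
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            agree += 1  # both routes report missing
            continue
        rho, p = spearman_with_p(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = stats.pearsonr(rx, ry).statistic
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = stats.pearsonr(rx, np.array(perm)).statistic
            hits += abs(r) >= abs(obs) - 1e-12
            total += 1
        agree += bool(np.isclose(rho, obs) and np.isclose(p, hits / total))
    return agree / n_cases


# --------------------------------------------------------------------------
# Planted-structure recovery and null calibration


def planted_clique_recovery(n_seeds: int, seed: int) -> dict:
    """One 6-taxon clique at rho 0.95 among 20 independent background taxa:
    clique edge connectivity and hub-classifier precision over seeds."""
    rng = np.random.default_rng(seed)
    connected = tp = predicted = 0
    for _ in range(n_seeds):
        cfg = synth.SynthConfig(
            n_taxa=26, n_hub_cliques=1, clique_size=6, clique_rho=0.95,
            depth=50_000, n_assoc_taxa=0, seed=int(rng.integers(2**31)),
        )
        table, truth = synth.generate_community(cfg)
        rho, p = spearman_matrix(table)
        net = build_network(rho, p)
        clique = truth.cliques[0]
        connected += all(
            net.has_edge(a, b) for a, b in itertools.combinations(clique, 2)
        )
        hubs = hub_core(net)
        tp += len(set(hubs) & truth.hub_taxa)
        predicted += len(hubs)
    return {
        "clique_connectivity_rate": connected / n_seeds,
        "hub_precision": tp / predicted if predicted else float("nan"),
        "hubs_predicted": predicted,
    }


def planted_association_power(n_seeds: int, seed: int) -> float:
    """Fraction of seeds in which the planted rho=0.9 taxon-compound pair
    is starred (p < 0.05)."""
    rng = np.random.default_rng(seed)
    starred = 0
    for _ in range(n_seeds):
        cfg = synth.SynthConfig(
            n_taxa=26, n_hub_cliques=0, n_assoc_taxa=1, assoc_rho=0.9,
            depth=50_000, seed=int(rng.integers(2**31)),
        )
        table, truth = synth.generate_community(cfg)
        compounds = synth.generate_compounds(table, truth, cfg)
        taxon, compound, _ = truth.assoc_pairs[0]
        frame = core_compound_spearman(table, compounds, [taxon])
        row = frame[(frame.taxon == taxon) & (frame.compound == compound)].iloc[0]
        starred += row.star != ""
    return starred / n_seeds


def anosim_null_rejection_rate(n_runs: int, seed: int, n_perm: int = 999) -> float:
    """Rejection rate at 0.05 of ANOSIM under randomly assigned labels."""
    from .beta import bray_curtis

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_runs):
        cfg = synth.SynthConfig(
            n_taxa=15, depth=5000, n_hub_cliques=0, n_assoc_taxa=0,
            seed=int(rng.integers(2**31)),
        )
        table, _ = synth.generate_community(cfg)
        dm = bray_curtis(table)
        labels = pd.Series(
            rng.permutation(np.repeat(["g1", "g2", "g3", "g4"], 3)),
            index=table.sample_ids,
        )
        res = anosim(dm, labels, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p <= 0.05
    return rejections / n_runs


def null_edge_rate(n_seeds: int, seed: int) -> float:
    """Mean co-occurrence edge discovery rate with no planted structure,
    under the default community (60 log-normal taxa, 12 samples).

    Compositional closure (every sample's proportions summing to 1) lifts
    the realized rate slightly above the independent-pair rate, so this
    sits near the nominal 0.05 level rather than well below it.
    """
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_seeds):
        cfg = synth.SynthConfig(
            n_hub_cliques=0, n_assoc_taxa=0, seed=int(rng.integers(2**31)),
        )
        table, _ = synth.generate_community(cfg)
        rho, p = spearman_matrix(table)
        net = build_network(rho, p)
        k = rho.shape[0]
        rates.append(net.number_of_edges() / (k * (k - 1) / 2))
    return float(np.mean(rates))
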