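"""Between-sample diversity: Bray-Curtis and weighted UniFrac distances,
UPGMA clustering, principal coordinates, and permutation tests of group
separation (ANOSIM, with PERMANOVA as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from .io import AbundanceTable


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = 1 - 2*sum(min)/sum(x+y) on raw counts."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise ValueError(f"zero-sum samples: {sums.index[sums == 0].tolist()}")
    condensed = pdist(table.counts.to_numpy(float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def _branch_proportions(table: AbundanceTable, tree: TreeNode):
    """Per-branch matrix of the proportion of each sample descending from it."""
    leaves = {t.name for t in tree.tips()}
    counts = table.counts
    present = counts.columns[(counts > 0).any(axis=0)]
    missing = set(present) - leaves
    if missing:
        raise ValueError(f"taxa with positive counts absent from tree: {sorted(missing)}")
    rel = counts.div(counts.sum(axis=1), axis=0)
    lengths = []
    props = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._wu = (
                rel[node.name].to_numpy()
                if node.name in rel.columns
                else np.zeros(len(rel))
            )
        else:
            node._wu = sum(c._wu for c in node.children)
        if node.length:
            lengths.append(node.length)
            props.append(node._wu)
    for node in tree.postorder(include_self=False):
        del node._wu
    return np.asarray(lengths), np.asarray(props)  # (B,), (B, n_samples)


def weighted_unifrac(table: AbundanceTable, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac: sum_b L_b |pA(b)-pB(b)|, divided (when normalized)
    by sum_b L_b (pA(b)+pB(b)) so distances lie in [0,1]."""
    lengths, props = _branch_proportions(table, tree)
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = float(lengths @ np.abs(props[:, i] - props[:, j]))
            if normalized:
                den = float(lengths @ (props[:, i] + props[:, j]))
                d = num / den if den > 0 else 0.0
            else:
                d = num
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=table.sample_ids)


@dataclass
class Dendrogram:
    """Average-linkage tree: scipy linkage matrix plus the leaf order."""

    ids: list[str]
    merges: np.ndarray  # scipy (n-1, 4) linkage matrix

    def cophenetic(self) -> DistanceMatrix:
        return DistanceMatrix(squareform(cophenet(self.merges)), ids=self.ids)

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.merges, self.ids)
        return str(tree).strip()


def upgma(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical clustering of a distance matrix (UPGMA by default)."""
    data = dm.condensed_form()
    if np.isnan(data).any():
        raise ValueError("distance matrix contains NaN")
    return Dendrogram(ids=list(dm.ids), merges=linkage(data, method=method))


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates on positive axes, full eigenvalue spectrum."""

    coordinates: pd.DataFrame       # samples x positive axes (PC1, PC2, ...)
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling: eigendecomposition of the Gower-centered
    squared distance matrix.  Negative eigenvalues are reported, excluded
    from the proportion-explained denominator, and carry no coordinates.
    """
    d = dm.data
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class GroupSeparation:
    """Permutation test summary: R (ANOSIM) or pseudo-F (PERMANOVA) with p."""

    statistic: float
    p: float
    n_perm: int
    method: str = "anosim"


def _group_masks(groups: pd.Series, ids) -> np.ndarray:
    labels = groups.loc[list(ids)].to_numpy()
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = values[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    return labels


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    within = rank_sq[iu][same[iu]]
    between = rank_sq[iu][~same[iu]]
    m = n * (n - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2.0))


def anosim(dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0) -> GroupSeparation:
    """Clarke's ANOSIM: R = (mean between-group rank - mean within-group
    rank) / (M/2) on the ranked distances, M = n(n-1)/2; one-sided upper
    permutation p with the +1 correction."""
    labels = _group_masks(groups, dm.ids)
    ranks = rankdata(dm.condensed_form())
    rank_sq = squareform(ranks)
    observed = _anosim_r(rank_sq, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _anosim_r(rank_sq, labels[perm]) >= observed:
            hits += 1
    return GroupSeparation(observed, (1 + hits) / (1 + n_perm), n_perm, "anosim")


def _permanova_f(d2_sq: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    ss_total = d2_sq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2_sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        k += 1
    ss_between = ss_total - ss_within
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def permanova(dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0) -> GroupSeparation:
    """One-way PERMANOVA pseudo-F with seeded label permutations."""
    labels = _group_masks(groups, dm.ids)
    d2 = dm.data**2
    observed = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _permanova_f(d2, labels[perm]) >= observed:
            hits += 1
    return GroupSeparation(observed, (1 + hits) / (1 + n_perm), n_perm, "permanova")
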