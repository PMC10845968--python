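import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from endocore import synth
from endocore.beta import (
    anosim,
    bray_curtis,
    pcoa,
    permanova,
    upgma,
    weighted_unifrac,
)
from endocore.io import AbundanceTable


def _table(rows, ids=None, taxa=None):
    rows = np.asarray(rows)
    ids = ids or [f"s{i+1}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{i+1}" for i in range(rows.shape[1])]
    return AbundanceTable(pd.DataFrame(rows, index=ids, columns=taxa))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = bray_curtis(_table([[3, 1, 4], [3, 1, 4]]))
        assert dm[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(_table([[5, 0], [0, 7]]))
        assert dm[0, 1] == 1.0

    def test_hand_evaluated(self):
        dm = bray_curtis(_table([[5, 0, 3], [2, 4, 3]]))
        assert dm[0, 1] == pytest.approx(1 - 2 * 5 / 17)

    def test_range_and_symmetry(self, demo_dataset):
        (table, *_), _ = demo_dataset
        dm = bray_curtis(table)
        assert np.allclose(dm.data, dm.data.T)
        assert ((dm.data >= 0) & (dm.data <= 1)).all()
        assert np.diag(dm.data).sum() == 0


def _brute_force_wunifrac(counts, taxa, tree):
    """Oracle: enumerate branches explicitly via leaf-descendant sets."""
    rel = counts / counts.sum(axis=1, keepdims=True)
    col = {t: k for k, t in enumerate(taxa)}
    out = np.zeros((len(counts), len(counts)))
    branches = []
    for node in tree.traverse(include_self=False):
        below = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if node.length:
            branches.append((node.length, below))
    for i, j in itertools.combinations(range(len(counts)), 2):
        num = den = 0.0
        for length, below in branches:
            pa = sum(rel[i, col[t]] for t in below if t in col)
            pb = sum(rel[j, col[t]] for t in below if t in col)
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        out[i, j] = out[j, i] = num / den if den else 0.0
    return out


class TestWeightedUnifrac:
    def test_identical_relative_abundances_zero(self):
        tree = TreeNode.read(_io.StringIO("(t1:1,t2:1):0;"))
        dm = weighted_unifrac(_table([[10, 10], [20, 20]]), tree)
        assert dm[0, 1] == pytest.approx(0.0)

    def test_opposite_leaves_of_two_leaf_tree(self):
        tree = TreeNode.read(_io.StringIO("(t1:1,t2:1):0;"))
        dm = weighted_unifrac(_table([[10, 0], [0, 10]]), tree)
        assert dm[0, 1] == pytest.approx(1.0)

    def test_matches_branch_enumeration_oracle(self, rng):
        for seed in range(20):
            taxa = [f"t{i+1}" for i in range(6)]
            tree = synth.generate_tree(taxa, seed=seed)
            counts = rng.integers(0, 50, size=(4, 6))
            counts[counts.sum(axis=1) == 0, 0] = 1
            dm = weighted_unifrac(_table(counts, taxa=taxa), tree)
            oracle = _brute_force_wunifrac(counts, taxa, tree)
            assert np.allclose(dm.data, oracle, atol=1e-12)

    def test_matches_skbio(self, rng):
        taxa = [f"t{i+1}" for i in range(8)]
        tree = synth.generate_tree(taxa, seed=3)
        counts = rng.integers(1, 40, size=(5, 8))
        mine = weighted_unifrac(_table(counts, taxa=taxa), tree)
        ref = beta_diversity(
            "weighted_unifrac", counts, ids=mine.ids, taxa=taxa, tree=tree,
            normalized=True,
        )
        assert np.allclose(mine.data, ref.data, atol=1e-12)


def _brute_force_upgma(dm_data, ids):
    """Oracle: naive O(n^3) average-linkage with explicit cluster lists."""
    clusters = [[i] for i in range(len(ids))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dm_data[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted(map(sorted, (clusters[a], clusters[b]))), d))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


class TestUpgma:
    def test_two_samples_merge_at_distance(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
        dendro = upgma(dm)
        assert dendro.merges.shape == (1, 4)
        assert dendro.merges[0, 2] == pytest.approx(0.4)

    def test_ultrametric_input_reproduced_exactly(self):
        # heights: (a,b) at 0.2; ((a,b),c) at 0.8
        data = np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
        dm = DistanceMatrix(data, ids=list("abc"))
        coph = upgma(dm).cophenetic()
        assert np.allclose(coph.data, data)

    def test_merge_sequence_matches_naive_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(5, 3))
            data = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            ids = list("abcde")
            dendro = upgma(DistanceMatrix(data, ids=ids))
            oracle = _brute_force_upgma(data, ids)
            heights = dendro.merges[:, 2]
            assert np.allclose(heights, [h for _, h in oracle])

    def test_nan_rejected(self):
        with pytest.raises(Exception, match="NaN|nan"):
            upgma(DistanceMatrix(np.array([[0, np.nan], [np.nan, 0]]), ids=["a", "b"]))


class TestPcoa:
    def test_collinear_points_recovered_in_one_dimension(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert (res.eigenvalues > 1e-9).sum() == 1
        x = res.coordinates["PC1"].to_numpy()
        rec = np.abs(x[:, None] - x[None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_equilateral_three_points_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_proportions_sum_to_one(self, demo_dataset):
        (table, *_), _ = demo_dataset
        res = pcoa(bray_curtis(table))
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)

    def test_identical_samples_give_zero_coordinates(self):
        dm = bray_curtis(_table([[3, 1], [3, 1], [3, 1]]))
        res = pcoa(dm)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_matches_skbio(self, demo_dataset):
        (table, *_), _ = demo_dataset
        dm = bray_curtis(table)
        mine = pcoa(dm)
        ref = skbio_pcoa(dm)
        npos = len(mine.proportion_explained)
        assert np.allclose(
            np.abs(mine.eigenvalues[:npos]), ref.eigvals.to_numpy()[:npos], atol=1e-9
        )
        assert np.allclose(
            mine.proportion_explained,
            ref.proportion_explained.to_numpy()[:npos],
            atol=1e-9,
        )


def _hand_anosim_r(data, labels):
    """Oracle: rank all pairwise distances by hand and apply Clarke's formula."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    dists = [data[i, j] for i, j in pairs]
    order = np.argsort(dists, kind="stable")
    ranks = np.empty(len(dists))
    # average ranks for ties
    sorted_d = np.sort(dists)
    for k, d in enumerate(dists):
        tied = [i + 1 for i, sd in enumerate(sorted_d) if sd == d]
        ranks[k] = np.mean(tied)
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


class TestAnosim:
    def _clustered_dm(self, rng, n_per=3, k=2, shift=4.0):
        pts = rng.normal(size=(n_per * k, 2))
        for g in range(k):
            pts[g * n_per : (g + 1) * n_per] += g * shift
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(len(pts))]
        labels = pd.Series(np.repeat([f"g{j}" for j in range(k)], n_per), index=ids)
        return DistanceMatrix(d, ids=ids), labels

    def test_perfect_separation_gives_r_one(self, rng):
        dm, labels = self._clustered_dm(rng, shift=100.0)
        res = anosim(dm, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_hand_rank_evaluation(self, rng):
        dm, labels = self._clustered_dm(rng, shift=1.0)
        res = anosim(dm, labels, n_perm=9, seed=0)
        oracle = _hand_anosim_r(dm.data, labels.to_numpy())
        assert res.statistic == pytest.approx(oracle)

    def test_matches_skbio_r_statistic(self, rng):
        dm, labels = self._clustered_dm(rng, n_per=4, shift=1.5)
        res = anosim(dm, labels, n_perm=9, seed=0)
        ref = skbio_anosim(dm, grouping=labels.to_numpy(), permutations=9)
        assert res.statistic == pytest.approx(ref["test statistic"])

    def test_seeded_reproducibility_and_label_renaming(self, rng):
        dm, labels = self._clustered_dm(rng, shift=0.5)
        a = anosim(dm, labels, n_perm=199, seed=11)
        b = anosim(dm, labels, n_perm=199, seed=11)
        renamed = labels.map({"g0": "organ", "g1": "stage"})
        c = anosim(dm, renamed, n_perm=199, seed=11)
        assert a.p == b.p == c.p
        assert a.statistic == c.statistic

    def test_singleton_group_rejected(self, rng):
        dm, labels = self._clustered_dm(rng)
        labels.iloc[0] = "lonely"
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(dm, labels, n_perm=9, seed=0)


class TestPermanova:
    def test_matches_skbio_pseudo_f(self, rng):
        pts = rng.normal(size=(9, 2))
        pts[5:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(9)]
        labels = pd.Series(["a"] * 5 + ["b"] * 4, index=ids)
        dm = DistanceMatrix(d, ids=ids)
        mine = permanova(dm, labels, n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=labels.to_numpy(), permutations=9)
        assert mine.statistic == pytest.approx(ref["test statistic"])
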