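"""Per-sample alpha-diversity indices: Chao1, Faith PD, Shannon evenness,
Simpson dominance.

The calculator forms follow the mothur conventions: bias-corrected Chao1,
finite-sample Simpson dominance D = sum n_i(n_i-1)/(N(N-1)) (smaller =
more diverse), Shannon evenness H/ln(S_obs) with natural logs, and rooted
Faith PD (the root path is included).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import AbundanceTable


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def observed_taxa(counts) -> int:
    return int((_as_counts(counts) > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default; the classic
    S_obs + F1^2/(2 F2) via ``bias_corrected=False`` (undefined when F2=0,
    in which case the bias-corrected form is returned).
    """
    arr = _as_counts(counts)
    if arr.sum() == 0:
        raise ValueError("all-zero sample")
    s_obs = (arr > 0).sum()
    f1 = (arr == 1).sum()
    f2 = (arr == 2).sum()
    if bias_corrected or f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    return float(s_obs + f1 * f1 / (2.0 * f2))


def shannon_evenness(counts) -> float:
    """Pielou-style evenness H/ln(S_obs); NaN when only one taxon is present."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    pos = arr[arr > 0]
    if pos.size == 1:
        return float("nan")
    p = pos / total
    h = -(p * np.log(p)).sum()
    return float(h / np.log(pos.size))


def simpson_dominance(counts) -> float:
    """Finite-sample Simpson dominance sum n_i(n_i-1)/(N(N-1))."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total < 2:
        raise ValueError("Simpson dominance needs at least 2 individuals")
    return float((arr * (arr - 1)).sum() / (total * (total - 1)))


def faith_pd(present_taxa, tree: TreeNode, rooted: bool = True) -> float:
    """Faith phylogenetic diversity: branch length of the minimal subtree
    spanning the present leaves (and the root when ``rooted``)."""
    present = set(present_taxa)
    if not present:
        return 0.0
    leaves = {t.name for t in tree.tips()}
    missing = present - leaves
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    total = 0.0
    # A branch counts when at least one present leaf descends from it
    # (for unrooted PD: at least one on each side, i.e. not all of them).
    n_present = len(present)
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._pd_n = 1 if node.name in present else 0
        else:
            node._pd_n = sum(c._pd_n for c in node.children)
        if node.length and node._pd_n > 0:
            if rooted or node._pd_n < n_present:
                total += node.length
    for node in tree.postorder(include_self=False):
        del node._pd_n
    return float(total)


def alpha_table(table: AbundanceTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """One row per sample: s_obs, chao, pd, shannoneven, simpson."""
    rows = {}
    for sample in table.sample_ids:
        counts = table.counts.loc[sample].to_numpy()
        present = [t for t, c in zip(table.taxon_ids, counts) if c > 0]
        rows[sample] = {
            "s_obs": observed_taxa(counts),
            "chao": chao1(counts),
            "pd": faith_pd(present, tree) if tree is not None else float("nan"),
            "shannoneven": shannon_evenness(counts),
            "simpson": simpson_dominance(counts),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["s_obs", "chao", "pd", "shannoneven", "simpson"]
    ]
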