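"""Community composition summaries: shared/unique taxon sets across groups,
the membership-rule core microbiome, and top-taxon abundance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import AbundanceTable, SampleMetadata, relative_abundance


@dataclass
class VennSummary:
    """Presence sets per group plus the across-group intersection."""

    group_sets: dict[str, set[str]]
    shared: set[str]
    unique: dict[str, set[str]]

    @property
    def unique_counts(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.unique.items()}


def venn_sets(
    table: AbundanceTable,
    metadata: SampleMetadata,
    presence_rule: str = "any",
) -> VennSummary:
    """Group-level presence sets.

    A taxon is present in a group if it has count > 0 in at least one of
    the group's samples (``presence_rule="any"``) or in every sample
    (``"all"``).  Unique = present in exactly one group; shared = present
    in every group.
    """
    if presence_rule not in {"any", "all"}:
        raise ValueError(f"unknown presence rule {presence_rule!r}")
    groups = metadata.groups_for(table.sample_ids)
    present = table.counts > 0
    group_sets: dict[str, set[str]] = {}
    for g in dict.fromkeys(groups):
        samples = groups.index[groups == g]
        mask = present.loc[samples]
        agg = mask.any(axis=0) if presence_rule == "any" else mask.all(axis=0)
        group_sets[g] = set(agg.index[agg])
    all_groups = list(group_sets)
    shared = set.intersection(*group_sets.values())
    unique = {
        g: group_sets[g] - set().union(*(group_sets[h] for h in all_groups if h != g))
        for g in all_groups
    }
    return VennSummary(group_sets=group_sets, shared=shared, unique=unique)


def membership_core(
    table: AbundanceTable,
    top_n: int = 10,
    ranking: str = "mean_relative",
) -> list[str]:
    """Membership-rule core microbiome: taxa present (count > 0) in every
    sample, ranked by mean per-sample relative abundance, truncated to the
    ``top_n`` highest.  Ties break lexicographically by taxon id.
    """
    present_all = (table.counts > 0).all(axis=0)
    candidates = list(present_all.index[present_all])
    if not candidates:
        return []
    if ranking == "mean_relative":
        score = relative_abundance(table)[candidates].mean(axis=0)
    elif ranking == "pooled":
        pooled = table.counts[candidates].sum(axis=0)
        score = pooled / table.counts.to_numpy().sum()
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    ranked = sorted(candidates, key=lambda t: (-score[t], t))
    return ranked[:top_n]


def top_abundance_matrix(
    table: AbundanceTable,
    metadata: SampleMetadata,
    n: int = 50,
) -> pd.DataFrame:
    """Group x taxon mean relative abundance for the global top-n taxa.

    Taxa are ranked by mean per-sample relative abundance over all
    samples; everything below rank n is aggregated into an ``other``
    column.  Rows (groups) sum to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(table.taxon_ids):
        warnings.warn(
            f"n={n} exceeds taxon count {len(table.taxon_ids)}; clamping",
            stacklevel=2,
        )
        n = len(table.taxon_ids)
    rel = relative_abundance(table)
    score = rel.mean(axis=0)
    top = sorted(table.taxon_ids, key=lambda t: (-score[t], t))[:n]
    groups = metadata.groups_for(table.sample_ids)
    rows = {}
    for g in dict.fromkeys(groups):
        mean_rel = rel.loc[groups.index[groups == g]].mean(axis=0)
        row = {t: mean_rel[t] for t in top}
        row["other"] = max(0.0, 1.0 - sum(row.values()))
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")[top + ["other"]]
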