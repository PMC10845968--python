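"""Tabular containers and readers/writers for abundance, metadata and compound data.

All on-disk formats are plain TSV (UTF-8, tab-separated, no quoting) with
samples as rows, plus Newick for phylogenies.  Depth normalization
(rarefaction to the smallest library) lives here because every downstream
analysis in the pipeline consumes the normalized table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

COMPOUND_IDS = ("OMA", "MA", "SC", "OSC", "TOTAL")


class TableError(ValueError):
    """Raised for malformed or inconsistent tables."""


def _check_unique(labels, kind: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {kind} ids: {dupes}")


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of non-negative integer counts.

    ``counts`` is a pandas DataFrame indexed by sample id with taxon ids as
    columns.  ``rank`` records the taxonomic rank of the columns (genus by
    default; OTU tables use rank="otu").
    """

    counts: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise TableError("abundance table needs at least one sample and one taxon")
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "taxon")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise TableError(
                    f"non-integer count at sample {self.counts.index[bad[0]]!r}, "
                    f"taxon {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative count at sample {self.counts.index[bad[0]]!r}, "
                f"taxon {self.counts.columns[bad[1]]!r}"
            )
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class SampleMetadata:
    """Per-sample design: group (stage or organ) label and replicate index."""

    frame: pd.DataFrame  # index: sample_id; columns: group, replicate

    def __post_init__(self) -> None:
        missing = {"group", "replicate"} - set(self.frame.columns)
        if missing:
            raise TableError(f"metadata missing columns: {sorted(missing)}")
        _check_unique(self.frame.index, "sample")
        self.frame.index.name = "sample_id"

    def groups_for(self, sample_ids) -> pd.Series:
        absent = [s for s in sample_ids if s not in self.frame.index]
        if absent:
            raise TableError(f"samples without metadata: {absent}")
        return self.frame.loc[list(sample_ids), "group"]

    @property
    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))


@dataclass
class CompoundTable:
    """Samples x alkaloid contents in mg/g.

    Columns are OMA, MA, SC, OSC and TOTAL.  The SC column carries the
    pooled sophocarpine + sophoridine amount (the two co-elute), and TOTAL
    is the sum of the four components.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        missing = set(COMPOUND_IDS) - set(self.values.columns)
        if missing:
            raise TableError(f"compound table missing columns: {sorted(missing)}")
        self.values = self.values[list(COMPOUND_IDS)].astype(float)
        if (self.values.to_numpy() < 0).any():
            raise TableError("compound contents must be non-negative")
        self.values.index.name = "sample_id"
        self.values.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# TSV round-trips


def read_abundance(path, rank: str = "genus") -> AbundanceTable:
    """Read a samples-x-taxa TSV (header row of taxon ids, first column sample ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise TableError(f"{path}: no taxon columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableError(
            f"{path}: non-numeric count at sample {raw.index[r]!r}, taxon {raw.columns[c]!r}"
        )
    frac = numeric.to_numpy() % 1
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise TableError(
            f"{path}: non-integer count {raw.iat[r, c]!r} at sample "
            f"{raw.index[r]!r}, taxon {raw.columns[c]!r}"
        )
    return AbundanceTable(numeric.astype(np.int64), rank=rank)


def write_abundance(table: AbundanceTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={"replicate": int})
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_compounds(path) -> CompoundTable:
    return CompoundTable(pd.read_csv(path, sep="\t", index_col=0))


def write_compounds(table: CompoundTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    _check_unique(names, "leaf")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Depth normalization


def normalize_to_min_depth(
    table: AbundanceTable,
    seed: int,
    *,
    with_replacement: bool = False,
    drop_empty_taxa: bool = False,
) -> AbundanceTable:
    """Subsample every sample to the smallest library size.

    Rarefaction without replacement (multivariate hypergeometric) by
    default, so each output sample sums to d = min over sample sums.
    Taxa whose column becomes all-zero are retained unless
    ``drop_empty_taxa`` so the taxon universe stays aligned across runs.
    """
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = sums.index[sums == 0].tolist()
        raise TableError(f"cannot rarefy samples with zero total: {empty}")
    depth = int(sums.min())
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, (_, row) in enumerate(table.counts.iterrows()):
        counts = row.to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        elif with_replacement:
            p = counts / counts.sum()
            out[i] = rng.multinomial(depth, p)
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    frame = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    if drop_empty_taxa:
        frame = frame.loc[:, frame.sum(axis=0) > 0]
    return AbundanceTable(frame, rank=table.rank)


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    sums = table.sample_sums()
    if (sums == 0).any():
        empty = sums.index[sums == 0].tolist()
        raise TableError(f"zero-sum samples: {empty}")
    return table.counts.div(sums, axis=0)
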