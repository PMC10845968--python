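"""Synthetic community, phylogeny and compound generators.

The generators emulate the statistical structure a stage/organ endophyte
survey hands to the analysis pipeline: a small replicated design (4 groups
x 3 replicates), compositional genus counts with a few dominant and many
rare taxa (heavy-tailed log-normal base abundances), planted correlated
cliques that should surface as high-centrality hub genera in the
co-occurrence network, and alkaloid content vectors with planted monotone
taxon-compound relationships.

Correlations are planted through a Gaussian copula on log-abundance: a
target Spearman rho is mapped to the latent Pearson correlation
r = 2*sin(pi*rho/6) (the bivariate-normal rank-correlation relation), and
each clique shares a common latent factor with loading sqrt(r).  The
multinomial read-sampling step perturbs ranks, so realized correlations
match the target only statistically; calibration is asserted over seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import AbundanceTable, CompoundTable, SampleMetadata

_COMPOUNDS = ("OMA", "MA", "SC", "OSC")
# mg/g log-scale location and spread per compound; magnitudes follow the
# typical quinolizidine-alkaloid ranges (tens of mg/g for OMA/OSC, a few
# for MA).
_COMPOUND_SCALE = {"OMA": 30.0, "MA": 5.0, "SC": 15.0, "OSC": 40.0}
_COMPOUND_SIGMA = 0.6


class ConfigError(ValueError):
    """Raised when a synthetic-data configuration violates a bound."""


def _latent_corr(spearman_rho: float) -> float:
    """Latent bivariate-normal correlation achieving a target Spearman rho."""
    return 2.0 * math.sin(math.pi * spearman_rho / 6.0)


@dataclass
class SynthConfig:
    """Parameters of the synthetic community.

    Defaults mirror the surveyed design: four groups (developmental stages
    or organs) with three replicates, log-normal taxon abundances with
    sigma 1.5 so one or two genera dominate, and read depths in the tens
    of thousands.
    """

    n_groups: int = 4
    n_reps: int = 3
    n_taxa: int = 60
    depth: int = 50_000
    n_hub_cliques: int = 2
    clique_size: int = 5
    clique_rho: float = 0.9
    n_assoc_taxa: int = 2
    assoc_rho: float = 0.9
    seed: int = 0
    sigma: float = 1.5       # log-normal spread of base abundances
    tau: float = 1.0         # per-sample log-abundance noise scale
    group_sigma: float = 0.0  # optional per-group latent shifts (succession)
    group_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_groups * self.n_reps < 4:
            raise ConfigError(
                "n_groups*n_reps must be >= 4 (Spearman needs >= 4 samples); "
                f"got {self.n_groups}*{self.n_reps}"
            )
        if self.n_hub_cliques > 0 and self.clique_size < 3:
            raise ConfigError(f"clique_size must be >= 3, got {self.clique_size}")
        if self.n_hub_cliques * self.clique_size > self.n_taxa:
            raise ConfigError(
                f"n_hub_cliques*clique_size ({self.n_hub_cliques * self.clique_size}) "
                f"exceeds n_taxa ({self.n_taxa})"
            )
        if self.depth <= 0:
            raise ConfigError(f"depth must be positive, got {self.depth}")
        for name in ("n_groups", "n_reps", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0.0 <= self.clique_rho <= 1.0:
            raise ConfigError(f"clique_rho must be in [0,1], got {self.clique_rho}")
        if not -1.0 <= self.assoc_rho <= 1.0:
            raise ConfigError(f"assoc_rho must be in [-1,1], got {self.assoc_rho}")
        if self.n_assoc_taxa > self.n_taxa:
            raise ConfigError("n_assoc_taxa exceeds n_taxa")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_reps

    def groups(self) -> list[str]:
        if self.group_names is not None:
            if len(self.group_names) != self.n_groups:
                raise ConfigError("group_names length must equal n_groups")
            return list(self.group_names)
        if self.n_groups == 4:
            return ["A", "F", "P", "M"]
        return [f"G{i + 1}" for i in range(self.n_groups)]


@dataclass
class SynthTruth:
    """Planted structure: what a perfect analysis should recover."""

    hub_taxa: set[str]
    cliques: list[list[str]]
    assoc_pairs: list[tuple[str, str, int]]  # (taxon, compound, sign)
    group_labels: dict[str, str]

    def to_json(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "hub_taxa": sorted(self.hub_taxa),
            "cliques": self.cliques,
            "assoc_pairs": [list(p) for p in self.assoc_pairs],
            "group_labels": self.group_labels,
        }
        path.write_text(json.dumps(payload, indent=2))


def generate_community(config: SynthConfig) -> tuple[AbundanceTable, SynthTruth]:
    """Draw a samples x taxa count table with planted correlated cliques."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n_s, n_t = config.n_samples, config.n_taxa

    taxa = [f"g{i + 1:03d}" for i in range(n_t)]
    groups = config.groups()
    sample_ids = [f"{g}{r + 1}" for g in groups for r in range(config.n_reps)]
    group_of = {s: g for s, g in zip(sample_ids, np.repeat(groups, config.n_reps))}

    base = rng.normal(0.0, config.sigma, size=n_t)          # heavy-tailed means
    noise = rng.normal(0.0, 1.0, size=(n_s, n_t))
    log_ab = base[None, :] + config.tau * noise

    cliques: list[list[str]] = []
    r = _latent_corr(config.clique_rho)
    load = math.sqrt(max(r, 0.0))
    resid = math.sqrt(max(1.0 - r, 0.0))
    for c in range(config.n_hub_cliques):
        idx = np.arange(c * config.clique_size, (c + 1) * config.clique_size)
        factor = rng.normal(0.0, 1.0, size=n_s)
        log_ab[:, idx] = base[idx][None, :] + config.tau * (
            load * factor[:, None] + resid * noise[:, idx]
        )
        cliques.append([taxa[i] for i in idx])

    if config.group_sigma > 0:
        shifts = rng.normal(0.0, config.group_sigma, size=(config.n_groups, n_t))
        for i, s in enumerate(sample_ids):
            log_ab[i] += shifts[groups.index(group_of[s])]

    probs = np.exp(log_ab - log_ab.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.depth, p) for p in probs])

    table = AbundanceTable(pd.DataFrame(counts, index=sample_ids, columns=taxa))
    truth = SynthTruth(
        hub_taxa=set().union(*cliques) if cliques else set(),
        cliques=cliques,
        assoc_pairs=_plan_assoc_pairs(config, taxa, cliques, base),
        group_labels=group_of,
    )
    return table, truth


def _plan_assoc_pairs(config, taxa, cliques, base) -> list[tuple[str, str, int]]:
    """Pick the planted taxon-compound links: most abundant non-clique taxa,
    compounds assigned round-robin, alternating signs."""
    if config.n_assoc_taxa == 0:
        return []
    in_clique = set().union(*cliques) if cliques else set()
    candidates = [t for t in taxa if t not in in_clique]
    if len(candidates) < config.n_assoc_taxa:
        candidates = list(taxa)
    order = sorted(candidates, key=lambda t: -base[taxa.index(t)])
    pairs = []
    for i in range(config.n_assoc_taxa):
        sign = 1 if i % 2 == 0 else -1
        pairs.append((order[i], _COMPOUNDS[i % 4], sign))
    return pairs


def metadata_for(config: SynthConfig) -> SampleMetadata:
    groups = config.groups()
    rows = [
        {"sample_id": f"{g}{r + 1}", "group": g, "replicate": r + 1}
        for g in groups
        for r in range(config.n_reps)
    ]
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(frame)


def generate_tree(taxa: list[str], seed: int) -> TreeNode:
    """Random rooted binary tree over ``taxa`` with exponential branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; branch
    lengths are Exponential with mean 0.1.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    rng = np.random.default_rng([seed, 13])
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1))) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_compounds(
    table: AbundanceTable, truth: SynthTruth, config: SynthConfig
) -> CompoundTable:
    """Alkaloid contents (mg/g) with planted monotone taxon links.

    Linked compounds follow a log-normal whose latent Gaussian is
    correlated (via the copula map) with the normal scores of the taxon's
    relative abundance; unlinked compounds are independent log-normals.
    TOTAL is the exact row sum of the four components.
    """
    config.validate()
    for taxon, compound, _ in truth.assoc_pairs:
        if taxon not in table.taxon_ids:
            raise ValueError(f"assoc pair references unknown taxon {taxon!r}")
        if compound not in _COMPOUNDS:
            raise ValueError(f"assoc pair references unknown compound {compound!r}")
    rng = np.random.default_rng([config.seed, 17])
    n = len(table.sample_ids)
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)

    from scipy.stats import norm, rankdata

    by_compound: dict[str, list[tuple[str, int]]] = {}
    for taxon, compound, sign in truth.assoc_pairs:
        by_compound.setdefault(compound, []).append((taxon, sign))

    cols = {}
    for compound in _COMPOUNDS:
        eps = rng.normal(0.0, 1.0, size=n)
        links = by_compound.get(compound, [])
        if links:
            u = np.zeros(n)
            for taxon, sign in links:
                ranks = rankdata(rel[taxon].to_numpy())
                u += sign * norm.ppf(ranks / (n + 1))
            u /= math.sqrt(len(links)) * np.std(norm.ppf(rankdata(np.arange(n)) / (n + 1)))
            r = abs(_latent_corr(config.assoc_rho))
            g = r * u + math.sqrt(max(1.0 - r * r, 0.0)) * eps
        else:
            g = eps
        cols[compound] = _COMPOUND_SCALE[compound] * np.exp(_COMPOUND_SIGMA * g)

    frame = pd.DataFrame(cols, index=table.sample_ids)
    frame["TOTAL"] = frame[list(_COMPOUNDS)].sum(axis=1)
    return CompoundTable(frame)


def generate_dataset(config: SynthConfig):
    """Convenience: community, metadata, tree, compounds, truth in one call."""
    table, truth = generate_community(config)
    meta = metadata_for(config)
    tree = generate_tree(table.taxon_ids, config.seed)
    compounds = generate_compounds(table, truth, config)
    return table, meta, tree, compounds, truth
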