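"""End-to-end orchestration: load or synthesize a dataset, normalize depth,
then run diversity, composition, network, core-microbiome and association
stages, writing a self-describing report bundle plus a manifest.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so any stage can be
re-run in isolation and still reproduce the full-pipeline output.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, alpha, association, beta, composition, io, network, synth

STAGE_SEEDS = {"synth": 0, "rarefy": 1, "anosim": 2, "modularity": 3}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def combine_cores(membership: list[str], hubs: list[str]) -> list[str]:
    """Combined core microbiome: union of the membership and hub rules."""
    return sorted(set(membership) | set(hubs))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([seed, STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (paths) or ``synth`` must be supplied."""

    seed: int
    out_dir: str | Path
    inputs: dict | None = None       # keys: abundance, metadata, tree, compounds
    synth: synth.SynthConfig | None = None
    edge_rule: network.EdgeRule = field(default_factory=network.EdgeRule)
    hub_rule: network.HubRule = field(default_factory=network.HubRule)
    top_n: int = 10
    heatmap_n: int = 50
    n_perm: int = 999
    min_prevalence: int = 3
    beta_metric: str = "wunifrac"  # metric for PCoA + ANOSIM

    def validate(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise PipelineError(
                "config: supply exactly one of input paths or a synth config"
            )
        if self.inputs is not None:
            missing = {"abundance", "metadata"} - set(self.inputs)
            if missing:
                raise PipelineError(f"config: missing input paths {sorted(missing)}")
            if self.beta_metric == "wunifrac" and "tree" not in self.inputs:
                raise PipelineError(
                    "config: weighted UniFrac requested but no tree supplied"
                )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load(config: PipelineConfig):
    if config.synth is not None:
        cfg = config.synth
        table, meta, tree, compounds, truth = synth.generate_dataset(cfg)
        return table, meta, tree, compounds, truth
    paths = config.inputs
    table = io.read_abundance(paths["abundance"])
    meta = io.read_metadata(paths["metadata"])
    tree = io.read_tree(paths["tree"]) if "tree" in paths else None
    compounds = io.read_compounds(paths["compounds"]) if "compounds" in paths else None
    return table, meta, tree, compounds, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- load / synthesize -------------------------------------------------
    try:
        if config.synth is not None and config.synth.seed != stage_seed(seed, "synth"):
            config.synth.seed = stage_seed(seed, "synth")
        raw_table, meta, tree, compounds, truth = _load(config)
        io.write_abundance(raw_table, out / "abundance_raw.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        if tree is not None:
            io.write_tree(tree, out / "tree.nwk")
        if compounds is not None:
            io.write_compounds(compounds, out / "compounds.tsv")
        if truth is not None:
            truth.to_json(out / "synth_truth.json")
    except PipelineError:
        raise
    except Exception as exc:
        fail("load", exc)

    # --- depth normalization ----------------------------------------------
    try:
        table = io.normalize_to_min_depth(raw_table, seed=stage_seed(seed, "rarefy"))
        io.write_abundance(table, out / "abundance_normalized.tsv")
    except Exception as exc:
        fail("normalize", exc)

    # --- alpha diversity ---------------------------------------------------
    try:
        alpha_df = alpha.alpha_table(table, tree)
        alpha_df.to_csv(out / "alpha.tsv", sep="\t", index_label="sample_id")
    except Exception as exc:
        fail("alpha", exc)

    # --- beta diversity ----------------------------------------------------
    try:
        bc = beta.bray_curtis(table)
        pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)).to_csv(
            out / "braycurtis.tsv", sep="\t", index_label="sample_id"
        )
        (out / "upgma_braycurtis.nwk").write_text(beta.upgma(bc).to_newick() + "\n")
        if tree is not None:
            wu = beta.weighted_unifrac(table, tree)
            pd.DataFrame(wu.data, index=list(wu.ids), columns=list(wu.ids)).to_csv(
                out / "wunifrac.tsv", sep="\t", index_label="sample_id"
            )
        dm = wu if (config.beta_metric == "wunifrac" and tree is not None) else bc
        ord_res = beta.pcoa(dm)
        ord_res.coordinates.to_csv(out / "ordination.tsv", sep="\t", index_label="sample_id")
        _write_json(
            {
                "metric": config.beta_metric,
                "eigenvalues": ord_res.eigenvalues.tolist(),
                "proportion_explained": ord_res.proportion_explained.tolist(),
            },
            out / "ordination_eigen.json",
        )
        groups = meta.groups_for(table.sample_ids)
        sep = beta.anosim(dm, groups, n_perm=config.n_perm, seed=stage_seed(seed, "anosim"))
        _write_json(
            {"R": sep.statistic, "p": sep.p, "n_perm": sep.n_perm, "metric": config.beta_metric},
            out / "anosim.json",
        )
    except Exception as exc:
        fail("beta", exc)

    # --- composition -------------------------------------------------------
    try:
        venn = composition.venn_sets(table, meta)
        _write_json(
            {
                "shared": sorted(venn.shared),
                "unique_counts": venn.unique_counts,
                "group_sizes": {g: len(s) for g, s in venn.group_sets.items()},
            },
            out / "venn.json",
        )
        heat = composition.top_abundance_matrix(table, meta, n=min(config.heatmap_n, len(table.taxon_ids)))
        heat.to_csv(out / "heatmap_matrix.tsv", sep="\t", index_label="group")
        members = composition.membership_core(table, top_n=config.top_n)
    except Exception as exc:
        fail("composition", exc)

    # --- network -----------------------------------------------------------
    try:
        rho, pmat = network.spearman_matrix(table, min_prevalence=config.min_prevalence)
        net = network.build_network(rho, pmat, config.edge_rule)
        network.annotate_network(net, table)
        topo = network.topology(net, seed=stage_seed(seed, "modularity"))
        _write_json(topo.to_dict(), out / "topology.json")
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
                for u, v, d in net.edges(data=True)
            ],
            columns=["source", "target", "rho", "p", "sign"],
        )
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        if net.number_of_nodes() >= 2:
            network.centralities(net).to_csv(out / "centralities.tsv", sep="\t", index_label="taxon")
        import networkx as nx

        nx.write_graphml(net, out / "network.graphml")
        hubs = network.hub_core(net, config.hub_rule)
    except Exception as exc:
        fail("network", exc)

    # --- core set ----------------------------------------------------------
    combined = combine_cores(members, hubs)
    _write_json(
        {
            "membership_core": members,
            "hub_core": hubs,
            "combined": combined,
            "rule_params": {
                "top_n": config.top_n,
                **asdict(config.edge_rule),
                **asdict(config.hub_rule),
            },
        },
        out / "core_set.json",
    )

    # --- association -------------------------------------------------------
    if compounds is not None:
        try:
            comparison = association.compare_groups(compounds, meta)
            comparison.anova.to_csv(out / "compound_anova.tsv", sep="\t", index_label="compound")
            comparison.means.to_csv(out / "compound_means.tsv", sep="\t", index_label="group")
            comparison.letters.to_csv(out / "compound_letters.tsv", sep="\t", index_label="group")
            assoc = association.core_compound_spearman(table, compounds, combined)
            assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        except Exception as exc:
            fail("association", exc)

    # --- manifest ----------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "endocore_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "stage_seeds": {k: stage_seed(seed, k) for k in STAGE_SEEDS},
        "parameters": {
            "top_n": config.top_n,
            "heatmap_n": config.heatmap_n,
            "n_perm": config.n_perm,
            "min_prevalence": config.min_prevalence,
            "beta_metric": config.beta_metric,
            "edge_rule": asdict(config.edge_rule),
            "hub_rule": asdict(config.hub_rule),
            "synth": asdict(config.synth) if config.synth else None,
            "inputs": {k: str(v) for k, v in config.inputs.items()} if config.inputs else None,
        },
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
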