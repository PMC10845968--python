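#!/usr/bin/env python
"""Generate the two synthetic surveys the downstream analyses consume.

Emulates the study design: a developmental-stage survey (adult, flowering,
podding, mature; A/F/P/M) and an organ survey at maturity (roots, stems,
leaves, seeds; R/St/L/S), each 4 groups x 3 replicates, with planted
correlated cliques (future network hubs), planted taxon-compound links,
and mild group-level succession structure.  Everything downstream is
reproducible from the seeds printed here.
"""

from pathlib import Path

from endocore import io, synth

OUT = Path("results/analysis")

SURVEYS = {
    "stages": synth.SynthConfig(
        n_taxa=60, depth=50_000, n_hub_cliques=2, clique_size=5, clique_rho=0.9,
        n_assoc_taxa=3, assoc_rho=0.8, group_sigma=0.8, seed=20240501,
    ),
    "organs": synth.SynthConfig(
        n_taxa=60, depth=50_000, n_hub_cliques=2, clique_size=5, clique_rho=0.9,
        n_assoc_taxa=3, assoc_rho=0.8, group_sigma=0.8, seed=20240502,
        group_names=("R", "St", "L", "S"),
    ),
}


def main() -> None:
    for name, cfg in SURVEYS.items():
        table, meta, tree, compounds, truth = synth.generate_dataset(cfg)
        out = OUT / "data" / name
        io.write_abundance(table, out / "abundance.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_tree(tree, out / "tree.nwk")
        io.write_compounds(compounds, out / "compounds.tsv")
        truth.to_json(out / "truth.json")
        print(
            f"{name}: {len(table.sample_ids)} samples x {len(table.taxon_ids)} taxa "
            f"at depth {cfg.depth}; planted hub taxa: {sorted(truth.hub_taxa)}; "
            f"planted links: {truth.assoc_pairs}"
        )


if __name__ == "__main__":
    main()
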