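#!/usr/bin/env python
"""Alpha and beta diversity per survey: per-sample indices and group
means, Bray-Curtis + weighted UniFrac distances, UPGMA clustering, PCoA
and the ANOSIM group-separation test."""

from pathlib import Path

import pandas as pd

from endocore import io
from endocore.alpha import alpha_table
from endocore.beta import anosim, bray_curtis, pcoa, upgma, weighted_unifrac

OUT = Path("results/analysis")
SEED = 20240510


def main() -> None:
    for name in ("stages", "organs"):
        data = OUT / "data" / name
        table = io.read_abundance(data / "abundance.tsv")
        table = io.normalize_to_min_depth(table, seed=SEED)
        meta = io.read_metadata(data / "metadata.tsv")
        tree = io.read_tree(data / "tree.nwk")
        groups = meta.groups_for(table.sample_ids)

        alpha = alpha_table(table, tree)
        alpha.to_csv(OUT / f"alpha_{name}.tsv", sep="\t")
        print(f"\n== {name}: group-mean alpha indices ==")
        print(alpha.groupby(groups).mean().round(3).to_string())

        bc = bray_curtis(table)
        wu = weighted_unifrac(table, tree)
        for metric, dm in (("braycurtis", bc), ("wunifrac", wu)):
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                OUT / f"dm_{metric}_{name}.tsv", sep="\t"
            )
        (OUT / f"upgma_{name}.nwk").write_text(upgma(bc).to_newick() + "\n")

        res = pcoa(wu)
        res.coordinates.to_csv(OUT / f"pcoa_{name}.tsv", sep="\t")
        pc1, pc2 = res.proportion_explained[:2]
        sep = anosim(wu, groups, n_perm=999, seed=SEED)
        print(
            f"PCoA (weighted UniFrac): PC1 {100*pc1:.2f}%, PC2 {100*pc2:.2f}%; "
            f"ANOSIM R = {sep.statistic:.4f}, P = {sep.p:.4f}"
        )


if __name__ == "__main__":
    main()
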