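#!/usr/bin/env python
"""Community composition per survey: shared/unique genera across groups
(Venn sets), the top-taxon heatmap matrix, and the membership-rule core
microbiome (present in every sample, top-10 by mean relative abundance)."""

import json
from pathlib import Path

from endocore import io
from endocore.composition import membership_core, top_abundance_matrix, venn_sets

OUT = Path("results/analysis")
SEED = 20240510


def main() -> None:
    for name in ("stages", "organs"):
        data = OUT / "data" / name
        table = io.normalize_to_min_depth(
            io.read_abundance(data / "abundance.tsv"), seed=SEED
        )
        meta = io.read_metadata(data / "metadata.tsv")

        venn = venn_sets(table, meta)
        (OUT / f"venn_{name}.json").write_text(json.dumps({
            "shared": sorted(venn.shared),
            "unique_counts": venn.unique_counts,
            "group_sizes": {g: len(s) for g, s in venn.group_sets.items()},
        }, indent=2))
        print(f"\n== {name} ==")
        print(f"{len(venn.shared)} genera shared by all groups; "
              f"unique per group: {venn.unique_counts}")

        heat = top_abundance_matrix(table, meta, n=20)
        heat.to_csv(OUT / f"heatmap_top20_{name}.tsv", sep="\t")
        dominant = heat.drop(columns="other").idxmax(axis=1)
        for group, taxon in dominant.items():
            print(f"dominant genus in {group}: {taxon} "
                  f"({100*heat.at[group, taxon]:.1f}% mean relative abundance)")

        core = membership_core(table, top_n=10)
        (OUT / f"membership_core_{name}.json").write_text(json.dumps(core, indent=2))
        print(f"membership core (top-10, present in all samples): {core}")


if __name__ == "__main__":
    main()
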