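#!/usr/bin/env python
"""Spearman association of the combined core microbiome with alkaloid
contents, starred at raw p < 0.05 (*) and p < 0.01 (**), and recovery of
the planted taxon-compound links."""

import json
from pathlib import Path

from endocore import io
from endocore.association import association_pivot, core_compound_spearman

OUT = Path("results/analysis")
SEED = 20240510


def main() -> None:
    for name in ("stages", "organs"):
        data = OUT / "data" / name
        table = io.normalize_to_min_depth(
            io.read_abundance(data / "abundance.tsv"), seed=SEED
        )
        compounds = io.read_compounds(data / "compounds.tsv")
        core = json.loads((OUT / f"core_set_{name}.json").read_text())["combined"]
        truth = json.loads((data / "truth.json").read_text())

        frame = core_compound_spearman(table, compounds, core)
        frame.to_csv(OUT / f"association_{name}.tsv", sep="\t", index=False)
        starred = frame[frame.star != ""]
        print(f"\n== {name}: core-taxon x compound Spearman ==")
        print(association_pivot(frame).round(2).to_string())
        print(f"{len(starred)}/{len(frame)} pairs starred:")
        for _, row in starred.iterrows():
            print(f"  {row.taxon} ~ {row.compound}: rho {row.rho:.2f} {row.star}")
        planted = {(t, c) for t, c, _ in map(tuple, truth["assoc_pairs"])}
        recovered = planted & {(r.taxon, r.compound) for _, r in starred.iterrows()}
        print(f"planted links recovered among starred pairs: "
              f"{len(recovered)}/{len(planted & {(r.taxon, r.compound) for _, r in frame.iterrows()})} "
              f"(planted taxa in the core set: "
              f"{sorted({t for t, _ in planted} & set(core))})")


if __name__ == "__main__":
    main()
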