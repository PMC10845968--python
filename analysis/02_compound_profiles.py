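#!/usr/bin/env python
"""Alkaloid content profiles per group: ANOVA + Tukey letters and the
largest between-group fold changes, per survey."""

import itertools
from pathlib import Path

from endocore import io
from endocore.association import compare_groups, fold_change

OUT = Path("results/analysis")


def main() -> None:
    for name in ("stages", "organs"):
        data = OUT / "data" / name
        compounds = io.read_compounds(data / "compounds.tsv")
        meta = io.read_metadata(data / "metadata.tsv")
        res = compare_groups(compounds, meta)
        res.means.to_csv(OUT / f"compound_means_{name}.tsv", sep="\t")
        res.anova.to_csv(OUT / f"compound_anova_{name}.tsv", sep="\t")
        res.letters.to_csv(OUT / f"compound_letters_{name}.tsv", sep="\t")
        print(f"\n== {name}: group means (mg/g) ==")
        print(res.means.round(1).to_string())
        sig = res.anova[res.anova["p"] < 0.05].index.tolist()
        print(f"compounds differing between groups at 0.05: {sig}")
        groups = list(res.means.index)
        for compound in ("OMA", "OSC", "SC", "MA"):
            best = max(
                itertools.permutations(groups, 2),
                key=lambda ab: fold_change(compounds, meta, compound, *ab)[0],
            )
            full, rounded = fold_change(compounds, meta, compound, *best)
            print(f"largest {compound} fold change: {best[0]}/{best[1]} = {rounded}")


if __name__ == "__main__":
    main()
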