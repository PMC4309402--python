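#!/usr/bin/env python
"""Direction-of-change summaries: the fraction of metabolites elevated in
AggE per superpathway and subpathway, with one-sided exact binomial tests
against a 50/50 null, plus the acute-vs-chronic two-proportion contrast for
the carbohydrate superpathway.

Reads results/sim/; writes results/direction/.
"""

from pathlib import Path

from stressmet import canonical_comparisons, load_design, load_matrix, load_pathways, scale_and_impute, write_table
from stressmet.direction import (
    direction_profiles,
    equal_proportions_test,
    pathway_direction_scan,
)

SIM = Path("results/sim")
OUT = Path("results/direction")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = scale_and_impute(load_matrix(SIM / "matrix.tsv"))
    design = load_design(SIM / "design.tsv")
    pathways = load_pathways(SIM / "pathways.tsv")
    profiles = direction_profiles(matrix, canonical_comparisons(design))
    for level in ("superpathway", "subpathway"):
        scan = pathway_direction_scan(profiles, pathways, level=level)
        write_table(scan, OUT / f"{level}.tsv", index=False)
        n05 = int(scan["flag_05"].sum())
        print(f"{level}: {n05} (grouping x comparison) rows at p<=0.05 of {len(scan)}")

    sup = pathway_direction_scan(profiles, pathways, level="superpathway")
    carb = sup[sup["grouping"] == "Carbohydrate"].set_index("comparison")
    acute = carb.loc["AggE_vs_Ctrl|10day|acute"]
    chronic = carb.loc["AggE_vs_Ctrl|10day|chronic"]
    p = equal_proportions_test(int(acute["n_up"]), int(acute["n_members"]),
                               int(chronic["n_up"]), int(chronic["n_members"]))
    print(f"carbohydrates up in AggE (10-day): {acute['fraction_up']:.0%} acutely vs "
          f"{chronic['fraction_up']:.0%} chronically; equal-proportions p = {p:.3f}")


if __name__ == "__main__":
    main()
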