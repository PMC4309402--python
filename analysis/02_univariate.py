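#!/usr/bin/env python
"""Per-metabolite Welch tests and two-way ANOVA across the eight canonical
comparisons of the simulated study; reports how many metabolites are
altered at p <= 0.05 in each comparison.

Reads results/sim/ (run analysis/01_simulate.py first); writes
results/univariate/.
"""

from pathlib import Path

import pandas as pd

from stressmet import canonical_comparisons, load_design, load_matrix, scale_and_impute, write_table
from stressmet.univariate import anova_all, compare_all

SIM = Path("results/sim")
OUT = Path("results/univariate")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = scale_and_impute(load_matrix(SIM / "matrix.tsv"))
    design = load_design(SIM / "design.tsv")
    frames = []
    for spec in canonical_comparisons(design):
        tab = compare_all(matrix, spec)
        frames.append(tab.reset_index())
        print(f"{spec.label:32s} {tab.attrs['n_significant']:3d} metabolites at p<=0.05")
    write_table(pd.concat(frames, ignore_index=True), OUT / "welch.tsv", index=False)
    av = anova_all(matrix, design)
    write_table(av, OUT / "anova.tsv", index_label="metabolite_id")
    n_inter = int((av["p_interaction"] <= 0.05).sum())
    print(f"two-way ANOVA: {n_inter} metabolites with treatment x time "
          f"interaction at p<=0.05 -> {OUT}/")


if __name__ == "__main__":
    main()
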