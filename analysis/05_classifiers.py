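#!/usr/bin/env python
"""Biomarker workflow on the simulated study: random-forest MDA ranking of
AggE-vs-Ctrl at acute and chronic time points, top-decile overlap between
the two lists, candidate consolidation, and exhaustive DD-KNN / rule-based
panel searches with leave-one-out evaluation.

Reads results/sim/; writes results/classifiers/.
"""

from pathlib import Path

import pandas as pd

from stressmet import MetaboliteMatrix, load_design, load_matrix, scale_and_impute, write_table
from stressmet.classifiers import (
    METHODS,
    candidate_pipeline,
    ddknn_panel_search,
    overlap_fisher,
    perfect_classifier_scan,
    rf_mda_rank,
    rule_panel_search,
    top_fraction,
    univariate_scores,
)

SIM = Path("results/sim")
OUT = Path("results/classifiers")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = scale_and_impute(load_matrix(SIM / "matrix.tsv"))
    design = load_design(SIM / "design.tsv")

    lists = {}
    for timepoint in ("acute", "chronic"):
        samples = design.table.index[design.table["timepoint"] == timepoint]
        sub = MetaboliteMatrix(matrix.data.loc[samples])
        labels = design.table.loc[samples, "treatment"]
        mda = rf_mda_rank(sub, labels, n_trees=200, seed=SEED)
        write_table(mda, OUT / f"mda_{timepoint}.tsv", meta={"seed": SEED}, index=False)
        lists[timepoint] = top_fraction(mda, 0.10)
        print(f"{timepoint}: top decile = {len(lists[timepoint])} metabolites; "
              f"best: {', '.join(mda['metabolite_id'].iloc[:3])}")

    overlap, p = overlap_fisher(matrix.shape[1], lists["acute"], lists["chronic"])
    print(f"top-decile overlap acute vs chronic: {overlap} metabolites, "
          f"hypergeometric p = {p:.3g}")

    acute = design.table.index[design.table["timepoint"] == "acute"]
    sub = MetaboliteMatrix(matrix.data.loc[acute])
    labels = design.table.loc[acute, "treatment"]
    perfect = perfect_classifier_scan(sub, labels)
    print(f"perfect classifiers at the acute time point: "
          f"{', '.join(perfect['metabolite_id']) or 'none'}")

    tables = {m: univariate_scores(sub, labels, m) for m in METHODS[1:]}
    scores = pd.concat(tables.values(), ignore_index=True)
    write_table(scores, OUT / "scores_acute.tsv", index=False)
    candidates = candidate_pipeline(sub, labels, score_tables=tables)
    mda_acute = rf_mda_rank(sub, labels, n_trees=200, seed=SEED)
    keep = mda_acute[mda_acute["metabolite_id"].isin(candidates)]
    candidates = list(keep.sort_values("rank")["metabolite_id"].iloc[:15])
    print(f"{len(candidates)} consolidated candidates")

    rows = []
    for name, search in (("ddknn", ddknn_panel_search), ("rule", rule_panel_search)):
        best = search(sub, labels, candidates, max_panel=2)
        for size, r in sorted(best.items()):
            if size == 0:
                continue
            rows.append({"classifier": name, "panel_size": size,
                         "members": ";".join(r.members),
                         "sensitivity": r.sensitivity, "specificity": r.specificity})
        top = best[0]
        print(f"{name}: best panel {top.members} LOO sensitivity "
              f"{top.sensitivity:.1%}, specificity {top.specificity:.1%}")
    write_table(pd.DataFrame(rows), OUT / "panels.tsv", index=False)


if __name__ == "__main__":
    main()
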