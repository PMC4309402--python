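"""Per-metabolite group comparisons.

Welch's unequal-variance t-test and a 2 x 2 two-way ANOVA (treatment, time,
interaction; Type-II sums of squares) are computed on natural-log
intensities; fold change is the ratio of arithmetic group means on the
original scale, matching how vendor reports pair an "FC" column with test
p-values.  Benjamini-Hochberg step-up q-values control the FDR across
metabolites within a comparison.

Metabolites that cannot support a test (too few observed values, constant
data, or observed in fewer than half the samples of a compared group) are
reported with a reason code rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .core import ComparisonSpec, MetaboliteMatrix, SampleDesign

MIN_OBSERVED_FRACTION = 0.5


@dataclass(frozen=True)
class AnovaResult:
    metabolite_id: str
    p_treatment: float
    p_time: float
    p_interaction: float
    untestable: str = ""


def welch_t(a, b) -> tuple[float, float]:
    """Welch's t with Satterthwaite df; returns (t, two-sided p).

    Degenerate inputs follow fixed conventions: both groups constant with
    equal means -> (0, 1); both constant with different means -> (+-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_two_way(values: pd.Series, design: SampleDesign) -> AnovaResult:
    """Two-way ANOVA of log intensity on treatment x timepoint (Type II).

    ``values`` is indexed by sample id on the original scale; regimens are
    pooled (the 2 x 2 layout is treatment x time).  Requires >= 2 observed
    samples in each of the four cells; degenerate inputs return an
    untestable marker instead of raising.
    """
    name = str(values.name) if values.name is not None else "metabolite"
    df = design.table.loc[values.index].copy()
    df["y"] = np.log(values.to_numpy(dtype=float))
    df = df.dropna(subset=["y"])
    counts = df.groupby(["treatment", "timepoint"], observed=True)["y"].count()
    if len(counts) < 4 or counts.min() < 2:
        return AnovaResult(name, np.nan, np.nan, np.nan, untestable="empty_cell")
    if df["y"].nunique() == 1:
        return AnovaResult(name, np.nan, np.nan, np.nan, untestable="constant")
    fit = ols("y ~ C(treatment) * C(timepoint)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    return AnovaResult(
        name,
        float(tab.loc["C(treatment)", "PR(>F)"]),
        float(tab.loc["C(timepoint)", "PR(>F)"]),
        float(tab.loc["C(treatment):C(timepoint)", "PR(>F)"]),
    )


def anova_all(matrix: MetaboliteMatrix, design: SampleDesign) -> pd.DataFrame:
    rows = [anova_two_way(matrix.data[m], design) for m in matrix.metabolite_ids]
    return pd.DataFrame(rows).set_index("metabolite_id")


def compare_all(matrix: MetaboliteMatrix, spec: ComparisonSpec,
                alpha: float = 0.05) -> pd.DataFrame:
    """Welch-test every metabolite for one comparison.

    Returns a table with fold_change (A/B, original scale), p_welch, q_bh,
    direction, group sizes and an ``untestable`` reason code (empty for
    testable rows).  q-values are computed over testable rows only.
    The number of testable rows with p <= ``alpha`` is available as
    ``result.attrs["n_significant"]``.
    """
    rows = []
    for m in matrix.metabolite_ids:
        col = matrix.data[m]
        a = col.reindex(list(spec.group_a)).dropna().to_numpy()
        b = col.reindex(list(spec.group_b)).dropna().to_numpy()
        rec = {
            "metabolite_id": m, "comparison": spec.label,
            "n_A": len(a), "n_B": len(b),
            "fold_change": np.nan, "p_welch": np.nan, "q_bh": np.nan,
            "direction": "", "untestable": "",
        }
        if len(a) < 2 or len(b) < 2:
            rec["untestable"] = "too_few_observed"
        elif (len(a) < MIN_OBSERVED_FRACTION * len(spec.group_a)
              or len(b) < MIN_OBSERVED_FRACTION * len(spec.group_b)):
            rec["untestable"] = "high_missingness"
        elif a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
            rec.update(fold_change=1.0, p_welch=1.0, direction="down")
        else:
            _, p = welch_t(np.log(a), np.log(b))
            fc = a.mean() / b.mean()
            rec.update(fold_change=fc, p_welch=p,
                       direction="up" if fc > 1 else "down")
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("metabolite_id")
    ok = out["untestable"] == ""
    if ok.any():
        out.loc[ok, "q_bh"] = bh_fdr(out.loc[ok, "p_welch"].to_numpy())
    out.attrs["n_significant"] = int((out.loc[ok, "p_welch"] <= alpha).sum())
    return out
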