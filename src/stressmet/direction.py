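"""Direction-of-change coding and pathway-level count tests.

Each metabolite gets an 8-bit direction profile across the study's eight
canonical comparisons: bit = 1 when the metabolite's mean intensity is
higher in group A (AggE for treatment comparisons, acute for time
comparisons).  Pathway-level questions are then count questions:

* exact binomial test of k-of-n metabolites moving the same way against a
  fair-coin null (the workhorse behind the superpathway and subpathway
  summaries);
* two-proportion z-test (pooled variance, Yates continuity correction)
  comparing the fraction elevated between two time points.

The binomial default is the one-sided tail P(X >= max(k, n-k)); the
two-sided variant doubles that tail (capped at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ComparisonSpec, MetaboliteMatrix, PathwayMap

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEMBERS = 3


def direction_profiles(matrix: MetaboliteMatrix,
                       specs: list[ComparisonSpec]) -> pd.DataFrame:
    """8-bit up/down profile per metabolite.

    Bit = 1 iff the observed group-A mean exceeds the group-B mean; exact
    ties are coded 0 and flagged in the ``n_ties`` column.  Metabolites whose
    mean cannot be computed in some comparison (no observed values in a
    group) are excluded and logged.
    """
    data = matrix.data
    bits = {}
    ties = {}
    dropped = []
    means = {}
    for spec in specs:
        ma = data.reindex(list(spec.group_a)).mean(axis=0, skipna=True)
        mb = data.reindex(list(spec.group_b)).mean(axis=0, skipna=True)
        means[spec.label] = (ma, mb)
    for m in matrix.metabolite_ids:
        row = []
        n_tie = 0
        ok = True
        for spec in specs:
            ma, mb = means[spec.label][0][m], means[spec.label][1][m]
            if np.isnan(ma) or np.isnan(mb):
                ok = False
                break
            if ma == mb:
                n_tie += 1
                row.append(0)
            else:
                row.append(int(ma > mb))
        if not ok:
            dropped.append(m)
            continue
        bits[m] = row
        ties[m] = n_tie
    if dropped:
        logger.warning("excluded %d metabolite(s) with incomputable group means: %s",
                       len(dropped), dropped[:5])
    out = pd.DataFrame.from_dict(bits, orient="index",
                                 columns=[s.label for s in specs]).astype(int)
    out["n_ties"] = pd.Series(ties)
    if out["n_ties"].sum():
        logger.info("tie-coded %d (metabolite, comparison) pair(s) as 0",
                    int(out["n_ties"].sum()))
    return out


def profile_bits(profiles: pd.DataFrame) -> pd.DataFrame:
    """The bare 8-column bit table (drops bookkeeping columns)."""
    return profiles.drop(columns=[c for c in ("n_ties",) if c in profiles.columns])


def binomial_direction_test(k_up: int, n: int, sided: str = "one") -> float:
    """Exact binomial test of k_up-of-n against a 50/50 null.

    One-sided: P(X >= max(k_up, n - k_up)) under Binomial(n, 1/2) — the tail
    for the observed majority direction.  Two-sided: twice that, capped at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k_up <= n:
        raise ValueError("k_up must be in [0, n]")
    k = max(k_up, n - k_up)
    p_one = float(stats.binom.sf(k - 1, n, 0.5))
    if sided == "one":
        return min(p_one, 1.0)
    if sided == "two":
        return min(2.0 * p_one, 1.0)
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def equal_proportions_test(k1: int, n1: int, k2: int, n2: int,
                           yates: bool = True) -> float:
    """Two-sided pooled-variance z-test that two proportions are equal.

    With ``yates`` the absolute difference is reduced by (1/n1 + 1/n2)/2
    before standardising (floored at 0) — the continuity correction used by
    R's ``prop.test``.  Degenerate pooled proportions (all 0 or all 1)
    return p = 1 by convention.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    diff = abs(p1 - p2)
    if yates:
        diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = diff / se
    return float(2.0 * stats.norm.sf(z))


@dataclass(frozen=True)
class DirectionSummary:
    grouping: str
    comparison: str
    n_members: int
    n_up: int
    fraction_up: float
    p_binomial: float


def pathway_direction_scan(profiles: pd.DataFrame, pathway_map: PathwayMap,
                           level: str = "subpathway",
                           comparisons: list[str] | None = None,
                           sided: str = "one",
                           min_members: int = DEFAULT_MIN_MEMBERS) -> pd.DataFrame:
    """Binomial direction test per (pathway grouping x comparison).

    ``level`` selects superpathway or subpathway groupings; groupings with
    fewer than ``min_members`` profiled metabolites are skipped (they cannot
    reach p <= 0.1).  Output flags significance at p <= 0.05 and p <= 0.1.
    """
    if level not in ("superpathway", "subpathway"):
        raise ValueError("level must be 'superpathway' or 'subpathway'")
    bits = profile_bits(profiles)
    if comparisons is None:
        comparisons = list(bits.columns)
    members = (pathway_map.subpathway_members() if level == "subpathway"
               else pathway_map.superpathway_members())
    rows = []
    for grouping in sorted(members):
        ids = [m for m in members[grouping] if m in bits.index]
        n = len(ids)
        if n < min_members:
            continue
        sub = bits.loc[ids, comparisons]
        for comp in comparisons:
            k = int(sub[comp].sum())
            p = binomial_direction_test(k, n, sided=sided)
            rows.append({
                "grouping": grouping, "comparison": comp,
                "n_members": n, "n_up": k, "fraction_up": k / n,
                "p_binomial": p,
                "flag_05": p <= 0.05, "flag_10": p <= 0.1,
            })
    return pd.DataFrame(rows)
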