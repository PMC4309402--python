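"""Metabolite biomarker selection workflow.

The workflow mirrors a multi-method screen for metabolites that separate
control from aggressor-exposed mice:

1. random-forest ranking by mean decrease in out-of-bag accuracy (MDA),
   with top-decile lists compared between time points by a hypergeometric
   overlap test;
2. a scan for "perfect classifiers" — metabolites whose class value ranges
   do not overlap;
3. five univariate scores (single-node decision trees under Gini impurity
   and information gain, chi-square on a median split, two-sample
   Kolmogorov-Smirnov, and a leave-one-out nearest-centroid accuracy that
   flags near-extremum samples);
4. candidate consolidation: union of each method's top scorers, grouped by
   Pearson correlation (single linkage at r > 0.7), one representative per
   group (largest maximum intensity), expanded by correlates of the
   representatives, plus all Gini exact separators;
5. exhaustive panel search with a distance-weighted K-nearest-neighbour
   classifier (DD-KNN) and with majority-vote threshold rules, both scored
   by leave-one-out sensitivity/specificity (AggE is the positive class).

Scores and distances are computed on natural-log intensities; DD-KNN
standardises features using training-fold statistics only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .core import MetaboliteMatrix

POSITIVE_CLASS = "AggE"
NEGATIVE_CLASS = "Ctrl"
METHODS = ("rf_mda", "gini_tree", "infogain_tree", "chi2", "ks", "extremum_centroid")
EPS = 1e-9


def _check_labels(labels: pd.Series) -> np.ndarray:
    y = np.asarray([1 if v == POSITIVE_CLASS else 0 for v in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both classes")
    return y


def _rank_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Dense 1..n ranking, best score first, ties broken by metabolite id."""
    df = df.sort_values(["score", "metabolite_id"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Random-forest MDA


def rf_mda_rank(matrix: MetaboliteMatrix, labels: pd.Series,
                n_trees: int = 500, seed: int = 0) -> pd.DataFrame:
    """Permutation importance as mean decrease in out-of-bag accuracy.

    A bagged ensemble of CART trees is grown on log intensities; for each
    tree, each feature the tree actually uses is permuted among the tree's
    out-of-bag samples and the drop in OOB accuracy recorded.  The score is
    the per-feature mean drop over all trees (features a tree ignores
    contribute zero for that tree).
    """
    labels = labels.reindex(matrix.sample_ids)
    y = _check_labels(labels)
    X = np.log(matrix.data.to_numpy(dtype=float))
    if np.isnan(X).any():
        raise ValueError("matrix must be imputed before random-forest ranking")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    mda_sum = np.zeros(p)
    max_feat = max(1, int(math.sqrt(p)))
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_feat,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[boot], y[boot])
        Xo = X[oob]
        yo = y[oob]
        acc0 = float(np.mean(tree.predict(Xo) == yo))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for f in used:
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            acc_f = float(np.mean(tree.predict(Xp) == yo))
            mda_sum[f] += acc0 - acc_f
    out = pd.DataFrame({
        "metabolite_id": matrix.metabolite_ids,
        "method": "rf_mda",
        "score": mda_sum / n_trees,
    })
    return _rank_scores(out)


def top_fraction(scores: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """Best round(fraction * n) metabolites by rank (half-up rounding).

    For the 330-metabolite panel at fraction 0.10 this is exactly 33.
    """
    if scores.empty:
        raise ValueError("empty score table")
    n_sel = int(math.floor(fraction * len(scores) + 0.5))
    ranked = scores.sort_values("rank", kind="mergesort")
    return list(ranked["metabolite_id"].iloc[:n_sel])


def overlap_fisher(universe_n: int, list_a, list_b) -> tuple[int, float]:
    """Hypergeometric upper-tail P(X >= observed overlap) between two lists
    drawn from a universe of ``universe_n`` metabolites."""
    a, b = set(list_a), set(list_b)
    if len(a) > universe_n or len(b) > universe_n:
        raise ValueError("list larger than universe")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_n, len(a), len(b)))
    return overlap, min(p, 1.0)


# ---------------------------------------------------------------------------
# Univariate scores


def perfect_classifier_scan(matrix: MetaboliteMatrix,
                            labels: pd.Series) -> pd.DataFrame:
    """Metabolites whose class value ranges do not overlap.

    direction "up" means every AggE value exceeds every Ctrl value.
    """
    labels = labels.reindex(matrix.sample_ids)
    y = _check_labels(labels)
    rows = []
    for m in matrix.metabolite_ids:
        col = matrix.data[m].to_numpy(dtype=float)
        pos = col[y == 1]
        neg = col[y == 0]
        pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
        if len(pos) == 0 or len(neg) == 0:
            continue
        if pos.min() > neg.max():
            rows.append({"metabolite_id": m, "direction": "up"})
        elif pos.max() < neg.min():
            rows.append({"metabolite_id": m, "direction": "down"})
    return pd.DataFrame(rows, columns=["metabolite_id", "direction"])


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _gini(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts / tot
    return float(1.0 - (p ** 2).sum())


def _best_split(x: np.ndarray, y: np.ndarray,
                impurity) -> tuple[float, float, bool]:
    """Best single-threshold split of x: returns (impurity decrease,
    threshold, both-children-pure flag).  Thresholds are midpoints between
    adjacent distinct values."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    parent = impurity(np.bincount(ys, minlength=2).astype(float))
    best, best_thr, best_pure = 0.0, np.nan, False
    left = np.zeros(2)
    right = np.bincount(ys, minlength=2).astype(float)
    for i in range(n - 1):
        left[ys[i]] += 1
        right[ys[i]] -= 1
        if xs[i] == xs[i + 1]:
            continue
        w = (i + 1) / n
        dec = parent - w * impurity(left) - (1 - w) * impurity(right)
        if dec > best + 1e-15:
            best = dec
            best_thr = (xs[i] + xs[i + 1]) / 2
            best_pure = impurity(left) == 0.0 and impurity(right) == 0.0
    return best, best_thr, best_pure


def extremum_centroid_score(values, labels) -> float:
    """Leave-one-out nearest-centroid accuracy for one metabolite.

    Each sample is held out, class centroids (means) recomputed on the
    rest, and the held-out value assigned to the nearer centroid;
    equidistant assignments count as errors.  Returns the fraction correct.
    """
    x = np.asarray(values, dtype=float)
    y = _check_labels(pd.Series(labels))
    correct = 0
    for i in range(len(x)):
        keep = np.ones(len(x), bool)
        keep[i] = False
        xk, yk = x[keep], y[keep]
        if len(xk[yk == 1]) == 0 or len(xk[yk == 0]) == 0:
            continue
        c1, c0 = xk[yk == 1].mean(), xk[yk == 0].mean()
        d1, d0 = abs(x[i] - c1), abs(x[i] - c0)
        if d1 == d0:
            continue  # equidistant -> counted incorrect
        pred = 1 if d1 < d0 else 0
        correct += int(pred == y[i])
    return correct / len(x)


def near_extremum_samples(values, frac: float = 0.05) -> list[int]:
    """Indices of samples within ``frac`` of the value range's extremes
    (reported alongside the centroid score; no algorithmic role)."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    span = hi - lo
    if span == 0:
        return []
    return [int(i) for i in np.where((x <= lo + frac * span) | (x >= hi - frac * span))[0]]


def univariate_scores(matrix: MetaboliteMatrix, labels: pd.Series,
                      method: str) -> pd.DataFrame:
    """Score every metabolite with one of the five univariate methods.

    gini_tree / infogain_tree: best single-threshold split quality on log
    intensity (impurity decrease / information gain in bits), with the
    threshold and an exact-separator flag recorded.  chi2: Yates-corrected
    chi-square statistic of the 2x2 table from a median split.  ks:
    two-sample Kolmogorov-Smirnov statistic.  extremum_centroid: LOO
    nearest-centroid accuracy.  Constant metabolites score 0.
    """
    if method not in METHODS[1:]:
        raise ValueError(f"method must be one of {METHODS[1:]}")
    labels = labels.reindex(matrix.sample_ids)
    y = _check_labels(labels)
    rows = []
    for m in matrix.metabolite_ids:
        raw = matrix.data[m].to_numpy(dtype=float)
        ok = ~np.isnan(raw)
        x, yy = np.log(raw[ok]), y[ok]
        rec = {"metabolite_id": m, "method": method, "score": 0.0,
               "threshold": np.nan, "exact_separator": False}
        if len(np.unique(x)) > 1 and len(np.unique(yy)) == 2:
            if method in ("gini_tree", "infogain_tree"):
                imp = _gini if method == "gini_tree" else _entropy
                score, thr, pure = _best_split(x, yy, imp)
                rec.update(score=score, threshold=thr, exact_separator=pure)
            elif method == "chi2":
                med = np.median(x)
                hi = x > med
                table = np.array([
                    [np.sum(hi & (yy == 1)), np.sum(~hi & (yy == 1))],
                    [np.sum(hi & (yy == 0)), np.sum(~hi & (yy == 0))],
                ])
                if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                    chi2 = stats.chi2_contingency(table, correction=True)[0]
                    rec.update(score=float(chi2))
            elif method == "ks":
                rec.update(score=float(stats.ks_2samp(x[yy == 1], x[yy == 0]).statistic))
            else:  # extremum_centroid
                rec.update(score=extremum_centroid_score(x, labels[ok]))
        rows.append(rec)
    return _rank_scores(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Candidate consolidation


def candidate_pipeline(matrix: MetaboliteMatrix, labels: pd.Series,
                       r_thresh: float = 0.7, top_k: int = 5,
                       score_tables: dict[str, pd.DataFrame] | None = None
                       ) -> list[str]:
    """Consolidate each method's top scorers into a candidate set.

    Union of top-``top_k`` metabolites per method -> single-linkage grouping
    at Pearson r > ``r_thresh`` (log intensities) -> one representative per
    group (largest maximum raw intensity, ties by id) -> expansion with every
    metabolite correlating above the threshold with a representative -> plus
    all Gini exact separators.  Returns a sorted metabolite list.
    """
    if score_tables is None:
        score_tables = {m: univariate_scores(matrix, labels, m) for m in METHODS[1:]}
    top: set[str] = set()
    for tab in score_tables.values():
        top.update(tab.sort_values("rank")["metabolite_id"].iloc[:top_k])
    top = sorted(top)
    logm = np.log(matrix.data)
    corr_top = logm[top].corr(method="pearson")

    # single-linkage components of the r > r_thresh graph
    comp: dict[str, int] = {}
    cid = 0
    for m in top:
        if m in comp:
            continue
        stack = [m]
        comp[m] = cid
        while stack:
            cur = stack.pop()
            linked = corr_top.index[(corr_top[cur] > r_thresh) & (corr_top.index != cur)]
            for other in linked:
                if other not in comp:
                    comp[other] = cid
                    stack.append(other)
        cid += 1

    reps = []
    maxima = matrix.data.max(axis=0, skipna=True)
    for c in range(cid):
        group = [m for m in top if comp[m] == c]
        group.sort(key=lambda m: (-maxima[m], m))
        reps.append(group[0])

    # expand with correlates of the representatives over all metabolites
    candidates = set(reps)
    corr_all = logm.corr(method="pearson")
    for rep in reps:
        linked = corr_all.index[(corr_all[rep] > r_thresh) & (corr_all.index != rep)]
        candidates.update(linked)

    gini = score_tables.get("gini_tree")
    if gini is None:
        gini = univariate_scores(matrix, labels, "gini_tree")
    candidates.update(gini.loc[gini["exact_separator"], "metabolite_id"])
    return sorted(candidates)


# ---------------------------------------------------------------------------
# Panel search


@dataclass(frozen=True)
class PanelResult:
    members: tuple[str, ...]
    classifier: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    balanced_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        sens = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        spec = self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0
        object.__setattr__(self, "sensitivity", sens)
        object.__setattr__(self, "specificity", spec)
        object.__setattr__(self, "balanced_accuracy", (sens + spec) / 2)


MAX_SUBSETS = 10**6
WEIGHTINGS = ("uniform", "inverse_distance", "inverse_distance_sq")


def _loo_ddknn(X: np.ndarray, y: np.ndarray, k: int, weighting: str) -> tuple[int, int, int, int]:
    """LOO confusion counts for DD-KNN on a feature subset (columns of X).

    Features are z-scored with training-fold statistics; votes weighted by
    1/(d + eps) (or uniform / 1/(d + eps)^2); weight ties predict negative.
    """
    n = len(y)
    tp = fn = tn = fp = 0
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xt, yt = X[keep], y[keep]
        mu = Xt.mean(axis=0)
        sd = Xt.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Zt = (Xt - mu) / sd
        zi = (X[i] - mu) / sd
        d = np.sqrt(((Zt - zi) ** 2).sum(axis=1))
        order = np.argsort(d, kind="mergesort")[:k]
        if weighting == "uniform":
            w = np.ones(len(order))
        elif weighting == "inverse_distance":
            w = 1.0 / (d[order] + EPS)
        else:
            w = 1.0 / (d[order] + EPS) ** 2
        w_pos = w[yt[order] == 1].sum()
        w_neg = w[yt[order] == 0].sum()
        pred = 1 if w_pos > w_neg else 0
        if y[i] == 1:
            tp += pred
            fn += 1 - pred
        else:
            tn += 1 - pred
            fp += pred
    return tp, fn, tn, fp


def _iter_panels(candidates: list[str], max_panel: int):
    n_subsets = sum(math.comb(len(candidates), s) for s in range(1, max_panel + 1))
    if n_subsets > MAX_SUBSETS:
        raise ValueError(
            f"{n_subsets} subsets exceeds the exhaustive-search guard "
            f"({MAX_SUBSETS}); tighten the candidate set"
        )
    for size in range(1, max_panel + 1):
        yield from itertools.combinations(sorted(candidates), size)


def ddknn_panel_search(matrix: MetaboliteMatrix, labels: pd.Series,
                       candidates, k: int = 3, max_panel: int = 3,
                       weighting: str = "inverse_distance"
                       ) -> dict[int, PanelResult]:
    """Exhaustive DD-KNN panel search with LOO evaluation.

    Evaluates every candidate subset up to ``max_panel`` metabolites and
    returns the best panel per size (key 0 holds the overall best), ranked
    by balanced accuracy with deterministic ties (smaller panel, then
    lexicographic members).
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    labels = labels.reindex(matrix.sample_ids)
    y = _check_labels(labels)
    candidates = sorted(set(candidates))
    logm = np.log(matrix.data[candidates].to_numpy(dtype=float))
    if np.isnan(logm).any():
        raise ValueError("matrix must be imputed before panel search")
    pos = {m: j for j, m in enumerate(candidates)}
    best: dict[int, PanelResult] = {}
    for panel in _iter_panels(candidates, max_panel):
        cols = [pos[m] for m in panel]
        res = PanelResult(panel, "ddknn", *_loo_ddknn(logm[:, cols], y, k, weighting))
        size = len(panel)
        for key in (size, 0):
            cur = best.get(key)
            if cur is None or _panel_better(res, cur):
                best[key] = res
    return best


def _panel_better(a: PanelResult, b: PanelResult) -> bool:
    ka = (a.balanced_accuracy, -len(a.members))
    kb = (b.balanced_accuracy, -len(b.members))
    if ka != kb:
        return ka > kb
    return a.members < b.members


def _fit_rule(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Threshold rule (cutpoint, direction) maximising training balanced
    accuracy; direction +1 predicts positive above the cutpoint.  Cutpoints
    are midpoints between adjacent distinct values; ties prefer the lowest
    cutpoint with direction +1."""
    xs = np.unique(x)
    cuts = (xs[:-1] + xs[1:]) / 2 if len(xs) > 1 else np.array([xs[0]])
    best = (-1.0, 0.0, 1)
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    for thr in cuts:
        above = x > thr
        for direction in (1, -1):
            pred = above if direction == 1 else ~above
            sens = np.sum(pred & (y == 1)) / n_pos
            spec = np.sum(~pred & (y == 0)) / n_neg
            ba = (sens + spec) / 2
            if ba > best[0] + 1e-12:
                best = (ba, float(thr), direction)
    return best[1], best[2]


def rule_panel_search(matrix: MetaboliteMatrix, labels: pd.Series,
                      candidates, max_panel: int = 3) -> dict[int, PanelResult]:
    """Exhaustive majority-vote threshold-rule panel search with LOO
    evaluation; same return convention as :func:`ddknn_panel_search`."""
    labels = labels.reindex(matrix.sample_ids)
    y = _check_labels(labels)
    candidates = sorted(set(candidates))
    logm = np.log(matrix.data[candidates].to_numpy(dtype=float))
    if np.isnan(logm).any():
        raise ValueError("matrix must be imputed before panel search")
    pos = {m: j for j, m in enumerate(candidates)}
    n = len(y)
    best: dict[int, PanelResult] = {}
    for panel in _iter_panels(candidates, max_panel):
        cols = [pos[m] for m in panel]
        tp = fn = tn = fp = 0
        for i in range(n):
            keep = np.ones(n, bool)
            keep[i] = False
            votes = 0
            for c in cols:
                thr, direction = _fit_rule(logm[keep, c], y[keep])
                above = logm[i, c] > thr
                votes += int(above if direction == 1 else not above)
            pred = 1 if votes > len(cols) / 2 else 0
            if y[i] == 1:
                tp += pred
                fn += 1 - pred
            else:
                tn += 1 - pred
                fp += pred
        res = PanelResult(panel, "rule", tp, fn, tn, fp)
        for key in (len(panel), 0):
            cur = best.get(key)
            if cur is None or _panel_better(res, cur):
                best[key] = res
    return best
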