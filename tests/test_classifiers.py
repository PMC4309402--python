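import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from stressmet import MetaboliteMatrix
from stressmet.classifiers import (
    EPS,
    PanelResult,
    candidate_pipeline,
    ddknn_panel_search,
    extremum_centroid_score,
    overlap_fisher,
    perfect_classifier_scan,
    rf_mda_rank,
    rule_panel_search,
    top_fraction,
    univariate_scores,
)


def _labelled_matrix(rng, n_per_class=6, n_null=20, planted_shift=0.0):
    """Random log-normal matrix with an optional planted marker ('marker')."""
    n = 2 * n_per_class
    cols = {f"null{i}": np.exp(rng.normal(0, 1, n)) for i in range(n_null)}
    base = rng.normal(0, 1, n)
    base[n_per_class:] += planted_shift
    cols["marker"] = np.exp(base)
    idx = [f"c{i}" for i in range(n_per_class)] + [f"a{i}" for i in range(n_per_class)]
    labels = pd.Series(["Ctrl"] * n_per_class + ["AggE"] * n_per_class, index=idx)
    return MetaboliteMatrix(pd.DataFrame(cols, index=idx)), labels


def test_rf_mda_ranks_planted_marker_first(rng):
    matrix, labels = _labelled_matrix(rng, n_null=100, planted_shift=10.0)
    scores = rf_mda_rank(matrix, labels, n_trees=150, seed=0)
    assert scores.iloc[0]["metabolite_id"] == "marker"
    assert scores.iloc[0]["rank"] == 1
    assert sorted(scores["rank"]) == list(range(1, len(scores) + 1))


def test_rf_mda_reproducible_and_permuted_labels_null(rng):
    matrix, labels = _labelled_matrix(rng, n_null=30, planted_shift=10.0)
    s1 = rf_mda_rank(matrix, labels, n_trees=60, seed=5)
    s2 = rf_mda_rank(matrix, labels, n_trees=60, seed=5)
    pd.testing.assert_frame_equal(s1, s2)
    # with labels permuted the marker's importance collapses into the null
    # spread: its mean MDA over seeds stays within 2 SD of the null scores
    marker_scores = []
    null_spread = []
    for seed in range(10):
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        s = rf_mda_rank(matrix, perm, n_trees=40, seed=seed).set_index("metabolite_id")
        marker_scores.append(s.loc["marker", "score"])
        null_spread.extend(s.drop("marker")["score"])
    import numpy as np

    assert abs(np.mean(marker_scores) - np.mean(null_spread)) <= 2 * np.std(null_spread)


def test_rf_mda_single_class_errors(rng):
    matrix, labels = _labelled_matrix(rng)
    with pytest.raises(ValueError):
        rf_mda_rank(matrix, pd.Series("Ctrl", index=labels.index), n_trees=5)


@pytest.mark.parametrize("n, fraction, expected", [(330, 0.10, 33), (10, 0.10, 1)])
def test_top_fraction_sizes(n, fraction, expected):
    scores = pd.DataFrame({
        "metabolite_id": [f"m{i:03d}" for i in range(n)],
        "method": "rf_mda",
        "score": np.linspace(1, 0, n),
        "rank": np.arange(1, n + 1),
    })
    assert len(top_fraction(scores, fraction)) == expected


def test_top_fraction_boundary_ties_break_by_id():
    scores = pd.DataFrame({
        "metabolite_id": ["b", "a", "c", "d"],
        "method": "ks", "score": [1.0, 0.5, 0.5, 0.5],
    })
    from stressmet.classifiers import _rank_scores

    ranked = _rank_scores(scores)
    assert top_fraction(ranked, 0.5) == ["b", "a"]


def _hypergeom_exact(N, K, n, obs):
    total = Fraction(math.comb(N, n))
    return float(sum(Fraction(math.comb(K, i) * math.comb(N - K, n - i)) / total
                     for i in range(obs, min(K, n) + 1)))


def test_overlap_fisher_printed_value():
    a = [f"a{i}" for i in range(33)]
    b = [f"a{i}" for i in range(9)] + [f"b{i}" for i in range(24)]
    overlap, p = overlap_fisher(330, a, b)
    assert overlap == 9
    assert p == pytest.approx(0.00234, abs=5e-5)
    assert round(p, 3) == 0.002


def test_overlap_fisher_matches_direct_summation(rng):
    for N, K, n, obs in [(330, 33, 33, 9), (50, 10, 8, 3), (1000, 40, 60, 5), (12, 6, 6, 6)]:
        a = [f"x{i}" for i in range(K)]
        b = [f"x{i}" for i in range(obs)] + [f"y{i}" for i in range(n - obs)]
        _, p = overlap_fisher(N, a, b)
        assert p == pytest.approx(_hypergeom_exact(N, K, n, obs), abs=1e-12)


def test_overlap_fisher_extremes():
    a = [f"m{i}" for i in range(5)]
    assert overlap_fisher(100, a, a)[0] == 5
    assert overlap_fisher(100, a, a)[1] < overlap_fisher(100, a, a[:4] + ["z"])[1]
    disjoint_p = overlap_fisher(100, a, [f"z{i}" for i in range(5)])[1]
    assert disjoint_p > 0.75
    with pytest.raises(ValueError):
        overlap_fisher(4, a, a)


def test_perfect_classifier_scan_directions():
    data = pd.DataFrame({
        "up_in_agge": [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],
        "down_in_agge": [7.0, 6.0, 5.0, 3.0, 2.0, 1.0],
        "overlapping": [1.0, 5.0, 3.0, 2.0, 6.0, 4.0],
    }, index=[f"s{i}" for i in range(6)])
    labels = pd.Series(["Ctrl"] * 3 + ["AggE"] * 3, index=data.index)
    hits = perfect_classifier_scan(MetaboliteMatrix(data), labels)
    hits = hits.set_index("metabolite_id")["direction"]
    assert hits.to_dict() == {"up_in_agge": "up", "down_in_agge": "down"}


def test_perfect_classifier_scan_equals_brute_force(rng):
    matrix, labels = _labelled_matrix(rng, n_null=30, planted_shift=8.0)
    hits = set(perfect_classifier_scan(matrix, labels)["metabolite_id"])
    y = (labels == "AggE").to_numpy()
    expected = set()
    for m in matrix.metabolite_ids:
        v = matrix.data[m].to_numpy()
        if v[y].min() > v[~y].max() or v[y].max() < v[~y].min():
            expected.add(m)
    assert hits == expected


def test_gini_flags_exact_separator_and_perfect_scan_subset(rng):
    matrix, labels = _labelled_matrix(rng, n_null=20, planted_shift=10.0)
    gini = univariate_scores(matrix, labels, "gini_tree")
    separators = set(gini.loc[gini["exact_separator"], "metabolite_id"])
    perfect = set(perfect_classifier_scan(matrix, labels)["metabolite_id"])
    assert perfect <= separators
    assert "marker" in separators
    assert gini.iloc[0]["metabolite_id"] == "marker"


def test_infogain_of_balanced_perfect_split_is_one_bit():
    data = pd.DataFrame({"m": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]},
                        index=[f"s{i}" for i in range(6)])
    labels = pd.Series(["Ctrl"] * 3 + ["AggE"] * 3, index=data.index)
    ig = univariate_scores(MetaboliteMatrix(data), labels, "infogain_tree")
    assert ig.iloc[0]["score"] == pytest.approx(1.0)
    assert ig.iloc[0]["exact_separator"]


def test_ks_and_chi2_near_null_for_identical_distributions(rng):
    n = 10
    vals = np.exp(rng.normal(0, 1, 2 * n))
    data = pd.DataFrame({"m": vals}, index=[f"s{i}" for i in range(2 * n)])
    labels = pd.Series(["Ctrl"] * n + ["AggE"] * n, index=data.index)
    m = MetaboliteMatrix(data)
    ks = univariate_scores(m, labels, "ks").iloc[0]["score"]
    chi2 = univariate_scores(m, labels, "chi2").iloc[0]["score"]
    assert ks <= 0.5
    assert chi2 <= 3.0


def test_constant_metabolite_scores_zero():
    data = pd.DataFrame({"m": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
    labels = pd.Series(["Ctrl"] * 3 + ["AggE"] * 3, index=data.index)
    for method in ("gini_tree", "infogain_tree", "chi2", "ks", "extremum_centroid"):
        tab = univariate_scores(MetaboliteMatrix(data), labels, method)
        assert tab.iloc[0]["score"] == 0.0


def test_extremum_centroid_hand_trace():
    # A: 1, 2; B: 10, 11 — every held-out sample lands nearer its own centroid
    values = [1.0, 2.0, 10.0, 11.0]
    labels = ["Ctrl", "Ctrl", "AggE", "AggE"]
    assert extremum_centroid_score(values, labels) == 1.0


def test_extremum_centroid_null_near_half(rng):
    accs = []
    for _ in range(30):
        values = rng.normal(0, 1, 12)
        labels = ["Ctrl"] * 6 + ["AggE"] * 6
        accs.append(extremum_centroid_score(values, labels))
    assert 0.3 < np.mean(accs) < 0.7


def test_candidate_pipeline_on_planted_blocks(rng):
    """Two perfectly correlated top metabolites collapse to the higher-max
    representative; correlates of representatives are pulled in."""
    n = 12
    y = np.array([0] * 6 + [1] * 6)
    strong = rng.normal(0, 0.2, n) + y * 6.0
    data = pd.DataFrame({
        "strong_hi": np.exp(strong + math.log(4)),  # r=1 duplicate, larger max
        "strong_lo": np.exp(strong),
        "correlate": np.exp(strong + rng.normal(0, 0.1, n)),
        "noise1": np.exp(rng.normal(0, 1, n)),
        "noise2": np.exp(rng.normal(0, 1, n)),
    }, index=[f"s{i}" for i in range(n)])
    labels = pd.Series(np.where(y, "AggE", "Ctrl"), index=data.index)
    cands = candidate_pipeline(MetaboliteMatrix(data), labels, top_k=2)
    assert "strong_hi" in cands
    assert "correlate" in cands
    reps_only = [c for c in cands if c.startswith("strong")]
    # strong_lo enters only as a correlate of the representative, which it is
    assert "strong_hi" in reps_only


def _naive_loo_ddknn(X, y, k):
    """Independent LOO DD-KNN reimplementation (plain loops)."""
    tp = fn = tn = fp = 0
    n = len(y)
    for i in range(n):
        train = [j for j in range(n) if j != i]
        mus = [np.mean([X[j][f] for j in train]) for f in range(len(X[0]))]
        sds = [np.std([X[j][f] for j in train]) or 1.0 for f in range(len(X[0]))]
        dists = []
        for j in train:
            d = math.sqrt(sum(((X[j][f] - mus[f]) / sds[f]
                               - (X[i][f] - mus[f]) / sds[f]) ** 2
                              for f in range(len(X[0]))))
            dists.append((d, j))
        dists.sort(key=lambda t: t[0])
        w_pos = sum(1 / (d + EPS) for d, j in dists[:k] if y[j] == 1)
        w_neg = sum(1 / (d + EPS) for d, j in dists[:k] if y[j] == 0)
        pred = 1 if w_pos > w_neg else 0
        if y[i] == 1:
            tp, fn = tp + pred, fn + 1 - pred
        else:
            tn, fp = tn + 1 - pred, fp + pred
    return tp, fn, tn, fp


def test_ddknn_matches_naive_reimplementation(rng):
    n = 12
    data = pd.DataFrame(
        {f"m{i}": np.exp(rng.normal(0, 1, n)) for i in range(4)},
        index=[f"s{i}" for i in range(n)])
    labels = pd.Series(["Ctrl"] * 6 + ["AggE"] * 6, index=data.index)
    matrix = MetaboliteMatrix(data)
    y = (labels == "AggE").astype(int).to_numpy()
    for panel in [("m0",), ("m1", "m3"), ("m0", "m1", "m2")]:
        best = ddknn_panel_search(matrix, labels, list(panel), k=3,
                                  max_panel=len(panel))
        res = [r for r in best.values() if r.members == tuple(sorted(panel))][0]
        X = np.log(data[list(sorted(panel))].to_numpy()).tolist()
        assert (res.tp, res.fn, res.tn, res.fp) == _naive_loo_ddknn(X, y, 3)


def test_ddknn_perfect_metabolite_gives_perfect_loo(rng):
    matrix, labels = _labelled_matrix(rng, n_null=5, planted_shift=12.0)
    best = ddknn_panel_search(matrix, labels, ["marker"], max_panel=1)
    assert best[0].sensitivity == 1.0
    assert best[0].specificity == 1.0
    assert best[0].tp + best[0].fn + best[0].tn + best[0].fp == len(labels)


def test_ddknn_exhaustive_equals_brute_force(rng):
    n = 10
    data = pd.DataFrame(
        {f"m{i}": np.exp(rng.normal(0, 1, n)) for i in range(5)},
        index=[f"s{i}" for i in range(n)])
    labels = pd.Series(["Ctrl"] * 5 + ["AggE"] * 5, index=data.index)
    matrix = MetaboliteMatrix(data)
    best = ddknn_panel_search(matrix, labels, list(data.columns), max_panel=2)
    # brute force over all 15 subsets using the searcher on singleton lists
    results = []
    for size in (1, 2):
        for panel in itertools.combinations(sorted(data.columns), size):
            r = ddknn_panel_search(matrix, labels, list(panel), max_panel=size)
            results.append([v for v in r.values() if v.members == panel][0])
    assert best[0].balanced_accuracy == max(r.balanced_accuracy for r in results)


def test_ddknn_guard_on_candidate_explosion(rng):
    n_feat = 200  # C(200, 3) > 1e6
    data = pd.DataFrame(rng.uniform(1, 2, size=(4, n_feat)),
                        index=["s0", "s1", "s2", "s3"],
                        columns=[f"m{i}" for i in range(n_feat)])
    labels = pd.Series(["Ctrl", "Ctrl", "AggE", "AggE"], index=data.index)
    with pytest.raises(ValueError, match="guard"):
        ddknn_panel_search(MetaboliteMatrix(data), labels,
                           list(data.columns), max_panel=3)


def test_rule_panel_perfect_separator(rng):
    matrix, labels = _labelled_matrix(rng, n_null=4, planted_shift=12.0)
    best = rule_panel_search(matrix, labels, ["marker"], max_panel=1)
    assert best[0].sensitivity == 1.0 and best[0].specificity == 1.0


def test_rule_panel_pair_beats_weak_singles():
    """A conjunctive concept (positive iff both features high): the 2-rule
    panel is perfect under LOO while either single rule misclassifies."""
    f1 = np.array([10.0] * 4 + [10.0] * 3 + [1.0] * 3 + [1.0] * 2)
    f2 = np.array([10.0] * 4 + [1.0] * 3 + [10.0] * 3 + [1.0] * 2)
    y = ["AggE"] * 4 + ["Ctrl"] * 8
    idx = [f"s{i}" for i in range(12)]
    data = pd.DataFrame({"f1": f1, "f2": f2}, index=idx)
    labels = pd.Series(y, index=idx)
    best = rule_panel_search(MetaboliteMatrix(data), labels, ["f1", "f2"],
                             max_panel=2)
    assert best[2].balanced_accuracy == 1.0
    assert best[2].balanced_accuracy > best[1].balanced_accuracy


def test_panel_result_confusion_identities():
    r = PanelResult(("m",), "ddknn", tp=10, fn=1, tn=9, fp=2)
    assert r.sensitivity == pytest.approx(10 / 11)
    assert r.specificity == pytest.approx(9 / 11)
    assert r.balanced_accuracy == pytest.approx((10 / 11 + 9 / 11) / 2)
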