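"""Subpathway coordination statistic and its permutation null.

The statistic is the mean pairwise Manhattan (Hamming) distance between the
8-bit direction profiles of a subpathway's metabolites: 0 when every member
moves the same way in all eight comparisons, 8 when members are perfectly
anti-coordinated.  Significance comes from a resampling null — m random
same-size metabolite sets drawn without replacement from all profiled
metabolites — with the slightly conservative add-one p-value
p = (b + 1) / (m + 1), where b counts null mean distances at least as
extreme as the observed one in the chosen tail (ties count).

The default tail is ``low``: coordinated subpathways have *small* mean
distance, so b counts null samples with mean distance <= observed.  The
``high`` tail (anti-coordination) is also available.

Subpathway direction behaviour is summarised by the mean-bit profile
(fraction of members up per comparison) and clustered hierarchically on L1
distances between those profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import PathwayMap
from .direction import profile_bits

DEFAULT_M = 10_000


def manhattan_distance(a, b) -> int:
    """Hamming count between two equal-length 0/1 direction profiles."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a - b).sum())


def subpathway_mean_distance(profiles: pd.DataFrame | np.ndarray) -> float:
    """Mean of all C(n,2) pairwise Manhattan distances among member profiles."""
    bits = profile_bits(profiles).to_numpy() if isinstance(profiles, pd.DataFrame) \
        else np.asarray(profiles)
    n = bits.shape[0]
    if n < 2:
        raise ValueError("need >= 2 member profiles")
    return float(_mean_pair_distance(bits[None, :, :])[0])


def _mean_pair_distance(sets: np.ndarray) -> np.ndarray:
    """Mean pairwise Hamming distance for a stack of (k x 8) bit sets.

    For 0/1 bits the pairwise distance sum per comparison column is
    ones * (k - ones), so the statistic needs only the column sums.
    """
    k = sets.shape[1]
    ones = sets.sum(axis=1)  # (n_sets, 8)
    pair_sum = (ones * (k - ones)).sum(axis=1)
    return pair_sum / (k * (k - 1) / 2)


@dataclass(frozen=True)
class CoordResult:
    subpathway: str
    n_members: int
    mean_distance: float
    b: int
    m: int
    p: float
    tail: str
    seed: int | None = None


def coordination_test(member_ids, profiles: pd.DataFrame, m: int = DEFAULT_M,
                      seed: int | None = None, tail: str = "low",
                      label: str | None = None) -> CoordResult:
    """Permutation coordination test for one metabolite set.

    ``member_ids`` index into ``profiles`` (all profiled metabolites — the
    resampling universe).  Draws m same-size sets without replacement and
    compares their mean pairwise distance with the observed one.
    """
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    if m < 1:
        raise ValueError("m must be >= 1")
    bits = profile_bits(profiles)
    members = list(member_ids)
    missing = set(members) - set(bits.index)
    if missing:
        raise KeyError(f"members not in profile table: {sorted(missing)[:5]}")
    k = len(members)
    n_all = len(bits)
    if not 2 <= k <= n_all:
        raise ValueError(f"member count {k} outside [2, {n_all}]")
    obs = subpathway_mean_distance(bits.loc[members])
    all_bits = bits.to_numpy()
    rng = np.random.default_rng(seed)
    null = _null_mean_distances(all_bits, k, m, rng)
    eps = 1e-12
    b = int((null <= obs + eps).sum()) if tail == "low" else int((null >= obs - eps).sum())
    return CoordResult(
        subpathway=label if label is not None else ",".join(members[:3]) + ("..." if k > 3 else ""),
        n_members=k, mean_distance=obs, b=b, m=m, p=(b + 1) / (m + 1),
        tail=tail, seed=seed,
    )


def _null_mean_distances(all_bits: np.ndarray, k: int, m: int,
                         rng: np.random.Generator,
                         batch: int = 2000) -> np.ndarray:
    """Mean pairwise distances of m random k-subsets of the profile rows."""
    n = all_bits.shape[0]
    out = np.empty(m)
    done = 0
    while done < m:
        nb = min(batch, m - done)
        # k smallest of iid uniforms per row = a uniform k-subset
        u = rng.random((nb, n))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        sets = all_bits[idx]  # (nb, k, 8)
        out[done:done + nb] = _mean_pair_distance(sets)
        done += nb
    return out


def branch_mean_distance_test(member_ids, profiles: pd.DataFrame,
                              m: int = DEFAULT_M, seed: int | None = None,
                              tail: str = "low",
                              label: str = "branch") -> CoordResult:
    """Coordination test for an arbitrary metabolite set (e.g. a dendrogram
    branch spanning several subpathways); identical contract to
    :func:`coordination_test`."""
    return coordination_test(member_ids, profiles, m=m, seed=seed, tail=tail,
                             label=label)


def scan_subpathways(profiles: pd.DataFrame, pathway_map: PathwayMap,
                     m: int = DEFAULT_M, seed: int | None = None,
                     tail: str = "low", min_members: int = 2) -> pd.DataFrame:
    """Coordination test for every subpathway with >= min_members profiled
    metabolites; per-subpathway seeds are spawned deterministically."""
    bits = profile_bits(profiles)
    root = np.random.default_rng(seed)
    rows = []
    for sub, ids in sorted(pathway_map.subpathway_members().items()):
        present = [i for i in ids if i in bits.index]
        if len(present) < max(2, min_members):
            continue
        sub_seed = int(root.integers(2**31 - 1))
        rows.append(coordination_test(present, profiles, m=m, seed=sub_seed,
                                      tail=tail, label=sub))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mean-bit profiles and clustering


def subpathway_mean_profiles(profiles: pd.DataFrame,
                             pathway_map: PathwayMap,
                             subpathways=None,
                             min_members: int = 2) -> pd.DataFrame:
    """Fraction of members with bit = 1 per comparison, per subpathway."""
    bits = profile_bits(profiles)
    members = pathway_map.subpathway_members()
    wanted = sorted(members) if subpathways is None else list(subpathways)
    rows = {}
    for sub in wanted:
        present = [i for i in members.get(sub, []) if i in bits.index]
        if len(present) >= min_members:
            rows[sub] = bits.loc[present].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=bits.columns)


def cluster_subpathways(mean_profiles: pd.DataFrame,
                        linkage: str = "average") -> tuple[np.ndarray, str]:
    """Agglomerative clustering of subpathways on L1 distances between
    mean-bit profiles.

    Returns the scipy linkage matrix (rows ordered lexicographically by
    subpathway name for determinism) and a Newick serialisation with merge
    heights as branch lengths.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    prof = mean_profiles.sort_index()
    if len(prof) < 2:
        raise ValueError("need >= 2 subpathways to cluster")
    d = pdist(prof.to_numpy(), metric="cityblock")
    z = hierarchy.linkage(d, method=linkage)
    newick = _to_newick(z, list(prof.index))
    return z, newick


def cut_clusters(z: np.ndarray, names: list[str], n_clusters: int = 2) -> dict[str, int]:
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return dict(zip(sorted(names), (int(x) for x in labels)))


def _to_newick(z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def rec(node, parent_h):
        if node.is_leaf():
            safe = names[node.id].replace(" ", "_").replace(",", "").replace(";", "")
            blen = parent_h if parent_h is not None else 0.0
            return f"{safe}:{blen:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        blen = (parent_h - node.dist) if parent_h is not None else 0.0
        return f"({left},{right}):{blen:g}"

    return rec(tree, None) + ";"
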