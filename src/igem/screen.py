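"""Screen profiling: ratio-to-control, viability gating, clustering into the
hypo-/hyper-/intermediate methylation categories, and the screen's test
statistics (ANOVA + Tukey HSD, Kruskal-Wallis + Steel-Dwass).

Chemicals are clustered on their 4-ratio profiles with correlation distance
(1 - Pearson r) and average linkage, the tree is cut at k = 3, and the three
clusters are labelled by ranking their mean foci-parameter ratio: lowest ->
A (hypomethylation), highest -> B (hypermethylation), middle -> C
(intermediate).  For other k a +/- delta band around 1 decides the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .imaging import WellMeasure

FOCI_COLUMNS = ["foci_intensity", "foci_area", "foci_count"]
RATIO_COLUMNS = FOCI_COLUMNS + ["nuclei_count"]

PARAM_ATTR = {
    "foci_intensity": "foci_intensity_per_nucleus",
    "foci_area": "foci_area_per_nucleus",
    "foci_count": "foci_count_per_nucleus",
    "nuclei_count": "nuclei_count",
}


class ScreenError(ValueError):
    pass


@dataclass
class StatResult:
    comparison: tuple[str, ...]
    statistic: float
    p_value: float


@dataclass
class CategoryCall:
    chemical: str
    cluster_id: int
    category: str


def ratio_to_control(
    treated: list[WellMeasure], control: list[WellMeasure]
) -> pd.DataFrame:
    """Per-parameter ratio of treated to vehicle-control well means.

    ``ratio = mean(treated) / mean(control)``; the standard error combines
    replicate variation of both arms by the delta method.  Raises if a
    control parameter is zero or undefined, naming the parameter.
    """
    if not treated or not control:
        raise ScreenError("need at least one replicate per arm")
    rows = {}
    for param, attr in PARAM_ATTR.items():
        t = np.array([getattr(m, attr) for m in treated], dtype=float)
        c = np.array([getattr(m, attr) for m in control], dtype=float)
        if np.isnan(c).any() or np.mean(c) == 0:
            raise ScreenError(f"control parameter {param!r} is zero or undefined")
        if np.isnan(t).any():
            raise ScreenError(f"treated parameter {param!r} is undefined")
        mt, mc = t.mean(), c.mean()
        ratio = mt / mc
        se_t = t.std(ddof=1) / np.sqrt(len(t)) if len(t) > 1 else 0.0
        se_c = c.std(ddof=1) / np.sqrt(len(c)) if len(c) > 1 else 0.0
        rel_t = (se_t / mt) ** 2 if mt != 0 else 0.0
        se = abs(ratio) * np.sqrt(rel_t + (se_c / mc) ** 2)
        rows[param] = {"ratio": ratio, "se": se}
    return pd.DataFrame(rows).T


def viability_gate(table: pd.DataFrame, min_fraction: float = 0.70) -> pd.DataFrame:
    """Flag rows whose nuclei ratio falls below the viability cut-off.

    The screen's rule is "viability more than 70% of control"; the boundary
    is implemented inclusively (a ratio of exactly ``min_fraction`` is
    retained).  Flagged rows are kept in the output with ``viable = False``
    so nothing is silently dropped.
    """
    out = table.copy()
    out["viable"] = out["nuclei_count"] >= min_fraction
    return out


def cluster_chemicals(
    table: pd.DataFrame, k: int = 3
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage agglomerative clustering of chemicals on correlation
    distance (1 - Pearson r) between their 4-ratio profiles; the tree is cut
    into ``k`` clusters.  Returns the linkage matrix and a cluster-id Series.
    """
    X = table[RATIO_COLUMNS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ScreenError("ratio table contains missing values")
    if len(X) < k:
        raise ScreenError(f"need at least k={k} rows to cut into {k} clusters")
    constant = np.isclose(X.std(axis=1), 0.0)
    if constant.any():
        bad = list(table.index[constant])
        raise ScreenError(
            f"Pearson distance undefined for constant-profile rows: {bad}"
        )
    dist = pdist(X, metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    ids = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return linkage, pd.Series(ids, index=table.index, name="cluster_id")


def assign_categories(
    clusters: pd.Series, table: pd.DataFrame, delta: float = 0.05
) -> list[CategoryCall]:
    """Label each cluster A/B/C from its mean foci-parameter ratio.

    With exactly three clusters the labels are forced distinct by ranking
    the cluster means (lowest -> A, highest -> B, middle -> C); otherwise a
    cluster is B if its mean exceeds 1 + delta, A if below 1 - delta, else C.
    """
    foci_mean = table[FOCI_COLUMNS].mean(axis=1)
    cluster_means = foci_mean.groupby(clusters).mean()
    if len(cluster_means) == 3:
        order = cluster_means.sort_values().index
        mapping = {order[0]: "A", order[2]: "B", order[1]: "C"}
    else:
        mapping = {
            cid: ("B" if m > 1 + delta else "A" if m < 1 - delta else "C")
            for cid, m in cluster_means.items()
        }
    return [
        CategoryCall(chemical=chem, cluster_id=int(cid), category=mapping[cid])
        for chem, cid in clusters.items()
    ]


def categorize_screen(
    table: pd.DataFrame,
    k: int = 3,
    delta: float = 0.05,
    min_viability: float = 0.70,
) -> pd.DataFrame:
    """Viability gate + clustering + category labels in one call."""
    gated = viability_gate(table, min_viability)
    usable = gated[gated["viable"]]
    _, clusters = cluster_chemicals(usable, k=k)
    calls = assign_categories(clusters, usable, delta=delta)
    out = pd.DataFrame(
        {
            "chemical": [c.chemical for c in calls],
            "cluster_id": [c.cluster_id for c in calls],
            "category": [c.category for c in calls],
        }
    ).set_index("chemical")
    return out


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch
    lengths (merge-height differences)."""
    tree = hierarchy.to_tree(linkage)

    def build(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------

def dose_response_test(
    groups: dict[str, np.ndarray], control_label: str
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA across dose groups followed by Tukey HSD for each
    dose-vs-control pair (two-sided, studentized-range reference)."""
    if control_label not in groups:
        raise ScreenError(f"control label {control_label!r} not among groups")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if any(len(a) < 2 for a in arrays):
        raise ScreenError("each group needs at least 2 observations")
    f_stat, p = stats.f_oneway(*arrays)
    if np.isnan(f_stat):  # all groups identical -> zero variance
        f_stat, p = 0.0, 1.0
    omnibus = StatResult(tuple(labels), float(f_stat), float(p))
    with np.errstate(invalid="ignore", divide="ignore"):
        tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    ci = labels.index(control_label)
    for j, lab in enumerate(labels):
        if lab == control_label:
            continue
        stat = float(tukey.statistic[j, ci])
        p = float(tukey.pvalue[j, ci])
        if np.isnan(p):  # zero within-group variance
            p = 1.0 if stat == 0 else 0.0
        pairwise.append(StatResult((lab, control_label), stat, p))
    return omnibus, pairwise


def steel_dwass(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    method: str = "auto",
    n_resamples: int = 100_000,
    seed: int = 0,
) -> list[StatResult]:
    """Steel-Dwass all-pairs nonparametric comparison.

    For each pair of groups the two samples are ranked jointly and the rank
    sum of the first group is standardized with the tie-corrected variance.

    ``method="asymptotic"`` refers ``sqrt(2) |t|`` to the studentized range
    distribution with ``k`` groups (infinite degrees of freedom); with k = 2
    this reduces to the tie-corrected normal-approximation Wilcoxon rank-sum
    test.  ``method="permutation"`` refers each pairwise statistic to the
    permutation distribution of the *maximum* standardized pairwise
    statistic over all pairs (the exact analogue of the studentized-range
    family adjustment), enumerated exhaustively when feasible and otherwise
    sampled with a seeded Monte Carlo.  ``method="auto"`` uses the
    permutation reference for small studies (total n <= 24, k >= 3), where
    the asymptotic reference is least accurate, and the asymptotic reference
    otherwise.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[lab], dtype=float) for lab in labels]
    else:
        labels = [str(i) for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2:
        raise ScreenError("need at least two groups")
    for lab, g in zip(labels, data):
        if len(g) < 2:
            raise ScreenError(f"group {lab!r} has fewer than 2 observations")
    k = len(data)
    total_n = sum(len(g) for g in data)
    if method == "auto":
        method = "permutation" if (total_n <= 24 and k >= 3) else "asymptotic"
    if method not in ("asymptotic", "permutation"):
        raise ScreenError(f"unknown method {method!r}")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    t_obs = {p: _steel_dwass_statistic(data[p[0]], data[p[1]]) for p in pairs}
    if method == "asymptotic":
        pvals = {
            p: min(
                float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf)),
                1.0,
            )
            for p, t in t_obs.items()
        }
    else:
        pvals = _steel_dwass_permutation(data, t_obs, n_resamples, seed)
    return [
        StatResult((labels[i], labels[j]), float(t_obs[(i, j)]), pvals[(i, j)])
        for i, j in pairs
    ]


def _pairwise_t_matrix(perm_data: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Standardized pairwise rank-sum statistics for a batch of permuted
    datasets (rows); returns shape (n_batch, n_pairs)."""
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    k = len(sizes)
    cols = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = sizes[i], sizes[j]
            sub = np.concatenate(
                [
                    perm_data[:, bounds[i] : bounds[i + 1]],
                    perm_data[:, bounds[j] : bounds[j + 1]],
                ],
                axis=1,
            )
            ranks = stats.rankdata(sub, axis=1)
            big_n = ni + nj
            r = ranks[:, :ni].sum(axis=1)
            expect = ni * (big_n + 1) / 2.0
            var = ni * nj / (big_n * (big_n - 1.0)) * (
                (ranks**2).sum(axis=1) - big_n * (big_n + 1.0) ** 2 / 4.0
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, (r - expect) / np.sqrt(var), 0.0)
            cols.append(t)
    return np.column_stack(cols)


def _steel_dwass_permutation(
    data: list[np.ndarray],
    t_obs: dict[tuple[int, int], float],
    n_resamples: int,
    seed: int,
    exhaustive_limit: int = 250_000,
) -> dict[tuple[int, int], float]:
    from itertools import combinations
    from math import comb

    sizes = [len(g) for g in data]
    pooled = np.concatenate(data)
    total_n = len(pooled)
    n_exact = 1
    remaining = total_n
    for s in sizes[:-1]:
        n_exact *= comb(remaining, s)
        remaining -= s
    if n_exact <= exhaustive_limit:
        index_rows = np.empty((n_exact, total_n), dtype=np.intp)

        def fill(row, prefix, rest, size_idx):
            if size_idx == len(sizes) - 1:
                index_rows[fill.cursor] = prefix + rest
                fill.cursor += 1
                return
            for chosen in combinations(range(len(rest)), sizes[size_idx]):
                chosen_set = set(chosen)
                fill(
                    row,
                    prefix + [rest[c] for c in chosen],
                    [r for c, r in enumerate(rest) if c not in chosen_set],
                    size_idx + 1,
                )

        fill.cursor = 0
        fill(0, [], list(range(total_n)), 0)
        perm_data = pooled[index_rows]
    else:
        rng = np.random.default_rng(seed)
        perm_data = np.tile(pooled, (n_resamples, 1))
        perm_data = rng.permuted(perm_data, axis=1)
    t_all = np.abs(_pairwise_t_matrix(perm_data, sizes))
    t_max = t_all.max(axis=1)
    return {
        p: float(np.mean(t_max >= abs(t) - 1e-12)) for p, t in t_obs.items()
    }


def _steel_dwass_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one pair."""
    ni, nj = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    big_n = ni + nj
    r = ranks[:ni].sum()
    expect = ni * (big_n + 1) / 2.0
    var = ni * nj / (big_n * (big_n - 1.0)) * (
        (ranks**2).sum() - big_n * (big_n + 1.0) ** 2 / 4.0
    )
    if var <= 0:  # all observations tied
        return 0.0
    return (r - expect) / np.sqrt(var)
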