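"""Tree-ensemble ranking of physiological activities against MBD parameters.

A regression random forest is fitted with each fluorescent MBD parameter's
ratio-to-control as the response and the harmonized activity labels as
features; activities are ranked by impurity importance (total node-variance
decrease summed over trees, the "increase in node purity" of the classic R
implementation, in response-variance units).  Group differences of the MBD
parameters across activity labels are tested with Kruskal-Wallis followed by
Steel-Dwass all-pairs comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .screen import StatResult, steel_dwass

ORDINAL_CODES = {"active": 1.0, "inconclusive": 0.5, "inactive": 0.0}


class AssociationError(ValueError):
    pass


def encode_activities(matrix: pd.DataFrame, encoding: str = "ordinal") -> pd.DataFrame:
    """Encode the label matrix numerically.

    ``ordinal``: active = 1, inconclusive = 0.5, inactive = 0, with missing
    cells imputed to the column median (of the encoded non-missing labels).
    ``onehot``: three indicator columns per activity (``act=label``), missing
    rows all-zero.  Columns missing in every row are dropped.
    """
    if encoding == "ordinal":
        enc = matrix.apply(lambda col: col.map(ORDINAL_CODES).astype(float))
        all_missing = enc.isna().all(axis=0)
        enc = enc.loc[:, ~all_missing]
        return enc.fillna(enc.median(axis=0))
    if encoding == "onehot":
        cols = {}
        for act in matrix.columns:
            if (matrix[act] == "missing").all():
                continue
            for lab in ORDINAL_CODES:
                cols[f"{act}={lab}"] = (matrix[act] == lab).astype(float)
        return pd.DataFrame(cols, index=matrix.index)
    raise AssociationError(f"unknown encoding {encoding!r}")


def decode_onehot(encoded: pd.DataFrame) -> pd.DataFrame:
    """Invert the one-hot encoding (rows with no set indicator -> missing)."""
    acts = sorted({c.rsplit("=", 1)[0] for c in encoded.columns})
    out = pd.DataFrame("missing", index=encoded.index, columns=acts)
    for col in encoded.columns:
        act, lab = col.rsplit("=", 1)
        out.loc[encoded[col] > 0.5, act] = lab
    return out


def rf_importance(
    features: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    top_n: int = 30,
) -> pd.DataFrame:
    """Rank activities by node-purity increase for one MBD parameter.

    Fits a regression forest (bootstrap samples, ceil(p/3) features per
    split) and sums the unnormalized impurity decreases over trees, scaled
    by the sample count so importances carry response-variance units.  Ties
    are broken alphabetically by activity name for a deterministic ranking.
    Returns all features ranked, with a ``top`` flag for the first ``top_n``.
    """
    common = features.index.intersection(response.index)
    X = features.loc[common]
    y = response.loc[common].astype(float)
    if len(common) < 10:
        raise AssociationError("need at least 10 chemicals")
    if n_trees < 100:
        raise AssociationError("need at least 100 trees")
    if not np.isfinite(y).all():
        raise AssociationError("response contains non-finite values")
    if np.isclose(y.std(), 0.0):
        raise AssociationError("response is constant")
    p = X.shape[1]
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, int(np.ceil(p / 3))),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y.to_numpy())
    raw = np.zeros(p)
    for tree in forest.estimators_:
        raw += tree.tree_.compute_feature_importances(normalize=False)
    importance = raw * len(common)  # per-tree mean impurity decrease x n
    ranking = pd.DataFrame(
        {"activity": X.columns, "importance": importance}
    ).sort_values(["importance", "activity"], ascending=[False, True], kind="mergesort")
    ranking["rank"] = np.arange(1, p + 1)
    ranking["top"] = ranking["rank"] <= top_n
    return ranking.reset_index(drop=True)


def compare_by_label(
    ratios: pd.Series, labels: pd.Series
) -> tuple[StatResult, list[StatResult]]:
    """Kruskal-Wallis across the active/inconclusive/inactive groups of one
    activity, followed by Steel-Dwass pairwise comparisons."""
    common = ratios.index.intersection(labels.index)
    ratios, labels = ratios.loc[common], labels.loc[common]
    groups = {
        lab: ratios[labels == lab].to_numpy(dtype=float)
        for lab in ("active", "inconclusive", "inactive")
        if (labels == lab).any()
    }
    if len(groups) < 2:
        raise AssociationError("need at least two non-empty label groups")
    if any(len(g) < 2 for g in groups.values()):
        raise AssociationError("each label group needs at least 2 chemicals")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:  # all observations identical
        omnibus = StatResult(tuple(groups), 0.0, 1.0)
    else:
        h, p = stats.kruskal(*arrays)
        omnibus = StatResult(tuple(groups), float(h), float(p))
    pairwise = steel_dwass(groups)
    return omnibus, pairwise
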