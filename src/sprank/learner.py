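"""Target construction and the random-forest move ranker.

The regression label for one (starting tree, SPR move) pair is

    target = (LL_neighbor - LL_start) / LL_start

i.e. the log-likelihood change relative to the starting tree's
log-likelihood.  Because LL_start < 0 for any proper alignment, an
*improving* move has a *negative* target; ranking moves best-first means
sorting by target ascending, equivalently by predicted delta-LL
(= target * LL_start) descending.  Targets are trained through the
uniformizing transform f(t) = 2^(t+1), which is strictly increasing, and
predictions are mapped back with its inverse log2(y) - 1.

The ranker is a random forest regressor with 70 trees considering a random
third of the features (ceil(k/3)) at each split.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import FEATURE_NAMES

__all__ = [
    "compute_target",
    "transform_target",
    "inverse_transform",
    "RankModel",
    "train",
    "rank_moves",
    "feature_importance",
    "single_feature_models",
    "backward_elimination",
]


def compute_target(ll_neighbor, ll_start):
    """Relative log-likelihood change (LL_neighbor - LL_start) / LL_start."""
    ll_start = np.asarray(ll_start, dtype=float)
    if np.any(ll_start == 0):
        raise ValueError("ll_start must be nonzero")
    out = (np.asarray(ll_neighbor, dtype=float) - ll_start) / ll_start
    return out if out.ndim else float(out)


def transform_target(t):
    """Uniformizing transform f(t) = 2^(t+1)."""
    out = np.exp2(np.asarray(t, dtype=float) + 1.0)
    return out if out.ndim else float(out)


def inverse_transform(y):
    """Inverse of the target transform: log2(y) - 1 (requires y > 0)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("inverse transform requires positive values")
    out = np.log2(y) - 1.0
    return out if out.ndim else float(out)


@dataclass
class RankModel:
    """A trained move ranker: forest plus the feature ordering it expects."""

    forest: RandomForestRegressor
    feature_names: tuple[str, ...]
    training_meta: dict = field(default_factory=dict)

    def predict_transformed(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected (n, {len(self.feature_names)}) feature matrix, got {features.shape}"
            )
        return self.forest.predict(features)

    def save(self, path: str) -> None:
        joblib.dump(self.forest, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                {"feature_names": list(self.feature_names), "training_meta": self.training_meta},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str) -> "RankModel":
        forest = joblib.load(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(
            forest=forest,
            feature_names=tuple(meta["feature_names"]),
            training_meta=meta.get("training_meta", {}),
        )


def _check_matrix(X: np.ndarray, names) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"non-finite feature value at row {r}, column {names[c]!r}")
    return X


def train(
    X: np.ndarray,
    transformed_y: np.ndarray,
    feature_names=FEATURE_NAMES,
    n_trees: int = 70,
    features_per_split: float = 1.0 / 3.0,
    seed: int = 0,
    meta: dict | None = None,
) -> RankModel:
    """Fit the random-forest ranker on transformed targets.

    ``features_per_split`` is a fraction of the feature count; the actual
    number tried per split is its ceiling (7 of 19 at the full set).
    Deterministic given *seed*.
    """
    X = _check_matrix(X, feature_names)
    y = np.asarray(transformed_y, dtype=float)
    if X.shape[0] < 1 or X.shape[0] != y.shape[0]:
        raise ValueError("need matching, non-empty features and targets")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")
    max_features = max(1, math.ceil(features_per_split * X.shape[1]))
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return RankModel(
        forest=forest,
        feature_names=tuple(feature_names),
        training_meta={
            "n_trees": n_trees,
            "max_features": max_features,
            "seed": seed,
            "n_examples": int(X.shape[0]),
            **(meta or {}),
        },
    )


def rank_moves(
    model: RankModel, features: np.ndarray, ll_start: float
) -> pd.DataFrame:
    """Rank moves best-first by predicted log-likelihood change.

    Returns a DataFrame ordered best-first with columns ``move_id``,
    ``predicted_transformed``, ``predicted_target`` and
    ``predicted_delta_ll`` (= predicted_target * ll_start; positive means a
    predicted improvement since ll_start < 0).  Ties are broken by move id.
    """
    if ll_start >= 0:
        raise ValueError("ll_start must be negative")
    pred_tr = model.predict_transformed(features)
    pred_target = inverse_transform(pred_tr)
    delta_ll = pred_target * ll_start
    order = np.lexsort((np.arange(len(delta_ll)), -delta_ll))
    return pd.DataFrame(
        {
            "move_id": order,
            "predicted_transformed": pred_tr[order],
            "predicted_target": pred_target[order],
            "predicted_delta_ll": delta_ll[order],
        }
    )


def feature_importance(model: RankModel) -> pd.DataFrame:
    """Impurity-based importances, descending (they sum to 1)."""
    imp = model.forest.feature_importances_
    df = pd.DataFrame({"feature": model.feature_names, "importance": imp})
    return df.sort_values("importance", ascending=False, ignore_index=True)


def single_feature_models(corpus_frame: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Held-out accuracy of 19 one-feature rankers.

    For each feature, trains a forest on that single column and evaluates the
    mean per-dataset Spearman correlation under dataset-grouped k-fold
    cross-validation.  Returns one row per feature, sorted by mean rho.
    """
    from .evaluation import cross_validate_frame

    rows = []
    for name in FEATURE_NAMES:
        reports = cross_validate_frame(
            corpus_frame, feature_names=(name,), k=k, seed=seed
        )
        rows.append({"feature": name, "mean_rho": float(reports["spearman_rho"].mean())})
    return pd.DataFrame(rows).sort_values("mean_rho", ascending=False, ignore_index=True)


def backward_elimination(corpus_frame: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Backward stepwise feature elimination.

    Starting from all 19 features, repeatedly drops the feature with the
    smallest impurity importance (from a forest fit on the full table) and
    records the cross-validated mean Spearman rho of each nested feature
    set.  Returns 19 rows, from the full set down to a single feature.
    """
    from .evaluation import cross_validate_frame

    current = list(FEATURE_NAMES)
    rows = []
    while current:
        reports = cross_validate_frame(
            corpus_frame, feature_names=tuple(current), k=k, seed=seed
        )
        model = train(
            corpus_frame[current].to_numpy(),
            corpus_frame["transformed_target"].to_numpy(),
            feature_names=tuple(current),
            seed=seed,
        )
        imp = model.forest.feature_importances_
        dropped = current[int(np.argmin(imp))]
        rows.append(
            {
                "n_features": len(current),
                "features": tuple(current),
                "mean_rho": float(reports["spearman_rho"].mean()),
                "next_dropped": dropped if len(current) > 1 else None,
            }
        )
        if len(current) == 1:
            break
        current.remove(dropped)
    return pd.DataFrame(rows)
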