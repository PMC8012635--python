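"""Ranking-accuracy metrics and dataset-grouped cross-validation.

Three per-dataset metrics quantify how well predicted move scores reproduce
the true likelihood ranking of a tree's SPR neighborhood:

1. Spearman rank correlation between true and predicted scores (+1 when the
   predicted ordering matches the true best-to-worst ordering);
2. the percentile rank of the empirically best move within the predicted
   ranking (100 * rank / n_moves, rank 1 = predicted best);
3. the percentile rank of the predicted-best move within the true ranking.

Small percentiles are good for both (2) and (3).  Cross-validation folds
group whole datasets (all moves of one starting tree stay in one fold), so
no tree contributes to both training and evaluation.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES
from .learner import inverse_transform, train

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "spearman_rho",
    "percentile_metrics",
    "cross_validate",
    "cross_validate_frame",
]


@dataclass
class MetricsReport:
    dataset_id: str
    spearman_rho: float
    best_move_predicted_percentile: float
    predicted_best_true_percentile: float
    top1_improves: bool
    n_moves: int


def spearman_rho(true_ll, predicted_scores) -> float:
    """Spearman rank correlation between true and predicted move scores.

    Both inputs are 'higher is better'; +1 means the predicted ranking
    reproduces the true one.  Returns NaN (with a warning) if either vector
    is constant.
    """
    true_ll = np.asarray(true_ll, dtype=float)
    pred = np.asarray(predicted_scores, dtype=float)
    if true_ll.shape != pred.shape or true_ll.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(true_ll) == 0 or np.ptp(pred) == 0:
        logger.warning("constant score vector: Spearman correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.spearmanr(true_ll, pred).statistic)


def percentile_metrics(
    true_ll, predicted_scores, ll_start: float | None = None
) -> tuple[float, float, bool]:
    """(best-move percentile in predicted ranking, predicted-best percentile
    in true ranking, whether the predicted-best move truly improves).

    Percentile = 100 * rank / n with rank 1 the best; ties take the average
    rank.  The improvement flag compares the predicted-best move's true
    log-likelihood against *ll_start* (False when ll_start is omitted).
    """
    true_ll = np.asarray(true_ll, dtype=float)
    pred = np.asarray(predicted_scores, dtype=float)
    if true_ll.shape != pred.shape or true_ll.size < 1:
        raise ValueError("need two equal-length non-empty vectors")
    n = true_ll.size
    pred_ranks = stats.rankdata(-pred, method="average")
    true_ranks = stats.rankdata(-true_ll, method="average")
    best_true_idx = int(np.argmax(true_ll))
    best_pred_idx = int(np.flatnonzero(pred == pred.max())[0])  # ties -> first move
    best_in_predicted = 100.0 * pred_ranks[best_true_idx] / n
    predicted_in_true = 100.0 * true_ranks[best_pred_idx] / n
    improves = bool(ll_start is not None and true_ll[best_pred_idx] > ll_start)
    return float(best_in_predicted), float(predicted_in_true), improves


def _fold_assignment(dataset_ids: list[str], k: int, seed: int) -> dict[str, int]:
    if len(dataset_ids) < k:
        raise ValueError(f"need at least {k} datasets for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = list(dataset_ids)
    rng.shuffle(order)
    return {ds: i % k for i, ds in enumerate(order)}


def cross_validate_frame(
    corpus_frame: pd.DataFrame,
    feature_names=FEATURE_NAMES,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 70,
) -> pd.DataFrame:
    """Dataset-grouped k-fold cross-validation on a labelled corpus table.

    The table must carry ``dataset_id``, the feature columns,
    ``transformed_target``, ``ll_start`` and ``ll_neighbor``.  For each
    fold a forest is trained on the other folds and every held-out dataset
    is scored; returns one row of metrics per dataset.
    """
    feature_names = tuple(feature_names)
    ids = sorted(corpus_frame["dataset_id"].unique())
    folds = _fold_assignment(ids, k, seed)
    fold_col = corpus_frame["dataset_id"].map(folds)
    reports = []
    for fold in range(k):
        test_mask = fold_col == fold
        train_df = corpus_frame[~test_mask]
        model = train(
            train_df[list(feature_names)].to_numpy(),
            train_df["transformed_target"].to_numpy(),
            feature_names=feature_names,
            n_trees=n_trees,
            seed=seed,
        )
        for ds_id, group in corpus_frame[test_mask].groupby("dataset_id"):
            pred_tr = model.predict_transformed(group[list(feature_names)].to_numpy())
            ll_start = float(group["ll_start"].iloc[0])
            pred_delta = inverse_transform(pred_tr) * ll_start
            true_ll = group["ll_neighbor"].to_numpy()
            rho = spearman_rho(true_ll, pred_delta)
            p1, p2, improves = percentile_metrics(true_ll, pred_delta, ll_start)
            reports.append(
                {
                    "dataset_id": ds_id,
                    "fold": fold,
                    "spearman_rho": rho,
                    "best_move_predicted_percentile": p1,
                    "predicted_best_true_percentile": p2,
                    "top1_improves": improves,
                    "n_moves": int(len(group)),
                }
            )
    return pd.DataFrame(reports).sort_values("dataset_id", ignore_index=True)


def cross_validate(corpus, k: int = 10, seed: int = 0, n_trees: int = 70):
    """Cross-validate a :class:`~sprank.simulate.Corpus`.

    Returns ``(per_dataset, summary)`` where *per_dataset* has one
    MetricsReport row per dataset and *summary* holds means and medians of
    each metric.
    """
    frame = corpus.to_frame() if hasattr(corpus, "to_frame") else corpus
    per_dataset = cross_validate_frame(frame, k=k, seed=seed, n_trees=n_trees)
    summary = {
        "mean_spearman_rho": float(per_dataset["spearman_rho"].mean()),
        "median_spearman_rho": float(per_dataset["spearman_rho"].median()),
        "mean_best_move_predicted_percentile": float(
            per_dataset["best_move_predicted_percentile"].mean()
        ),
        "median_best_move_predicted_percentile": float(
            per_dataset["best_move_predicted_percentile"].median()
        ),
        "mean_predicted_best_true_percentile": float(
            per_dataset["predicted_best_true_percentile"].mean()
        ),
        "median_predicted_best_true_percentile": float(
            per_dataset["predicted_best_true_percentile"].median()
        ),
        "frac_top1_improves": float(per_dataset["top1_improves"].mean()),
        "n_datasets": int(len(per_dataset)),
    }
    return per_dataset, summary
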