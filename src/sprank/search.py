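"""Likelihood hill-climbing over SPR neighborhoods, optionally ML-guided.

The guided search ranks every SPR neighbor with a trained move ranker,
computes true (branch-length-optimized) likelihoods only for the
top-predicted fraction, and steps to the best evaluated candidate; it stops
when no evaluated candidate improves the current tree.  The exhaustive
variant evaluates every neighbor and serves as the baseline the guided
search is measured against.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import batch_features
from .learner import RankModel, inverse_transform
from .likelihood import SubstitutionModel, optimize_branch_lengths, score_all_neighbors
from .spr import apply_spr, enumerate_spr_moves
from .tree import Alignment, PhyloTree, rf_distance

logger = logging.getLogger(__name__)

__all__ = [
    "SearchStep",
    "SearchChain",
    "ForestRanker",
    "OracleRanker",
    "ml_guided_search",
    "exhaustive_hill_climb",
]


@dataclass
class SearchStep:
    iteration: int
    tree: PhyloTree
    log_likelihood: float
    n_evaluations: int
    rf_to_final: int | None = None


@dataclass
class SearchChain:
    steps: list[SearchStep] = field(default_factory=list)

    @property
    def final_tree(self) -> PhyloTree:
        return self.steps[-1].tree

    @property
    def final_log_likelihood(self) -> float:
        return self.steps[-1].log_likelihood

    @property
    def log_likelihoods(self) -> list[float]:
        return [s.log_likelihood for s in self.steps]

    def annotate_rf_to_final(self) -> None:
        final = self.final_tree
        for step in self.steps:
            step.rf_to_final = rf_distance(step.tree, final)


class ForestRanker:
    """Scores moves with a trained random-forest ranker (predicted delta-LL)."""

    def __init__(self, model: RankModel):
        self.model = model

    def score(self, tree, aln, subst_model, moves, features, ll_start) -> np.ndarray:
        pred = self.model.predict_transformed(features)
        return inverse_transform(pred) * ll_start


class OracleRanker:
    """Scores moves with their true optimized likelihoods (perfect oracle)."""

    def __init__(self, tol: float = 1e-4, max_sweeps: int = 8):
        self.tol = tol
        self.max_sweeps = max_sweeps

    def score(self, tree, aln, subst_model, moves, features, ll_start) -> np.ndarray:
        scored = score_all_neighbors(
            tree, aln, subst_model, moves, tol=self.tol, max_sweeps=self.max_sweeps
        )
        return np.array([ll - ll_start for _mv, ll in scored])


def ml_guided_search(
    start: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    ranker,
    top_fraction: float = 0.05,
    max_iters: int = 50,
    min_candidates: int = 5,
    accept_tol: float = 1e-3,
    mode: str = "top-fraction",
    neighbor_tol: float = 1e-4,
    neighbor_max_sweeps: int = 8,
) -> SearchChain:
    """Iterative SPR hill-climbing evaluating only top-ranked moves.

    At each iteration all SPR moves are enumerated and scored by *ranker*
    (any object with a ``score(tree, aln, model, moves, features, ll_start)``
    method returning higher-is-better values); true likelihoods are computed
    for the top ``ceil(top_fraction * n_moves)`` candidates (never fewer
    than *min_candidates*) and the search moves to the best if it improves
    the current log-likelihood by more than *accept_tol*.  With
    ``mode='first-improvement'`` candidates are instead evaluated in ranked
    order and the first improving move is taken.  Substitution-model
    parameters stay fixed throughout.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if mode not in ("top-fraction", "first-improvement"):
        raise ValueError(f"unknown mode {mode!r}")

    res = optimize_branch_lengths(start, aln, model, tol=neighbor_tol, max_sweeps=20)
    current, ll_current = res.tree, res.log_likelihood
    chain = SearchChain([SearchStep(0, current, ll_current, 0)])
    for iteration in range(1, max_iters + 1):
        moves = enumerate_spr_moves(current)
        if not moves:
            break
        features = batch_features(current, moves)
        scores = np.asarray(ranker.score(current, aln, model, moves, features, ll_current))
        order = np.lexsort((np.arange(len(moves)), -scores))
        n_top = min(len(moves), max(min_candidates, math.ceil(top_fraction * len(moves))))

        best_move, best_ll, n_eval = None, -np.inf, 0
        if mode == "top-fraction":
            candidates = [moves[i] for i in order[:n_top]]
            scored = score_all_neighbors(
                current, aln, model, candidates,
                tol=neighbor_tol, max_sweeps=neighbor_max_sweeps,
            )
            n_eval = len(scored)
            for mv, ll in scored:
                if ll > best_ll:
                    best_move, best_ll = mv, ll
        else:
            for i in order:
                mv = moves[i]
                (_, ll), = score_all_neighbors(
                    current, aln, model, [mv],
                    tol=neighbor_tol, max_sweeps=neighbor_max_sweeps,
                )
                n_eval += 1
                if ll > ll_current + accept_tol:
                    best_move, best_ll = mv, ll
                    break
                if ll > best_ll:
                    best_move, best_ll = mv, ll
                if n_eval >= n_top:
                    break

        if best_move is None or best_ll <= ll_current + accept_tol:
            logger.info("search converged after %d iterations", iteration - 1)
            break
        neighbor = apply_spr(current, best_move)
        res = optimize_branch_lengths(
            neighbor, aln, model, tol=neighbor_tol, max_sweeps=20
        )
        current, ll_current = res.tree, res.log_likelihood
        chain.steps.append(SearchStep(iteration, current, ll_current, n_eval))
    chain.annotate_rf_to_final()
    return chain


def exhaustive_hill_climb(
    start: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    max_iters: int = 50,
    accept_tol: float = 1e-3,
    neighbor_tol: float = 1e-4,
    neighbor_max_sweeps: int = 8,
) -> SearchChain:
    """SPR hill-climbing that evaluates every neighbor at each step."""
    res = optimize_branch_lengths(start, aln, model, tol=neighbor_tol, max_sweeps=20)
    current, ll_current = res.tree, res.log_likelihood
    chain = SearchChain([SearchStep(0, current, ll_current, 0)])
    for iteration in range(1, max_iters + 1):
        moves = enumerate_spr_moves(current)
        if not moves:
            break
        scored = score_all_neighbors(
            current, aln, model, moves, tol=neighbor_tol, max_sweeps=neighbor_max_sweeps
        )
        best_move, best_ll = None, -np.inf
        for mv, ll in scored:
            if ll > best_ll:
                best_move, best_ll = mv, ll
        if best_move is None or best_ll <= ll_current + accept_tol:
            break
        neighbor = apply_spr(current, best_move)
        res = optimize_branch_lengths(neighbor, aln, model, tol=neighbor_tol, max_sweeps=20)
        current, ll_current = res.tree, res.log_likelihood
        chain.steps.append(SearchStep(iteration, current, ll_current, len(scored)))
    chain.annotate_rf_to_final()
    return chain
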