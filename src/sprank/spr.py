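"""Subtree-prune-and-regraft (SPR) neighborhoods.

An SPR move detaches a subtree *b* at its pruned branch, merges the two
branches left dangling at the detachment point, and reattaches *b* in the
middle of a regraft branch elsewhere in the remaining tree *c*.  The move
also induces the two subtrees *c1* and *c2* on either side of the regraft
branch; the four subtrees (b, c, c1, c2) drive the move features.

Enumeration convention: one move per (directed pruned branch, regraft
branch) pair, excluding the regraft positions that recreate the starting
topology (the two branches adjacent to the detachment point), deduplicated
by resulting topology.  Under this convention every binary unrooted tree on
n leaves has exactly 2(n-3)(2n-7) SPR neighbors, independent of shape.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .tree import PhyloTree, TreeError

__all__ = [
    "SPRMove",
    "SubtreeStats",
    "SubtreeDecomposition",
    "enumerate_spr_moves",
    "apply_spr",
    "decompose",
    "spr_neighborhood_size",
]


@dataclass(frozen=True, order=True)
class SPRMove:
    """One candidate SPR rearrangement.

    ``prune_branch`` is cut; ``prune_side`` is its endpoint on the side of
    the pruned subtree (the orientation); ``regraft_branch`` is the branch of
    the remaining tree into which the pruned subtree is reinserted.
    """

    prune_branch: int
    prune_side: int
    regraft_branch: int


@dataclass(frozen=True)
class SubtreeStats:
    """Summary of one of the four move-induced subtrees."""

    n_leaves: int
    total_bl: float
    longest_bl: float
    leaves: frozenset[str]


@dataclass(frozen=True)
class SubtreeDecomposition:
    """The four subtrees induced by an SPR move.

    ``b`` includes the stub of the pruned branch in its branch-length totals;
    ``c1``/``c2`` exclude the regraft branch itself, so that
    ``c1.total_bl + c2.total_bl + regraft length == c.total_bl``.
    ``c1`` is the side of the regraft branch nearer the detachment point.
    """

    b: SubtreeStats
    c: SubtreeStats
    c1: SubtreeStats
    c2: SubtreeStats


def spr_neighborhood_size(n_taxa: int) -> int:
    """Number of distinct SPR neighbors of a binary unrooted tree."""
    if n_taxa < 4:
        return 0
    return 2 * (n_taxa - 3) * (2 * n_taxa - 7)


def _move_parts(tree: PhyloTree, move: SPRMove):
    """Validate a move and return its structural pieces.

    Returns (u, v, a1, a2, x1, x2) where u = prune-side endpoint,
    v = detachment node, a1/a2 = the two other branches at v (sorted by id),
    x1/x2 their far endpoints.
    """
    if move.prune_branch not in tree.branches:
        raise TreeError(f"unknown prune branch {move.prune_branch}")
    if move.regraft_branch not in tree.branches:
        raise TreeError(f"unknown regraft branch {move.regraft_branch}")
    u = move.prune_side
    pu, pv = tree.branch_endpoints(move.prune_branch)
    if u not in (pu, pv):
        raise TreeError("prune_side is not an endpoint of prune_branch")
    v = pv if u == pu else pu
    if tree.is_leaf(v):
        raise TreeError("cannot prune: remaining tree would be a single leaf")
    (x1, a1), (x2, a2) = sorted(
        ((nbr, bid) for nbr, bid in tree.neighbors(v).items() if bid != move.prune_branch),
        key=lambda p: p[1],
    )
    if move.regraft_branch in (move.prune_branch, a1, a2):
        raise TreeError("regraft position recreates the starting topology")
    _nodes_c, branches_c = tree.component(v, move.prune_branch)
    if move.regraft_branch not in branches_c:
        raise TreeError("regraft branch lies inside the pruned subtree")
    return u, v, a1, a2, x1, x2


def enumerate_spr_moves(tree: PhyloTree) -> list[SPRMove]:
    """All SPR moves of *tree*, one per distinct neighbor topology.

    Moves are generated in sorted (prune_branch, prune_side, regraft_branch)
    order; when several moves yield the same neighbor topology (the NNI-type
    rearrangements) only the first is kept.  Trees with fewer than 4 taxa
    have no non-trivial SPR neighbors.
    """
    if tree.n_taxa < 4:
        return []
    start_key = tree.topology_key()
    moves: list[SPRMove] = []
    seen: set[frozenset[int]] = {start_key}
    for bid in tree.branch_ids:
        for side in sorted(tree.branch_endpoints(bid)):
            v = tree.other_endpoint(bid, side)
            if tree.is_leaf(v):
                continue
            adjacent = {nbid for _nbr, nbid in tree.neighbors(v).items()}
            _nodes_c, branches_c = tree.component(v, bid)
            for g in sorted(branches_c - adjacent):
                move = SPRMove(bid, side, g)
                key = apply_spr(tree, move).topology_key()
                if key in seen:
                    continue
                seen.add(key)
                moves.append(move)
    return moves


def apply_spr(tree: PhyloTree, move: SPRMove) -> PhyloTree:
    """Apply an SPR move, returning a new tree (input unchanged).

    The two branches adjacent to the detachment point are merged with summed
    lengths; the regraft branch of length l is split into two halves and the
    pruned subtree is attached at the split point by a branch of its original
    pruned-branch length.  Total branch length is conserved.
    """
    u, v, a1, a2, x1, x2 = _move_parts(tree, move)
    t = tree.copy()
    l1 = t.branch_length(a1)
    l2 = t.branch_length(a2)
    le = t.branch_length(move.prune_branch)
    p, q = t.branch_endpoints(move.regraft_branch)
    lg = t.branch_length(move.regraft_branch)
    # detach b: remove the pruned branch and the detachment node, merge a1+a2
    t._remove_branch(move.prune_branch)
    t._remove_branch(a1)
    t._remove_branch(a2)
    t._remove_node(v)
    t._add_branch(x1, x2, l1 + l2)
    # split the regraft branch and attach b
    t._remove_branch(move.regraft_branch)
    w = t._new_node()
    t._add_branch(p, w, lg / 2.0)
    t._add_branch(w, q, lg / 2.0)
    t._add_branch(w, u, le)
    t.validate()
    return t


def branch_total(tree: PhyloTree, branch_ids: Iterable[int], extra: float | None = None) -> float:
    """Correctly-rounded sum of branch lengths (canonical ascending-id order).

    Both the per-move and the batch feature routes total branch lengths
    through this helper so their results agree exactly.
    """
    values = [tree.branch_length(b) for b in sorted(branch_ids)]
    if extra is not None:
        values.append(extra)
    return math.fsum(values)


def _component_stats(
    tree: PhyloTree, nodes: set[int], branch_ids: set[int], extra: float | None = None
) -> tuple[int, float, float, frozenset[str]]:
    leaves = frozenset(
        tree.label(n) for n in nodes if tree.is_leaf(n)
    )
    total = branch_total(tree, branch_ids, extra)
    longest = max((tree.branch_length(b) for b in branch_ids), default=0.0)
    return len(leaves), float(total), float(longest), leaves


def decompose(tree: PhyloTree, move: SPRMove) -> SubtreeDecomposition:
    """Build the four-subtree decomposition of a move by explicit traversal.

    This is the straightforward per-move route (components are walked
    explicitly); the batch feature extractor cross-checks against it.
    """
    u, v, a1, a2, x1, x2 = _move_parts(tree, move)
    le = tree.branch_length(move.prune_branch)
    lg = tree.branch_length(move.regraft_branch)
    merged = tree.branch_length(a1) + tree.branch_length(a2)

    # b: pruned subtree plus its stub
    nodes_b, branches_b = tree.component(u, move.prune_branch)
    nb, tb, lb, leaves_b = _component_stats(tree, nodes_b, branches_b, extra=le)
    b = SubtreeStats(nb, tb, max(lb, le), leaves_b)

    # c: remaining tree with the two adjacent branches merged
    nodes_c, branches_c = tree.component(v, move.prune_branch)
    nodes_c = nodes_c - {v}
    branches_c_merged = branches_c - {a1, a2}
    nc, tc, lc, leaves_c = _component_stats(tree, nodes_c, branches_c_merged, extra=merged)
    c = SubtreeStats(nc, tc, max(lc, merged), leaves_c)

    # split c at the regraft branch; decide which side holds the merged branch
    p, q = tree.branch_endpoints(move.regraft_branch)
    nodes_p, branches_p = tree.component(p, move.regraft_branch)
    if x1 in nodes_p or x2 in nodes_p:
        near, far = p, q
    else:
        near, far = q, p
    nodes_far, branches_far = tree.component(far, move.regraft_branch)
    n2, t2, l2_, leaves2 = _component_stats(tree, nodes_far, branches_far)
    c2 = SubtreeStats(n2, t2, l2_, leaves2)
    nodes_near = nodes_c - nodes_far
    branches_near = branches_c_merged - branches_far - {move.regraft_branch}
    n1, t1, l1_, leaves1 = _component_stats(tree, nodes_near, branches_near, extra=merged)
    c1 = SubtreeStats(n1, t1, max(l1_, merged), leaves1)
    return SubtreeDecomposition(b=b, c=c, c1=c1, c2=c2)
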