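"""The 19 topological / branch-length predictors of an SPR move.

For a starting tree and one candidate move the features are, in canonical
order:

1.  ``total_bl``        - sum of branch lengths of the starting tree
2.  ``longest_branch``  - longest branch of the starting tree
3.  ``pruned_bl``       - length of the pruned branch
4.  ``regraft_bl``      - length of the regraft branch
5.  ``topo_dist``       - number of branches strictly between the pruned and
                          regraft branches (neither endpoint branch counted)
6.  ``bl_dist``         - summed length of those in-between branches
7.  ``new_branch_bl``   - length of the branch formed by the pruning, i.e. the
                          merge of the two branches adjacent to the
                          detachment point
8-11.  number of leaves in subtrees b, c, c1, c2
12-15. total branch length of b, c, c1, c2
16-19. longest branch of b, c, c1, c2

where b is the pruned subtree (including its stub), c the remaining tree,
and c1/c2 the two sides of the regraft branch within c (c1 the side nearer
the detachment point; both exclude the regraft branch itself).  Features 1
and 2 do not depend on the move.

``extract_features`` recomputes everything per move from an explicit
four-subtree decomposition; ``batch_features`` produces identical values for
all moves of one tree from shared directed-subtree aggregates computed in
two traversals.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, fields

import numpy as np

from .spr import SPRMove, _move_parts, branch_total, decompose
from .tree import PhyloTree

__all__ = ["FEATURE_NAMES", "FeatureVector", "extract_features", "batch_features"]

FEATURE_NAMES = (
    "total_bl",
    "longest_branch",
    "pruned_bl",
    "regraft_bl",
    "topo_dist",
    "bl_dist",
    "new_branch_bl",
    "n_leaves_b",
    "n_leaves_c",
    "n_leaves_c1",
    "n_leaves_c2",
    "total_bl_b",
    "total_bl_c",
    "total_bl_c1",
    "total_bl_c2",
    "longest_bl_b",
    "longest_bl_c",
    "longest_bl_c1",
    "longest_bl_c2",
)


@dataclass(frozen=True)
class FeatureVector:
    total_bl: float
    longest_branch: float
    pruned_bl: float
    regraft_bl: float
    topo_dist: int
    bl_dist: float
    new_branch_bl: float
    n_leaves_b: int
    n_leaves_c: int
    n_leaves_c1: int
    n_leaves_c2: int
    total_bl_b: float
    total_bl_c: float
    total_bl_c1: float
    total_bl_c2: float
    longest_bl_b: float
    longest_bl_c: float
    longest_bl_c1: float
    longest_bl_c2: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def _path_between(tree: PhyloTree, v: int, prune_branch: int, regraft_branch: int):
    """Branch ids strictly between the detachment node *v* and the nearer
    endpoint of the regraft branch (the regraft branch itself excluded)."""
    parent_branch: dict[int, int] = {}
    parent_node: dict[int, int] = {}
    seen = {v}
    queue = deque([v])
    while queue:
        node = queue.popleft()
        for nbr, bid in sorted(tree.neighbors(node).items()):
            if bid == prune_branch or bid == regraft_branch or nbr in seen:
                continue
            seen.add(nbr)
            parent_branch[nbr] = bid
            parent_node[nbr] = node
            queue.append(nbr)
    p, q = tree.branch_endpoints(regraft_branch)
    near = p if p in seen else q
    path = []
    node = near
    while node != v:
        path.append(parent_branch[node])
        node = parent_node[node]
    return path


def extract_features(tree: PhyloTree, move: SPRMove) -> FeatureVector:
    """Per-move feature extraction from an explicit subtree decomposition."""
    _u, v, _a1, _a2, _x1, _x2 = _move_parts(tree, move)
    dec = decompose(tree, move)
    path = _path_between(tree, v, move.prune_branch, move.regraft_branch)
    merged = tree.branch_length(_a1) + tree.branch_length(_a2)
    return FeatureVector(
        total_bl=tree.total_branch_length(),
        longest_branch=tree.longest_branch(),
        pruned_bl=tree.branch_length(move.prune_branch),
        regraft_bl=tree.branch_length(move.regraft_branch),
        topo_dist=len(path),
        bl_dist=branch_total(tree, path),
        new_branch_bl=merged,
        n_leaves_b=dec.b.n_leaves,
        n_leaves_c=dec.c.n_leaves,
        n_leaves_c1=dec.c1.n_leaves,
        n_leaves_c2=dec.c2.n_leaves,
        total_bl_b=dec.b.total_bl,
        total_bl_c=dec.c.total_bl,
        total_bl_c1=dec.c1.total_bl,
        total_bl_c2=dec.c2.total_bl,
        longest_bl_b=dec.b.longest_bl,
        longest_bl_c=dec.c.longest_bl,
        longest_bl_c1=dec.c1.longest_bl,
        longest_bl_c2=dec.c2.longest_bl,
    )


@dataclass(frozen=True)
class _DirStats:
    """Aggregates of the subtree on one side of a branch (branch excluded)."""

    n_leaves: int
    total_bl: float
    longest_bl: float


def _directed_stats(tree: PhyloTree) -> dict[tuple[int, int], _DirStats]:
    """Stats of the component containing *node* when *branch* is removed,
    for every (branch id, endpoint) pair, via one down and one up pass."""
    internal = [n for n in tree.nodes if not tree.is_leaf(n)]
    root = min(internal) if internal else min(tree.nodes)
    walk = list(tree.traverse_from(root))
    children: dict[int, list[tuple[int, int]]] = {n: [] for n in tree.nodes}
    for node, parent, bid in walk:
        if parent is not None:
            children[parent].append((node, bid))

    down: dict[int, _DirStats] = {}
    for node, _parent, _bid in reversed(walk):
        nl = 1 if tree.is_leaf(node) else 0
        tot = 0.0
        lng = 0.0
        for child, bid in children[node]:
            l = tree.branch_length(bid)
            nl += down[child].n_leaves
            tot += down[child].total_bl + l
            lng = max(lng, down[child].longest_bl, l)
        down[node] = _DirStats(nl, tot, lng)

    up: dict[int, _DirStats] = {}
    for node, parent, bid_up in walk:
        for child, bid in children[node]:
            nl = 1 if tree.is_leaf(node) else 0
            tot = 0.0
            lng = 0.0
            if parent is not None:
                l = tree.branch_length(bid_up)
                nl += up[node].n_leaves
                tot += up[node].total_bl + l
                lng = max(lng, up[node].longest_bl, l)
            for sib, sbid in children[node]:
                if sib == child:
                    continue
                l = tree.branch_length(sbid)
                nl += down[sib].n_leaves
                tot += down[sib].total_bl + l
                lng = max(lng, down[sib].longest_bl, l)
            up[child] = _DirStats(nl, tot, lng)

    directed: dict[tuple[int, int], _DirStats] = {}
    for node, parent, bid in walk:
        if parent is None:
            continue
        directed[(bid, node)] = down[node]
        directed[(bid, parent)] = up[node]
    return directed


def _directed_branch_masks(tree: PhyloTree):
    """Branch-membership bitmasks of the component on each side of every
    branch (the branch itself excluded), plus the bit-position maps.

    Bits follow ascending branch-id order, so iterating set bits yields
    branch ids in canonical order for exact summation.
    """
    sorted_ids = sorted(tree.branches)
    pos = {b: i for i, b in enumerate(sorted_ids)}
    internal = [n for n in tree.nodes if not tree.is_leaf(n)]
    root = min(internal) if internal else min(tree.nodes)
    walk = list(tree.traverse_from(root))
    children: dict[int, list[tuple[int, int]]] = {n: [] for n in tree.nodes}
    for node, parent, bid in walk:
        if parent is not None:
            children[parent].append((node, bid))
    down: dict[int, int] = {}
    for node, _parent, _bid in reversed(walk):
        m = 0
        for child, bid in children[node]:
            m |= down[child] | (1 << pos[bid])
        down[node] = m
    up: dict[int, int] = {}
    for node, parent, bid_up in walk:
        for child, bid in children[node]:
            m = 0
            if parent is not None:
                m |= up[node] | (1 << pos[bid_up])
            for sib, sbid in children[node]:
                if sib != child:
                    m |= down[sib] | (1 << pos[sbid])
            up[child] = m
    masks: dict[tuple[int, int], int] = {}
    for node, parent, bid in walk:
        if parent is None:
            continue
        masks[(bid, node)] = down[node]
        masks[(bid, parent)] = up[node]
    return masks, pos, sorted_ids


def _mask_ids(mask: int, sorted_ids: list[int]):
    i = 0
    while mask:
        if mask & 1:
            yield sorted_ids[i]
        mask >>= 1
        i += 1


def batch_features(tree: PhyloTree, moves: list[SPRMove]) -> np.ndarray:
    """Feature matrix (len(moves) x 19) from shared precomputation.

    Produces values identical to :func:`extract_features`, with
    directed-subtree aggregates computed once for the whole tree and a short
    path walk per move.  Row order matches the input move order.
    """
    directed = _directed_stats(tree)
    masks, pos, sorted_ids = _directed_branch_masks(tree)
    total_tree = tree.total_branch_length()
    longest_tree = tree.longest_branch()

    # group moves by directed pruned branch so the BFS from the detachment
    # node is shared across all regraft positions of that prune
    by_prune: dict[tuple[int, int], list[int]] = {}
    for i, mv in enumerate(moves):
        by_prune.setdefault((mv.prune_branch, mv.prune_side), []).append(i)

    out = np.empty((len(moves), len(FEATURE_NAMES)))
    for (e, su), idxs in by_prune.items():
        _u, v, a1, a2, x1, x2 = _move_parts(tree, moves[idxs[0]])
        le = tree.branch_length(e)
        l1, l2 = tree.branch_length(a1), tree.branch_length(a2)
        merged = l1 + l2
        db = directed[(e, su)]
        dc = directed[(e, v)]
        leaves_b = db.n_leaves
        total_b = branch_total(tree, _mask_ids(masks[(e, su)], sorted_ids), extra=le)
        longest_b = max(db.longest_bl, le)
        leaves_c = dc.n_leaves
        mask_c = masks[(e, v)] & ~((1 << pos[a1]) | (1 << pos[a2]))
        total_c = branch_total(tree, _mask_ids(mask_c, sorted_ids), extra=merged)
        longest_c = max(dc.longest_bl, merged)

        # BFS from v avoiding the pruned branch: parent pointers for paths
        parent_branch: dict[int, int] = {}
        parent_node: dict[int, int] = {}
        depth = {v: 0}
        queue = deque([v])
        while queue:
            node = queue.popleft()
            for nbr, bid in sorted(tree.neighbors(node).items()):
                if bid == e or nbr in depth:
                    continue
                depth[nbr] = depth[node] + 1
                parent_branch[nbr] = bid
                parent_node[nbr] = node
                queue.append(nbr)

        for i in idxs:
            g = moves[i].regraft_branch
            lg = tree.branch_length(g)
            p, q = tree.branch_endpoints(g)
            near = p if parent_branch.get(q) == g else q
            far = tree.other_endpoint(g, near)
            # path of branches strictly between v and the regraft branch
            path = []
            node = near
            while node != v:
                path.append(parent_branch[node])
                node = parent_node[node]
            d2 = directed[(g, far)]
            leaves_c1 = leaves_c - d2.n_leaves
            mask_far = masks[(g, far)]
            total_c2 = branch_total(tree, _mask_ids(mask_far, sorted_ids))
            mask_c1 = mask_c & ~mask_far & ~(1 << pos[g])
            total_c1 = branch_total(tree, _mask_ids(mask_c1, sorted_ids), extra=merged)
            # longest branch on the near side: merged branch, the off-path
            # directed subtrees hanging from path nodes, and the path itself
            # beyond its first branch (which is absorbed into the merge)
            a_other, x_other = (a2, x2) if path[-1] == a1 else (a1, x1)
            cand = [merged, directed[(a_other, x_other)].longest_bl]
            cand.extend(tree.branch_length(b) for b in path[:-1])
            node = near
            prev_branch = g
            while node != v:
                for nbr, bid in tree.neighbors(node).items():
                    if bid == prev_branch or bid == parent_branch[node]:
                        continue
                    cand.append(tree.branch_length(bid))
                    cand.append(directed[(bid, nbr)].longest_bl)
                prev_branch = parent_branch[node]
                node = parent_node[node]
            longest_c1 = max(cand)

            out[i] = (
                total_tree,
                longest_tree,
                le,
                lg,
                len(path),
                branch_total(tree, path),
                merged,
                leaves_b,
                leaves_c,
                leaves_c1,
                d2.n_leaves,
                total_b,
                total_c,
                total_c1,
                total_c2,
                longest_b,
                longest_c,
                longest_c1,
                d2.longest_bl,
            )
    return out
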