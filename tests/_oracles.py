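"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's SPR machinery: tree surgery is done
on plain adjacency dictionaries and bipartitions are recomputed with local
breadth-first searches, so agreement with the library is a genuine
cross-check rather than a tautology.
"""
from __future__ import annotations

from collections import deque


def graph_of(tree):
    """Adjacency copy {node: {nbr: length}} plus {node: label} for leaves."""
    adj = {}
    for node in tree.nodes:
        adj[node] = {}
        for nbr, bid in tree.neighbors(node).items():
            adj[node][nbr] = tree.branch_length(bid)
    labels = dict(tree.leaf_nodes)
    return adj, labels


def graph_bipartitions(adj, labels):
    """Non-trivial splits of an adjacency graph as frozensets of label sets."""
    all_labels = frozenset(labels.values())
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            # leaves on the v side when edge (u, v) is removed
            seen = _component(adj, v, (u, v))
            side = frozenset(labels[x] for x in seen if x in labels)
            if 2 <= len(side) <= len(all_labels) - 2:
                splits.add(frozenset({side, all_labels - side}))
    return frozenset(splits)


def _component(adj, start, banned_edge):
    a, b = banned_edge
    seen = {start}
    queue = deque([start])
    while queue:
        x = queue.popleft()
        for y in adj[x]:
            if {x, y} == {a, b}:
                continue
            if y not in seen:
                seen.add(y)
                queue.append(y)
    return seen


def brute_force_spr_topologies(tree):
    """Set of all distinct SPR-neighbor topologies by naive surgery.

    Tries every (edge, orientation, target edge) combination with no
    exclusion logic, performs the prune+regraft on an adjacency copy, and
    discards results identical to the starting topology.
    """
    adj0, labels = graph_of(tree)
    start_split = graph_bipartitions(adj0, labels)
    out = set()
    edges = sorted({tuple(sorted((u, v))) for u in adj0 for v in adj0[u]})
    next_node = max(adj0) + 1
    for u, v in edges:
        for prune_side, attach_node in ((u, v), (v, u)):
            # b = component of prune_side without edge (u, v)
            if len(adj0[attach_node]) < 3:
                continue  # detaching here leaves no tree to regraft into
            comp_c = _component(adj0, attach_node, (u, v))
            for p, q in edges:
                if {p, q} == {u, v} or p not in comp_c or q not in comp_c:
                    continue
                if attach_node in (p, q):
                    continue  # regrafting onto an adjacent edge; handled below anyway
                adj = {x: dict(nb) for x, nb in adj0.items()}
                # detach: remove prune edge, splice out the attach node
                del adj[prune_side][attach_node]
                del adj[attach_node][prune_side]
                (n1, l1), (n2, l2) = adj[attach_node].items()
                del adj[n1][attach_node]
                del adj[n2][attach_node]
                del adj[attach_node]
                adj[n1][n2] = l1 + l2
                adj[n2][n1] = l1 + l2
                # regraft: split (p, q), connect the new node to prune_side
                if q not in adj.get(p, {}):
                    continue  # edge vanished in the splice (was adjacent)
                lg = adj[p][q]
                del adj[p][q]
                del adj[q][p]
                w = next_node
                adj[w] = {p: lg / 2, q: lg / 2, prune_side: 1.0}
                adj[p][w] = lg / 2
                adj[q][w] = lg / 2
                adj[prune_side][w] = 1.0
                split = graph_bipartitions(adj, labels)
                if split != start_split:
                    out.add(split)
    return out


def jc_pruning_loglik(tree, aln, t_scale=1.0):
    """Hand-coded Jukes-Cantor pruning likelihood (site by site, no scaling).

    Small-instance oracle for the general GTR machinery: uses the JC
    closed-form transition probabilities directly.
    """
    import math

    adj, labels = graph_of(tree)
    root = next(n for n in adj if n not in labels)

    def p_match(t):
        return 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)

    def p_mismatch(t):
        return 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)

    total = 0.0
    for site in range(aln.length):
        chars = {lab: aln.sequence(lab)[site].upper() for lab in aln.taxa}

        def partial(node, parent):
            if node in labels:
                c = chars[labels[node]]
                if c in "ACGT" or c == "U":
                    c = "T" if c == "U" else c
                    return [1.0 if b == c else 0.0 for b in "ACGT"]
                return [1.0] * 4
            out = [1.0] * 4
            for nbr, length in adj[node].items():
                if nbr == parent:
                    continue
                sub = partial(nbr, node)
                for i in range(4):
                    s = 0.0
                    for j in range(4):
                        pij = p_match(length) if i == j else p_mismatch(length)
                        s += pij * sub[j]
                    out[i] *= s
            return out

        vec = partial(root, None)
        total += math.log(0.25 * sum(vec))
    return total
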