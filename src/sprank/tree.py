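"""Unrooted phylogenetic trees, alignments, Newick/FASTA I/O, RF distance, NJ starting trees.

The central object is :class:`PhyloTree`, an unrooted binary tree over a set of
labelled leaves with non-negative branch lengths (in expected substitutions per
site).  Internally the tree is stored as an undirected adjacency structure;
every branch carries a stable integer id assigned at construction time so that
rearrangement moves and feature vectors can refer to branches across
operations.

Trees with ``n_taxa >= 3`` are strictly binary: every internal node has degree
exactly 3.  Two-taxon trees (a single branch) are supported as a degenerate
case because they are useful for closed-form likelihood checks.
"""
from __future__ import annotations

import io
import logging
import math
import re
from collections import deque
from typing import Iterable, Iterator

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "AlignmentError",
    "PhyloTree",
    "Alignment",
    "read_newick",
    "write_newick",
    "rf_distance",
    "build_starting_tree",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class AlignmentError(ValueError):
    """Raised for invalid alignments."""


# nucleotide codes used throughout: A=0 C=1 G=2 T=3, anything else = -1 (missing)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class PhyloTree:
    """Unrooted binary phylogeny with branch lengths.

    Nodes are opaque integer ids; leaves carry taxon labels.  Branches are
    identified by stable integer ids; ``branches[bid] == (u, v)`` with
    ``u < v``.
    """

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, int]] = {}
        self._labels: dict[int, str] = {}
        self._lengths: dict[int, float] = {}
        self._branches: dict[int, tuple[int, int]] = {}
        self._next_node = 0
        self._next_branch = 0

    # ------------------------------------------------------------------ basics

    def _new_node(self, label: str | None = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self._adj[nid] = {}
        if label is not None:
            self._labels[nid] = label
        return nid

    def _add_branch(self, u: int, v: int, length: float, bid: int | None = None) -> int:
        if bid is None:
            bid = self._next_branch
            self._next_branch = max(self._next_branch, bid) + 1
        else:
            self._next_branch = max(self._next_branch, bid + 1)
        self._branches[bid] = (u, v) if u < v else (v, u)
        self._lengths[bid] = float(length)
        self._adj[u][v] = bid
        self._adj[v][u] = bid
        return bid

    def _remove_branch(self, bid: int) -> None:
        u, v = self._branches.pop(bid)
        del self._lengths[bid]
        del self._adj[u][v]
        del self._adj[v][u]

    def _remove_node(self, nid: int) -> None:
        if self._adj[nid]:
            raise TreeError("cannot remove node with incident branches")
        del self._adj[nid]
        self._labels.pop(nid, None)

    # ------------------------------------------------------------------ queries

    @property
    def nodes(self) -> list[int]:
        return sorted(self._adj)

    @property
    def branches(self) -> dict[int, tuple[int, int]]:
        return dict(self._branches)

    @property
    def branch_ids(self) -> list[int]:
        return sorted(self._branches)

    @property
    def branch_lengths(self) -> dict[int, float]:
        return dict(self._lengths)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._labels.values())

    @property
    def leaf_nodes(self) -> dict[int, str]:
        return dict(self._labels)

    @property
    def n_taxa(self) -> int:
        return len(self._labels)

    def is_leaf(self, nid: int) -> bool:
        return nid in self._labels

    def label(self, nid: int) -> str | None:
        return self._labels.get(nid)

    def degree(self, nid: int) -> int:
        return len(self._adj[nid])

    def neighbors(self, nid: int) -> dict[int, int]:
        """Map neighbor node -> connecting branch id."""
        return dict(self._adj[nid])

    def branch_endpoints(self, bid: int) -> tuple[int, int]:
        return self._branches[bid]

    def branch_length(self, bid: int) -> float:
        return self._lengths[bid]

    def set_branch_length(self, bid: int, length: float) -> None:
        if not math.isfinite(length) or length < 0:
            raise TreeError(f"branch length must be finite and >= 0, got {length}")
        self._lengths[bid] = float(length)

    def total_branch_length(self) -> float:
        # correctly-rounded, order-independent sum
        return math.fsum(self._lengths[b] for b in sorted(self._lengths))

    def longest_branch(self) -> float:
        return float(max(self._lengths.values()))

    def other_endpoint(self, bid: int, nid: int) -> int:
        u, v = self._branches[bid]
        if nid == u:
            return v
        if nid == v:
            return u
        raise TreeError(f"node {nid} is not an endpoint of branch {bid}")

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {n: dict(nb) for n, nb in self._adj.items()}
        t._labels = dict(self._labels)
        t._lengths = dict(self._lengths)
        t._branches = dict(self._branches)
        t._next_node = self._next_node
        t._next_branch = self._next_branch
        return t

    # ------------------------------------------------------------- validation

    def validate(self) -> None:
        labels = list(self._labels.values())
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate taxon labels")
        if any(not lab for lab in labels):
            raise TreeError("empty taxon label")
        n = self.n_taxa
        if n < 2:
            raise TreeError("tree must have at least 2 leaves")
        for nid in self._adj:
            d = self.degree(nid)
            if self.is_leaf(nid):
                if d != 1:
                    raise TreeError(f"leaf node {nid} has degree {d}")
            elif d != 3:
                raise TreeError(f"internal node {nid} has degree {d}, expected 3")
        for bid, length in self._lengths.items():
            if not math.isfinite(length) or length < 0:
                raise TreeError(f"branch {bid} has invalid length {length}")
        expected = 1 if n == 2 else 2 * n - 3
        if len(self._branches) != expected:
            raise TreeError(
                f"{len(self._branches)} branches for {n} taxa, expected {expected}"
            )

    # ------------------------------------------------------------- traversals

    def traverse_from(self, start: int, blocked_branch: int | None = None) -> Iterator[tuple[int, int | None, int | None]]:
        """Yield (node, parent, branch-to-parent) over the component of
        *start*, optionally refusing to cross *blocked_branch* (BFS order)."""
        seen = {start}
        queue = deque([(start, None, None)])
        while queue:
            node, parent, bid = queue.popleft()
            yield node, parent, bid
            for nbr, nbid in sorted(self._adj[node].items()):
                if nbid == blocked_branch or nbr in seen:
                    continue
                seen.add(nbr)
                queue.append((nbr, node, nbid))

    def component(self, start: int, blocked_branch: int) -> tuple[set[int], set[int]]:
        """Nodes and branch ids in the component of *start* when
        *blocked_branch* is removed (the blocked branch is excluded)."""
        nodes, branches = set(), set()
        for node, _parent, bid in self.traverse_from(start, blocked_branch):
            nodes.add(node)
            if bid is not None:
                branches.add(bid)
        return nodes, branches

    # ----------------------------------------------------------- bipartitions

    def _leaf_bit_order(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(sorted(self._labels.values()))}

    def split_masks(self) -> frozenset[int]:
        """Non-trivial bipartitions encoded as canonical leaf bitmasks.

        Each internal branch induces a split of the leaf set; the side not
        containing the alphabetically first taxon is encoded as a bitmask
        over the sorted taxon order.  Used for RF distance and for
        deduplicating rearrangement results by topology.
        """
        order = self._leaf_bit_order()
        n = len(order)
        full = (1 << n) - 1
        # post-order accumulation of leaf masks from an arbitrary root
        root = next(iter(self._adj))
        walk = list(self.traverse_from(root))
        mask: dict[int, int] = {}
        for node, parent, _bid in reversed(walk):
            m = mask.get(node, 0)
            if self.is_leaf(node):
                m |= 1 << order[self._labels[node]]
            mask[node] = m
            if parent is not None:
                mask[parent] = mask.get(parent, 0) | m
        splits = set()
        for node, parent, bid in walk:
            if parent is None:
                continue
            m = mask[node]
            if m & 1:
                m ^= full
            pc = bin(m).count("1")
            if 2 <= pc <= n - 2:
                splits.add(m)
        return frozenset(splits)

    def topology_key(self) -> frozenset[int]:
        return self.split_masks()

    # ------------------------------------------------------------------ newick

    def _format_label(self, label: str) -> str:
        if re.fullmatch(r"[A-Za-z0-9_.\-|/]+", label):
            return label
        return "'" + label.replace("'", "''") + "'"

    def to_newick(self, precision: int = 10) -> str:
        """Serialize to Newick.  Deterministic: rooted for output at the
        internal node adjacent to the alphabetically first taxon, children
        ordered by their smallest leaf label."""
        fmt = f"%.{precision}g"
        if self.n_taxa == 2:
            (a, la), (b, lb) = sorted(self._labels.items(), key=lambda kv: kv[1])
            bid = self._adj[a][b]
            half = self._lengths[bid] / 2.0
            return (
                f"({self._format_label(la)}:{fmt % half},"
                f"{self._format_label(lb)}:{fmt % half});"
            )
        first_leaf = min(self._labels, key=lambda nid: self._labels[nid])
        root = next(iter(self._adj[first_leaf]))

        def subtree_min(node: int, bid_from: int) -> str:
            best = None
            for nd, _p, _b in self.traverse_from(node, blocked_branch=bid_from):
                lab = self._labels.get(nd)
                if lab is not None and (best is None or lab < best):
                    best = lab
            return best or ""

        def render(node: int, bid_from: int) -> str:
            length = fmt % self._lengths[bid_from]
            if self.is_leaf(node):
                return f"{self._format_label(self._labels[node])}:{length}"
            parts = []
            for nbr, bid in self._adj[node].items():
                if bid == bid_from:
                    continue
                parts.append((subtree_min(nbr, bid), render(nbr, bid)))
            inner = ",".join(p for _k, p in sorted(parts))
            return f"({inner}):{length}"

        parts = []
        for nbr, bid in self._adj[root].items():
            key = self._labels[nbr] if self.is_leaf(nbr) else subtree_min(nbr, bid)
            parts.append((key, render(nbr, bid)))
        inner = ",".join(p for _k, p in sorted(parts))
        return f"({inner});"

    # -------------------------------------------------------------- mutations

    def suppress_degree_two(self) -> None:
        """Merge the two branches incident to any degree-2 internal node,
        summing their lengths (used to unroot parsed rooted trees)."""
        changed = True
        while changed:
            changed = False
            for nid in list(self._adj):
                if not self.is_leaf(nid) and self.degree(nid) == 2:
                    (n1, b1), (n2, b2) = sorted(self._adj[nid].items())
                    length = self._lengths[b1] + self._lengths[b2]
                    self._remove_branch(b1)
                    self._remove_branch(b2)
                    self._remove_node(nid)
                    self._add_branch(n1, n2, length)
                    changed = True
                    break

    def renumber(self) -> None:
        """Compact node and branch ids to 0..k-1 preserving relative order."""
        node_map = {old: i for i, old in enumerate(sorted(self._adj))}
        branch_map = {old: i for i, old in enumerate(sorted(self._branches))}
        self._adj = {
            node_map[n]: {node_map[m]: branch_map[b] for m, b in nb.items()}
            for n, nb in self._adj.items()
        }
        self._labels = {node_map[n]: lab for n, lab in self._labels.items()}
        self._branches = {
            branch_map[b]: tuple(sorted((node_map[u], node_map[v])))
            for b, (u, v) in self._branches.items()
        }
        self._lengths = {branch_map[b]: l for b, l in self._lengths.items()}
        self._next_node = len(self._adj)
        self._next_branch = len(self._branches)


# ---------------------------------------------------------------------- parse


def read_newick(text: str, default_length: float = 0.0) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    A rooted (bifurcating-root) input is unrooted by merging the root's two
    incident branches, summing their lengths.  Internal node labels /
    support values are ignored with a warning.  Missing branch lengths
    default to *default_length*.
    """
    if not isinstance(text, str) or not text.strip():
        raise TreeError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    t = PhyloTree()
    node_map: dict[object, int] = {}
    saw_internal_label = False
    for dnode in dtree.preorder_node_iter():
        is_leaf = dnode.is_leaf()
        label = None
        if is_leaf:
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("leaf without a taxon label")
            label = dnode.taxon.label
        elif dnode.label:
            saw_internal_label = True
        node_map[dnode] = t._new_node(label)
        if dnode.parent_node is not None:
            length = dnode.edge.length
            if length is None:
                length = default_length
            if length < 0:
                raise TreeError(f"negative branch length {length}")
            t._add_branch(node_map[dnode.parent_node], node_map[dnode], length)
    if saw_internal_label:
        logger.warning("internal node labels/support values in Newick input ignored")
    labels = list(t._labels.values())
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate taxon labels in Newick input")
    t.suppress_degree_two()
    t.renumber()
    t.validate()
    return t


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    return tree.to_newick(precision=precision)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets.  Requires identical leaf sets."""
    if t1.leaves != t2.leaves:
        raise TreeError("leaf sets differ")
    return len(t1.split_masks() ^ t2.split_masks())


# ------------------------------------------------------------------ alignment


class Alignment:
    """Nucleotide multiple sequence alignment.

    Sequences are uppercase strings over {A,C,G,T,U,-,N,...}; gap and
    ambiguity characters are treated as missing data by the likelihood
    machinery.  A sequence consisting entirely of gap/missing characters is
    rejected.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise AlignmentError("alignment has no sequences")
        seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        (self.length,) = lengths
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        for name, s in seqs.items():
            if not name:
                raise AlignmentError("empty taxon name")
            if all(c not in _CODE for c in s):
                raise AlignmentError(
                    f"sequence {name!r} is entirely gapped/missing"
                )
        self._seqs = seqs
        self.taxa: tuple[str, ...] = tuple(sorted(seqs))
        self._encoded: np.ndarray | None = None
        self._patterns: tuple[np.ndarray, np.ndarray] | None = None
        self._leaf_partials: dict[str, np.ndarray] | None = None
        self._compat: np.ndarray | None = None

    @property
    def n_taxa(self) -> int:
        return len(self._seqs)

    def sequence(self, taxon: str) -> str:
        return self._seqs[taxon]

    def items(self) -> Iterable[tuple[str, str]]:
        return ((t, self._seqs[t]) for t in self.taxa)

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        from Bio import SeqIO

        if isinstance(source, (str,)):
            handle = open(source)
            close = True
        else:
            handle, close = source, False
        try:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        finally:
            if close:
                handle.close()
        return cls(seqs)

    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle = open(handle, "w")
            close = True
        try:
            for name in self.taxa:
                handle.write(f">{name}\n{self._seqs[name]}\n")
        finally:
            if close:
                handle.close()

    def encoded(self) -> np.ndarray:
        """(n_taxa, length) int8 matrix in sorted-taxon order; -1 = missing."""
        if self._encoded is None:
            mat = np.full((self.n_taxa, self.length), -1, dtype=np.int8)
            for i, taxon in enumerate(self.taxa):
                row = np.frombuffer(self._seqs[taxon].encode(), dtype=np.uint8)
                for char, code in _CODE.items():
                    mat[i, row == ord(char)] = code
            self._encoded = mat
        return self._encoded

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities.

        Returns ``(codes, weights)`` with ``codes`` of shape
        (n_taxa, n_patterns) in sorted-taxon order.
        """
        if self._patterns is None:
            mat = self.encoded()
            cols, weights = np.unique(mat, axis=1, return_counts=True)
            self._patterns = (cols, weights.astype(np.float64))
        return self._patterns

    def leaf_partials(self) -> dict[str, np.ndarray]:
        """Per-taxon pattern indicator matrices (n_patterns, 4); missing -> 1s.

        Cached: these depend only on the alignment, so likelihood kernels for
        many trees share them (read-only).
        """
        if self._leaf_partials is None:
            codes, _w = self.patterns()
            eye = np.eye(4)
            out = {}
            for i, taxon in enumerate(self.taxa):
                col = codes[i]
                part = np.ones((codes.shape[1], 4))
                known = col >= 0
                part[known] = eye[col[known]]
                out[taxon] = part
            self._leaf_partials = out
        return self._leaf_partials

    def invariant_compat(self) -> np.ndarray:
        """(n_patterns, 4) bools: states compatible with the pattern being
        an invariant site (all non-missing characters equal that state)."""
        if self._compat is None:
            codes, _w = self.patterns()
            compat = np.ones((codes.shape[1], 4), dtype=bool)
            eye = np.eye(4, dtype=bool)
            for row in codes:
                known = row >= 0
                compat[known] &= eye[row[known]]
            self._compat = compat
        return self._compat

    def base_frequencies(self, floor: float = 1e-6) -> np.ndarray:
        """Empirical A,C,G,T frequencies over non-missing characters."""
        mat = self.encoded()
        counts = np.array([(mat == k).sum() for k in range(4)], dtype=float)
        if counts.sum() == 0:
            return np.full(4, 0.25)
        freqs = counts / counts.sum()
        freqs = np.maximum(freqs, floor)
        return freqs / freqs.sum()


# ------------------------------------------------------------- starting tree


def jc_distance_matrix(aln: Alignment, max_distance: float = 10.0) -> np.ndarray:
    """Pairwise Jukes-Cantor corrected distances, d = -3/4 ln(1 - 4p/3).

    Saturated pairs (p >= 3/4) and pairs with no comparable sites are capped
    at *max_distance* with a warning.
    """
    mat = aln.encoded()
    n = aln.n_taxa
    dist = np.zeros((n, n))
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = (mat[i] >= 0) & (mat[j] >= 0)
            nv = int(valid.sum())
            if nv == 0:
                d = max_distance
                capped += 1
            else:
                p = float((mat[i][valid] != mat[j][valid]).mean())
                if p >= 0.749999:
                    d = max_distance
                    capped += 1
                else:
                    d = -0.75 * math.log1p(-4.0 * p / 3.0)
                    d = min(d, max_distance)
            dist[i, j] = dist[j, i] = d
    if capped:
        logger.warning(
            "%d saturated/incomparable pairs capped at distance %g", capped, max_distance
        )
    return dist


def build_starting_tree(aln: Alignment, max_distance: float = 10.0) -> PhyloTree:
    """Neighbor-joining starting tree on JC-corrected distances.

    Negative NJ branch-length estimates are clamped to zero.  Requires at
    least 3 taxa.
    """
    if aln.n_taxa < 3:
        raise AlignmentError("need >= 3 taxa for a starting tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(jc_distance_matrix(aln, max_distance), ids=list(aln.taxa))
    tn = nj(dm)
    for node in tn.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tn.write(buf, format="newick")
    tree = read_newick(buf.getvalue())
    tree.validate()
    return tree
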