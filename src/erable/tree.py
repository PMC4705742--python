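"""Unrooted phylogenetic trees: parsing, restriction, and path arithmetic.

Trees are stored unrooted (rooted Newick input is accepted; the degree-2
root is suppressed on input, summing the two incident branch lengths).
Edges carry integer ids local to a tree; identity of edges *across* trees
is by leaf-set bipartition, which is what :meth:`PhyloTree.bipartitions`
exposes. Multifurcations are allowed throughout.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .distmat import DistanceMatrix
from .errors import NewickParseError, TreeError

__all__ = [
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "restrict",
    "patristic_distances",
    "path_edges",
    "normalize_total_length",
    "export_bipartitions",
]


class PhyloTree:
    """An unrooted, connected, acyclic graph with uniquely labelled leaves.

    Construct via :meth:`from_newick` or :meth:`from_edges`; instances are
    treated as immutable (mutating operations return new trees).
    """

    __slots__ = ("_adj", "_ends", "_lengths", "_leaf_of", "_label_of")

    def __init__(
        self,
        ends: Sequence[tuple[int, int]],
        lengths: Sequence[float | None],
        leaf_labels: Mapping[int, str],
    ) -> None:
        ends = [(int(u), int(v)) for u, v in ends]
        adj: dict[int, dict[int, int]] = {}
        for eid, (u, v) in enumerate(ends):
            if u == v:
                raise TreeError("self-loop edge")
            adj.setdefault(u, {})
            adj.setdefault(v, {})
            if v in adj[u]:
                raise TreeError("parallel edges")
            adj[u][v] = eid
            adj[v][u] = eid
        nodes = set(adj)
        if not nodes:
            raise TreeError("empty tree")
        if len(ends) != len(nodes) - 1:
            raise TreeError("edge count must be node count - 1 (tree property)")
        # connectivity (acyclicity follows from the edge count)
        seen = {next(iter(nodes))}
        stack = list(seen)
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if seen != nodes:
            raise TreeError("graph is not connected")
        labels = dict(leaf_labels)
        if any(not lab for lab in labels.values()):
            raise TreeError("empty leaf label")
        if len(set(labels.values())) != len(labels):
            dupes = sorted({l for l in labels.values()
                            if list(labels.values()).count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for node in nodes:
            deg = len(adj[node])
            if deg == 1 and node not in labels:
                raise TreeError("degree-1 node without a leaf label")
            if deg > 1 and node in labels:
                raise TreeError(f"labelled node {labels[node]!r} is not a leaf")
        lens = []
        for x in lengths:
            if x is None:
                lens.append(None)
            else:
                x = float(x)
                if not math.isfinite(x):
                    raise TreeError("branch lengths must be finite")
                lens.append(x)
        if len(lens) != len(ends):
            raise TreeError("one length slot per edge required")
        self._adj = adj
        self._ends = ends
        self._lengths = lens
        self._leaf_of = {lab: node for node, lab in labels.items()}
        self._label_of = labels

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int, float | None]],
        leaf_labels: Mapping[int, str],
    ) -> "PhyloTree":
        edges = list(edges)
        return cls([(u, v) for u, v, _ in edges], [l for _, _, l in edges], leaf_labels)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy reports line/column in the message
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        ids: dict[int, int] = {}
        ends: list[tuple[int, int]] = []
        lengths: list[float | None] = []
        labels: dict[int, str] = {}
        for node in dt.preorder_node_iter():
            ids[id(node)] = len(ids)
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickParseError("leaf without a label")
                labels[ids[id(node)]] = node.taxon.label
            if node.parent_node is not None:
                ends.append((ids[id(node.parent_node)], ids[id(node)]))
                lengths.append(node.edge.length)
        if not ends:
            raise NewickParseError("tree has fewer than two nodes")
        ends, lengths, labels = _suppress_degree2(ends, lengths, labels)
        return cls(ends, lengths, labels)

    # -- basic attributes ----------------------------------------------------

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._leaf_of)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_of)

    @property
    def n_edges(self) -> int:
        return len(self._ends)

    @property
    def has_lengths(self) -> bool:
        return all(x is not None for x in self._lengths)

    @property
    def edge_lengths(self) -> np.ndarray:
        """Lengths indexed by edge id; ``NaN`` where absent."""
        return np.array(
            [np.nan if x is None else x for x in self._lengths], dtype=float
        )

    def edge_length(self, eid: int) -> float | None:
        return self._lengths[eid]

    @property
    def total_length(self) -> float:
        if not self.has_lengths:
            raise TreeError("tree has edges without lengths")
        return float(sum(self._lengths))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves}, n_edges={self.n_edges})"

    @property
    def leaf_nodes(self) -> dict[str, int]:
        """Label -> node id (a copy)."""
        return dict(self._leaf_of)

    def edges_preorder(self) -> list[tuple[int, int, int]]:
        """(parent, child, edge id) triples in a deterministic preorder from
        a maximum-degree node — a ready-made rooting for simulations."""
        root = max(self._adj, key=lambda n: (len(self._adj[n]), -n))
        out: list[tuple[int, int, int]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            for child, eid in sorted(self._adj[node].items()):
                if child != parent:
                    out.append((node, child, eid))
                    stack.append((child, node))
        return out

    # -- derived trees -------------------------------------------------------

    def with_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        lens = np.asarray(lengths, dtype=float)
        if lens.shape != (self.n_edges,):
            raise TreeError("length vector must have one entry per edge")
        return PhyloTree(self._ends, lens.tolist(), dict(self._label_of))

    def normalized(self) -> "PhyloTree":
        """Rescale so branch lengths sum to one (proportions unchanged)."""
        total = self.total_length
        if total <= 0:
            raise TreeError("total branch length must be positive to normalize")
        return self.with_lengths(self.edge_lengths / total)

    def restrict(self, taxa: Iterable[str]) -> "PhyloTree":
        """Induced tree on ``taxa``: prune everything else and suppress the
        resulting degree-2 nodes (their incident lengths are summed), so
        patristic distances among retained taxa are unchanged."""
        taxa = set(taxa)
        if not taxa <= self.leaves:
            raise TreeError(f"not leaves of this tree: {sorted(taxa - self.leaves)}")
        if len(taxa) < 2:
            raise TreeError("restriction needs at least two taxa")
        adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        keep_nodes = {self._leaf_of[t] for t in taxa}
        # iteratively strip non-selected tips
        fringe = deque(
            n for n in adj if len(adj[n]) == 1 and n not in keep_nodes
        )
        while fringe:
            n = fringe.popleft()
            if n not in adj or len(adj[n]) != 1:
                continue
            (nbr,) = adj[n]
            del adj[nbr][n]
            del adj[n]
            if len(adj[nbr]) == 1 and nbr not in keep_nodes:
                fringe.append(nbr)
        ends, lengths, labels = [], [], {}
        for u in adj:
            for v, eid in adj[u].items():
                if u < v:
                    ends.append((u, v))
                    lengths.append(self._lengths[eid])
            if u in self._label_of and u in keep_nodes:
                labels[u] = self._label_of[u]
        ends, lengths, labels = _suppress_degree2(ends, lengths, labels)
        return PhyloTree(ends, lengths, labels)

    # -- path arithmetic -----------------------------------------------------

    def path_edges(self, i: str, j: str) -> frozenset[int]:
        """Edge ids of the unique simple path between leaves ``i`` and ``j``."""
        for t in (i, j):
            if t not in self._leaf_of:
                raise TreeError(f"unknown taxon {t!r}")
        if i == j:
            raise TreeError("path endpoints must differ")
        src, dst = self._leaf_of[i], self._leaf_of[j]
        parent: dict[int, tuple[int, int]] = {src: (-1, -1)}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            if u == dst:
                break
            for v, eid in self._adj[u].items():
                if v not in parent:
                    parent[v] = (u, eid)
                    queue.append(v)
        path = []
        node = dst
        while node != src:
            node, eid = parent[node]
            path.append(eid)
        return frozenset(path)

    def patristic_matrix(self) -> DistanceMatrix:
        """All leaf-to-leaf path-length sums, as a :class:`DistanceMatrix`."""
        if not self.has_lengths:
            raise TreeError("patristic distances require lengths on every edge")
        taxa = sorted(self._leaf_of)
        n = len(taxa)
        out = np.zeros((n, n))
        for a, t in enumerate(taxa):
            dist = {self._leaf_of[t]: 0.0}
            queue = deque([self._leaf_of[t]])
            while queue:
                u = queue.popleft()
                for v, eid in self._adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + self._lengths[eid]
                        queue.append(v)
            for b in range(n):
                out[a, b] = dist[self._leaf_of[taxa[b]]]
        np.fill_diagonal(out, 0.0)
        return DistanceMatrix(taxa, (out + out.T) / 2.0)

    # -- bipartitions --------------------------------------------------------

    def bipartitions(self) -> dict[int, frozenset[str]]:
        """Map edge id -> the leaf set on the side *not* containing the
        lexicographically smallest leaf (a canonical split encoding, stable
        across trees with the same leaf set)."""
        anchor = min(self.leaves)
        out = {}
        for eid, (u, v) in enumerate(self._ends):
            side = self._leaves_behind(v, u)
            if anchor in side:
                side = self.leaves - side
            out[eid] = frozenset(side)
        return out

    def _leaves_behind(self, start: int, blocked: int) -> set[str]:
        seen = {start, blocked}
        stack = [start]
        labs = set()
        while stack:
            u = stack.pop()
            if u in self._label_of:
                labs.add(self._label_of[u])
            for v in self._adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return labs

    # -- serialization -------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        """Newick string; lengths in fixed notation with ``precision``
        decimal places, omitted entirely on edges without lengths."""
        if precision < 1:
            raise TreeError("precision must be a positive integer")
        root = max(self._adj, key=lambda n: (len(self._adj[n]), -n))

        def fmt(eid: int) -> str:
            x = self._lengths[eid]
            return "" if x is None else f":{x:.{precision}f}"

        def sub(node: int, parent: int) -> str:
            children = [
                (v, eid) for v, eid in sorted(self._adj[node].items()) if v != parent
            ]
            if not children:
                return _quote(self._label_of[node])
            inner = ",".join(sub(v, node) + fmt(eid) for v, eid in children)
            return f"({inner})"

        if len(self._adj[root]) == 1:  # two-node tree: root at the leaf
            (child, eid), = self._adj[root].items()
            return f"({sub(child, root)}{fmt(eid)}){_quote(self._label_of[root])};"
        return sub(root, -1) + ";"


def _suppress_degree2(ends, lengths, labels):
    """Remove unlabelled degree-2 nodes, concatenating their two edges.
    The merged edge length is the sum when both are present, else None."""
    adj: dict[int, dict[int, int]] = {}
    for eid, (u, v) in enumerate(ends):
        adj.setdefault(u, {})[v] = eid
        adj.setdefault(v, {})[u] = eid
    lengths = list(lengths)
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node in labels or len(adj.get(node, {})) != 2:
                continue
            (a, e1), (b, e2) = adj[node].items()
            if a == b:
                continue
            la, lb = lengths[e1], lengths[e2]
            # rooted Newick often leaves the root edge unlengthed: a missing
            # length contributes nothing if the other half is present
            merged = None if (la is None and lb is None) else (la or 0.0) + (lb or 0.0)
            del adj[a][node]
            del adj[b][node]
            del adj[node]
            lengths.append(merged)
            eid = len(lengths) - 1
            adj[a][b] = eid
            adj[b][a] = eid
            changed = True
    new_ends, new_lengths = [], []
    emitted = set()
    for u in sorted(adj):
        for v, eid in sorted(adj[u].items()):
            if eid not in emitted:
                emitted.add(eid)
                new_ends.append((u, v))
                new_lengths.append(lengths[eid])
    return new_ends, new_lengths, {n: l for n, l in labels.items() if n in adj}


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`<> \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- functional aliases (module-level operation surface) ----------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into an (unrooted) :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    return tree.to_newick(precision=precision)


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    return tree.restrict(taxa)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    return tree.patristic_matrix()


def path_edges(tree: PhyloTree, i: str, j: str) -> frozenset[int]:
    return tree.path_edges(i, j)


def normalize_total_length(tree: PhyloTree) -> PhyloTree:
    return tree.normalized()


def export_bipartitions(tree: PhyloTree, path) -> None:
    """TSV table: edge id, |-separated smaller-side leaf set, length."""
    bip = tree.bipartitions()
    with open(path, "w") as fh:
        fh.write("edge\tsmaller_side\tlength\n")
        for eid in range(tree.n_edges):
            side = bip[eid]
            other = tree.leaves - side
            small = side if len(side) <= len(other) else other
            x = tree.edge_length(eid)
            fh.write(
                f"{eid}\t{'|'.join(sorted(small))}\t"
                f"{'' if x is None else repr(x)}\n"
            )
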