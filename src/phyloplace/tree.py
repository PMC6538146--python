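"""Reference tree with numbered edges.

Phylogenetic placement tools report query positions relative to the
*edges* of a fixed reference tree, identified by integer edge numbers
embedded in the Newick string (``{N}`` in pplacer/jplace style, ``[N]``
in the older EPA style).  This module parses that dialect into a compact
array-backed tree that the mass, distance, and factorization code can
traverse cheaply.

The tree is expected to be strictly bifurcating; an unrooted input keeps
its top-level trifurcation, whose junction node serves as the "root" for
all root-side/non-root-side conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["ReferenceTree", "TreeFormatError"]

_CURLY_EDGE = re.compile(r"\{(\d+)\}")


class TreeFormatError(ValueError):
    """Raised when a Newick string violates the edge-numbered dialect."""


@dataclass
class ReferenceTree:
    """Edge-numbered, (mostly) bifurcating reference tree.

    Nodes are integers, ``0`` is the root.  Every non-root node has
    exactly one parent edge; per-node arrays therefore double as
    per-edge storage keyed by the *child* node of the edge.

    Attributes
    ----------
    parent : (num_nodes,) int array, ``-1`` for the root.
    children : adjacency lists, child order as in the Newick string.
    labels : taxon label per node, ``None`` for anonymous inner nodes.
    node_edge_num : jplace edge number of the edge above each node
        (``-1`` for the root, unless the input carries a root edge).
    node_branch_length : length of the edge above each node.
    """

    parent: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    node_edge_num: np.ndarray
    node_branch_length: np.ndarray
    root_edge_num: int = -1
    root_branch_length: float = 0.0

    # derived, filled in __post_init__
    edge_order: np.ndarray = field(init=False)
    _edge_col: dict[int, int] = field(init=False, repr=False)
    _col_child: np.ndarray = field(init=False, repr=False)
    _preorder: np.ndarray = field(init=False, repr=False)
    _postorder: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._preorder = self._traverse(post=False)
        self._postorder = self._traverse(post=True)
        # Canonical edge/column order: preorder from the root, so that
        # matrices built on the same tree are comparable across runs.
        order = [self.node_edge_num[v] for v in self._preorder if self.node_edge_num[v] >= 0]
        if self.root_edge_num >= 0:
            order.insert(0, self.root_edge_num)
        self.edge_order = np.asarray(order, dtype=np.intp)
        self._edge_col = {int(e): i for i, e in enumerate(self.edge_order)}
        if len(self._edge_col) != len(self.edge_order):
            raise TreeFormatError("duplicate edge numbers in tree")
        col_child = np.full(self.num_edges, -1, dtype=np.intp)
        for v in range(self.num_nodes):
            e = self.node_edge_num[v]
            if e >= 0:
                col_child[self._edge_col[int(e)]] = v
        if self.root_edge_num >= 0:
            col_child[self._edge_col[self.root_edge_num]] = 0
        self._col_child = col_child
        self._validate()

    # ------------------------------------------------------------------
    # construction

    @classmethod
    def from_newick(cls, newick: str) -> "ReferenceTree":
        """Parse an edge-numbered Newick string (``{N}`` or ``[N]`` style)."""
        text = newick.strip()
        if _CURLY_EDGE.search(text):
            text = _CURLY_EDGE.sub(r"[\1]", text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeFormatError(f"cannot parse reference tree: {exc}") from exc

        dnodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        n = len(dnodes)
        parent = np.full(n, -1, dtype=np.intp)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        edge_num = np.full(n, -1, dtype=np.intp)
        blen = np.zeros(n, dtype=float)
        root_edge = -1
        root_blen = 0.0
        for i, nd in enumerate(dnodes):
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
            num = None
            for comment in nd.comments:
                m = re.fullmatch(r"\d+", comment.strip())
                if m:
                    num = int(m.group())
            length = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.parent_node is None:
                if num is not None:
                    root_edge = num
                    root_blen = float(length)
                continue
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            blen[i] = float(length)
            if num is None:
                raise TreeFormatError(
                    f"edge above node {labels[i] or i} carries no edge number"
                )
            edge_num[i] = num
        return cls(
            parent=parent,
            children=children,
            labels=labels,
            node_edge_num=edge_num,
            node_branch_length=blen,
            root_edge_num=root_edge,
            root_branch_length=root_blen,
        )

    def to_newick(self, edge_style: str = "{}", edge_comments: dict[int, str] | None = None) -> str:
        """Write the tree back to edge-numbered Newick.

        ``edge_comments`` optionally maps edge numbers to extra ``[...]``
        comment payloads (used e.g. for per-edge colors).
        """
        open_c, close_c = ("{", "}") if edge_style == "{}" else ("[", "]")

        def annot(e: int, length: float) -> str:
            s = f":{length!r}{open_c}{e}{close_c}"
            if edge_comments and e in edge_comments:
                s += f"[{edge_comments[e]}]"
            return s

        def rec(v: int) -> str:
            if not self.children[v]:
                core = self.labels[v] or ""
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if self.labels[v]:
                    core += self.labels[v]
            if v == 0:
                if self.root_edge_num >= 0:
                    core += annot(self.root_edge_num, self.root_branch_length)
                return core + ";"
            return core + annot(int(self.node_edge_num[v]), float(self.node_branch_length[v]))

        return rec(0)

    # ------------------------------------------------------------------
    # basic properties

    @property
    def num_nodes(self) -> int:
        return len(self.children)

    @property
    def num_edges(self) -> int:
        return self.num_nodes - 1 + (1 if self.root_edge_num >= 0 else 0)

    @property
    def num_tips(self) -> int:
        return sum(1 for c in self.children if not c)

    def edge_column(self, edge_num: int) -> int:
        """Column index of an edge number in the canonical preorder layout."""
        try:
            return self._edge_col[int(edge_num)]
        except KeyError:
            raise KeyError(f"edge number {edge_num} not present in reference tree") from None

    def has_edge(self, edge_num: int) -> bool:
        return int(edge_num) in self._edge_col

    def edge_child_node(self, col: int) -> int:
        """Node on the non-root side of the edge at canonical column ``col``."""
        return int(self._col_child[col])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch lengths in canonical column order."""
        out = np.empty(self.num_edges)
        for col in range(self.num_edges):
            v = self._col_child[col]
            if v == 0:
                out[col] = self.root_branch_length
            else:
                out[col] = self.node_branch_length[v]
        return out

    @property
    def tip_edge_mask(self) -> np.ndarray:
        """Boolean mask (canonical order) of edges leading to a tip."""
        return np.array(
            [not self.children[self._col_child[c]] for c in range(self.num_edges)]
        )

    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self._preorder if not self.children[v]]

    # ------------------------------------------------------------------
    # traversal

    def preorder_nodes(self) -> np.ndarray:
        return self._preorder

    def postorder_nodes(self) -> np.ndarray:
        return self._postorder

    def _traverse(self, post: bool) -> np.ndarray:
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if post:
            seen = np.asarray(order[::-1], dtype=np.intp)
            # children-before-parent ordering
            return seen
        return np.asarray(order, dtype=np.intp)

    def subtree_edge_columns(self, edge_num: int) -> np.ndarray:
        """Canonical columns of all edges strictly on the non-root side of an edge."""
        col = self.edge_column(edge_num)
        v = self._col_child[col]
        cols: list[int] = []
        stack = list(self.children[v])
        while stack:
            w = stack.pop()
            cols.append(self._edge_col[int(self.node_edge_num[w])])
            stack.extend(self.children[w])
        return np.asarray(sorted(cols), dtype=np.intp)

    def path_edge_nums(self, edge_num: int) -> list[int]:
        """Edge numbers on the path from the root down to (and including) an edge."""
        col = self.edge_column(edge_num)
        v = self._col_child[col]
        path = []
        while v != 0:
            path.append(int(self.node_edge_num[v]))
            v = int(self.parent[v])
        return path[::-1]

    def node_depths(self) -> np.ndarray:
        """Path length from the root to every node."""
        depth = np.zeros(self.num_nodes)
        for v in self._preorder:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.node_branch_length[v]
        return depth

    # ------------------------------------------------------------------
    # validation

    def _validate(self) -> None:
        for v in range(self.num_nodes):
            deg = len(self.children[v])
            if v == 0:
                if deg not in (0, 2, 3):
                    raise TreeFormatError(
                        f"root has {deg} children; expected a bifurcation or a "
                        "top-level trifurcation"
                    )
            elif deg not in (0, 2):
                raise TreeFormatError(
                    f"inner node {v} has {deg} children; tree must be strictly bifurcating"
                )
        bl = self.branch_lengths
        if not np.all(np.isfinite(bl)):
            raise TreeFormatError("non-finite branch length in reference tree")
        if np.any(bl < 0):
            raise TreeFormatError("negative branch length in reference tree")

    def same_topology_as(self, other: "ReferenceTree") -> bool:
        """Cheap identity check used to guard cross-sample operations."""
        return (
            self.num_edges == other.num_edges
            and list(self.edge_order) == list(other.edge_order)
            and self.tip_labels() == other.tip_labels()
        )
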