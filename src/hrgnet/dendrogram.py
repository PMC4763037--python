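"""Rooted binary dendrograms over a gene set.

A dendrogram over N genes has N leaves (one per gene) and exactly N - 1
internal nodes, each with two children.  Nodes are integers: leaves are
``0..N-1`` in gene-list order, internal nodes are ``N..2N-2``.  The structure
is stored in flat parent/left/right arrays, which keeps copying cheap for the
annealer and makes validation straightforward.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Dendrogram",
    "random_dendrogram",
    "enumerate_dendrograms",
    "from_nested",
    "lca",
]

_NO_NODE = -1


class Dendrogram:
    """Rooted binary tree with N leaves and N - 1 internal nodes."""

    __slots__ = ("genes", "n_leaves", "parent", "left", "right", "root")

    def __init__(
        self,
        genes: Sequence[str],
        parent: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        root: int,
        validate: bool = True,
    ):
        self.genes = tuple(str(g) for g in genes)
        self.n_leaves = len(self.genes)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.root = int(root)
        if validate:
            self.validate()

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def n_internal(self) -> int:
        return self.n_leaves - 1

    def internal_nodes(self) -> range:
        return range(self.n_leaves, self.n_nodes)

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} is not a leaf of this dendrogram") from None

    def copy(self) -> "Dendrogram":
        return Dendrogram(
            self.genes, self.parent.copy(), self.left.copy(), self.right.copy(),
            self.root, validate=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dendrogram):
            return NotImplemented
        return self.canonical_signature() == other.canonical_signature()

    def __hash__(self) -> int:
        return hash(self.canonical_signature())

    # -- structure ----------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise ValueError on violation."""
        n, total = self.n_leaves, self.n_nodes
        if n < 2:
            raise ValueError("a dendrogram needs at least 2 leaves")
        for arr in (self.parent, self.left, self.right):
            if arr.shape != (total,):
                raise ValueError("parent/left/right arrays must have length 2N-1")
        if not (n <= self.root < total):
            raise ValueError("root must be an internal node")
        if self.parent[self.root] != _NO_NODE:
            raise ValueError("root must have no parent")
        for leaf in range(n):
            if self.left[leaf] != _NO_NODE or self.right[leaf] != _NO_NODE:
                raise ValueError(f"leaf {leaf} has children")
        for node in self.internal_nodes():
            l, r = self.left[node], self.right[node]
            if l == _NO_NODE or r == _NO_NODE or l == r:
                raise ValueError(f"internal node {node} lacks two distinct children")
            for child in (l, r):
                if not (0 <= child < total):
                    raise ValueError(f"node {node} has out-of-range child {child}")
                if self.parent[child] != node:
                    raise ValueError(f"child {child} does not point back to parent {node}")
        # reachability: every node on a unique path to the root
        seen = 0
        stack = [self.root]
        visited = np.zeros(total, dtype=bool)
        while stack:
            node = stack.pop()
            if visited[node]:
                raise ValueError("cycle detected")
            visited[node] = True
            seen += 1
            if not self.is_leaf(node):
                stack.extend((self.left[node], self.right[node]))
        if seen != total:
            raise ValueError("tree is not connected: unreachable nodes exist")

    def depths(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not self.is_leaf(node):
                for child in (self.left[node], self.right[node]):
                    d[child] = d[node] + 1
                    stack.append(child)
        return d

    def postorder_internal(self) -> list[int]:
        """Internal nodes, children before parents."""
        order, stack = [], [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if self.is_leaf(node):
                continue
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                stack.append((self.left[node], False))
                stack.append((self.right[node], False))
        return order

    def n_leaves_below(self) -> np.ndarray:
        """Number of leaves in the subtree rooted at each node."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n_leaves] = 1
        for node in self.postorder_internal():
            counts[node] = counts[self.left[node]] + counts[self.right[node]]
        return counts

    def leaves_below(self, node: int) -> set[int]:
        out: set[int] = set()
        stack = [node]
        while stack:
            nd = stack.pop()
            if self.is_leaf(nd):
                out.add(nd)
            else:
                stack.extend((self.left[nd], self.right[nd]))
        return out

    # -- LCA ----------------------------------------------------------------

    def lca_index(self, u: int, v: int, depths: np.ndarray | None = None) -> int:
        """Lowest common ancestor of two distinct leaf indices."""
        if u == v:
            raise ValueError("LCA of a leaf with itself is not defined here")
        if depths is None:
            depths = self.depths()
        du, dv = depths[u], depths[v]
        while du > dv:
            u = self.parent[u]
            du -= 1
        while dv > du:
            v = self.parent[v]
            dv -= 1
        while u != v:
            u = self.parent[u]
            v = self.parent[v]
        return int(u)

    def lca_map(self) -> dict[tuple[int, int], int]:
        """lca for every unordered leaf pair, keyed (i, j) with i < j.

        Computed bottom-up in O(N^2): at each internal node every
        (left-leafset x right-leafset) pair has that node as its LCA.
        """
        out: dict[tuple[int, int], int] = {}
        leafsets: dict[int, set[int]] = {}
        for node in self.postorder_internal():
            l, r = self.left[node], self.right[node]
            ls = leafsets.pop(l, None) or ({l} if self.is_leaf(l) else set())
            rs = leafsets.pop(r, None) or ({r} if self.is_leaf(r) else set())
            for a in ls:
                for b in rs:
                    out[(a, b) if a < b else (b, a)] = node
            leafsets[node] = ls | rs
        return out

    # -- canonical form ------------------------------------------------------

    def canonical_signature(self) -> str:
        """Order-independent string form of the leaf-labeled shape."""

        def sig(node: int) -> str:
            if self.is_leaf(node):
                return self.genes[node]
            a, b = sig(self.left[node]), sig(self.right[node])
            if a > b:
                a, b = b, a
            return f"({a},{b})"

        return sig(self.root)


def lca(tree: Dendrogram, u: str, v: str) -> int:
    """LCA of two distinct genes; returns the internal node index."""
    if u == v:
        raise ValueError(f"LCA of gene {u!r} with itself is not defined")
    return tree.lca_index(tree.gene_index(u), tree.gene_index(v))


def _from_child_lists(genes: Sequence[str], children: dict[int, tuple[int, int]], root: int) -> Dendrogram:
    n = len(genes)
    total = 2 * n - 1
    parent = np.full(total, _NO_NODE, dtype=np.int64)
    left = np.full(total, _NO_NODE, dtype=np.int64)
    right = np.full(total, _NO_NODE, dtype=np.int64)
    for node, (l, r) in children.items():
        left[node], right[node] = l, r
        parent[l] = parent[r] = node
    return Dendrogram(genes, parent, left, right, root, validate=False)


def random_dendrogram(genes: Sequence[str], rng: np.random.Generator | None = None) -> Dendrogram:
    """Random rooted binary tree by sequential uniform branch insertion.

    Each leaf after the second is attached to a uniformly chosen existing
    node's parent branch (attaching at the root creates a new root), which
    gives every leaf-labeled shape positive probability.
    """
    genes = tuple(str(g) for g in genes)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to build a dendrogram")
    rng = np.random.default_rng(rng)
    order = rng.permutation(n)
    total = 2 * n - 1
    parent = np.full(total, _NO_NODE, dtype=np.int64)
    left = np.full(total, _NO_NODE, dtype=np.int64)
    right = np.full(total, _NO_NODE, dtype=np.int64)

    nodes = [int(order[0])]  # nodes currently in the tree
    root = int(order[0])
    next_internal = n
    for k in range(1, n):
        leaf = int(order[k])
        attach = nodes[int(rng.integers(len(nodes)))]
        new = next_internal
        next_internal += 1
        p = parent[attach]
        # new internal node takes attach's place, adopting attach and the leaf
        if rng.random() < 0.5:
            left[new], right[new] = attach, leaf
        else:
            left[new], right[new] = leaf, attach
        parent[attach] = parent[leaf] = new
        parent[new] = p
        if p == _NO_NODE:
            root = new
        else:
            if left[p] == attach:
                left[p] = new
            else:
                right[p] = new
        nodes.extend((leaf, new))
    return Dendrogram(genes, parent, left, right, root, validate=False)


def from_nested(spec) -> Dendrogram:
    """Build a dendrogram from nested 2-tuples of gene labels.

    ``from_nested(("a", ("b", "c")))`` is the tree with a cherry (b, c).
    Gene order follows left-to-right appearance.
    """

    genes: list[str] = []

    def collect(node) -> None:
        if isinstance(node, (tuple, list)):
            if len(node) != 2:
                raise ValueError("every internal node must have exactly 2 children")
            collect(node[0])
            collect(node[1])
        else:
            genes.append(str(node))

    collect(spec)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to build a dendrogram")
    children: dict[int, tuple[int, int]] = {}
    leaf_iter = iter(range(n))
    counter = iter(range(n, 2 * n - 1))

    def build(node) -> int:
        if isinstance(node, (tuple, list)):
            l, r = build(node[0]), build(node[1])
            me = next(counter)
            children[me] = (l, r)
            return me
        return next(leaf_iter)

    root = build(spec)
    return _from_child_lists(genes, children, root)


def enumerate_dendrograms(genes: Sequence[str]) -> Iterator[Dendrogram]:
    """All (2N-3)!! leaf-labeled rooted binary shapes, by leaf insertion."""
    genes = tuple(str(g) for g in genes)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to enumerate dendrograms")

    def recurse(k: int, children: dict[int, tuple[int, int]], root: int, nodes: list[int]) -> Iterator[Dendrogram]:
        if k == n:
            yield _from_child_lists(genes, children, root)
            return
        new = n + k - 1  # internal node ids assigned in insertion order
        for attach in list(nodes):
            sub = dict(children)
            sub[new] = (attach, k)
            # find attach's parent slot
            new_root = root
            for p, (l, r) in children.items():
                if l == attach:
                    sub[p] = (new, r)
                    break
                if r == attach:
                    sub[p] = (l, new)
                    break
            else:
                new_root = new
            yield from recurse(k + 1, sub, new_root, nodes + [k, new])

    yield from recurse(1, {}, 0, [0])
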