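"""Simulated-annealing search for the maximum-likelihood dendrogram.

The search space is the set of (2N-3)!! leaf-labeled rooted binary trees.
Proposals are local rearrangements at a randomly selected internal node *s*
that has at least one internal child.  Writing the configuration below *s* as
(A, (B, C)) — A the subtree on one side, B and C the grandchildren under the
internal child — the two operators are:

* Exchange: swap A with B or with C, giving (B, (A, C)) or (C, (B, A)).
* Rotate:   regroup to ((A, B), C) or ((A, C), B).

On unordered trees the two operators generate the same neighborhood (they are
the rooted nearest-neighbor-interchange moves); both are kept because they
are the natural ordered-tree reading of the method and their union is
trivially ergodic (see the breadth-first closure tests).

The cooling loop follows the printed procedure exactly: the current tree is
reset to the best tree at the start of every temperature epoch, the best tree
is replaced only on strict improvement, and a proposal drawn at a node with
two leaf children consumes one iteration of the per-epoch budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dendrogram import Dendrogram, enumerate_dendrograms, random_dendrogram
from .hrg import HRGModel, fit_theta, log_likelihood, node_log_likelihood
from .networks import NetworkEnsemble

__all__ = [
    "AnnealSchedule",
    "AnnealTrace",
    "MoveNotApplicable",
    "exchange",
    "rotate",
    "neighbors",
    "accept_probability",
    "anneal",
    "exhaustive_search",
    "ExhaustiveResult",
    "REDUCED_SCHEDULE",
]


class MoveNotApplicable(ValueError):
    """Raised when both children of the selected node are leaves."""


@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling schedule.  Defaults are the full-scale settings.

    ``n_max`` (proposals per temperature) defaults to ``n_max_factor * N``;
    pass ``n_max`` explicitly to override the N-scaling.
    """

    t_start: float = 1000.0
    t_end: float = 0.1
    gamma: float = 0.99
    n_max_factor: int = 1000
    n_max: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (self.t_start > self.t_end > 0):
            raise ValueError("need t_start > t_end > 0")
        if not (0 < self.gamma < 1):
            raise ValueError("cooling factor gamma must lie in (0, 1)")
        if self.n_max is not None and self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.n_max is None and self.n_max_factor < 1:
            raise ValueError("n_max_factor must be >= 1")

    def proposals_per_epoch(self, n_leaves: int) -> int:
        return self.n_max if self.n_max is not None else self.n_max_factor * n_leaves

    @property
    def n_epochs(self) -> int:
        return math.ceil(math.log(self.t_end / self.t_start) / math.log(self.gamma))


#: Small-problem schedule used throughout the test-suite-scale experiments.
REDUCED_SCHEDULE = AnnealSchedule(t_start=10.0, t_end=0.1, gamma=0.9, n_max_factor=200)


@dataclass
class AnnealTrace:
    """Per-epoch progress of a run; best objective is non-decreasing."""

    temperature: list[float] = field(default_factory=list)
    obj_current: list[float] = field(default_factory=list)
    obj_best: list[float] = field(default_factory=list)
    n_accepted: list[int] = field(default_factory=list)
    n_noop: list[int] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.temperature)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["epoch\ttemperature\tobj_current\tobj_best\tn_accepted\tn_noop"]
        for i in range(self.n_epochs):
            lines.append(
                f"{i}\t{self.temperature[i]:.6g}\t{self.obj_current[i]:.10g}"
                f"\t{self.obj_best[i]:.10g}\t{self.n_accepted[i]}\t{self.n_noop[i]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def accept_probability(obj_current: float, obj_test: float, temperature: float) -> float:
    """Metropolis acceptance: min{1, exp(-(Obj_c - Obj_t) / T)}."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if obj_test >= obj_current:
        return 1.0
    return math.exp(-(obj_current - obj_test) / temperature)


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------


def _pick_config(tree: Dendrogram, s: int, rng: np.random.Generator) -> tuple[int, int]:
    """Return (a, c): a sibling subtree root and an internal child of s."""
    if tree.is_leaf(s):
        raise ValueError(f"node {s} is a leaf; moves act on internal nodes")
    l, r = int(tree.left[s]), int(tree.right[s])
    internal = [ch for ch in (l, r) if not tree.is_leaf(ch)]
    if not internal:
        raise MoveNotApplicable(f"node {s} has two leaf children; no move applies")
    c = internal[int(rng.integers(len(internal)))] if len(internal) == 2 else internal[0]
    a = r if c == l else l
    return a, c


def _set_child(tree: Dendrogram, parent: int, old: int, new: int) -> None:
    if tree.left[parent] == old:
        tree.left[parent] = new
    else:
        tree.right[parent] = new
    tree.parent[new] = parent


def _apply_exchange(tree: Dendrogram, s: int, c: int, a: int, g: int) -> None:
    """In place: swap subtree a (child of s) with subtree g (child of c)."""
    _set_child(tree, s, a, g)
    _set_child(tree, c, g, a)


def _apply_rotate(tree: Dendrogram, s: int, c: int, a: int, keep: int) -> None:
    """In place: (A, (B, C)) -> ((A, keep), other); keep is a child of c."""
    other = int(tree.left[c]) if tree.right[c] == keep else int(tree.right[c])
    # c becomes the lower group (a, keep); `other` moves up beside it.
    _set_child(tree, s, a, other)
    _set_child(tree, c, other, a)
    # note: identical pointer surgery to an exchange of a with `other`; the
    # ordered-tree pictures differ but the unordered result coincides.


def exchange(tree: Dendrogram, s: int, rng: np.random.Generator | None = None) -> Dendrogram:
    """Exchange move at internal node s; returns a new tree.

    Swaps the child subtree on one side of s with a uniformly chosen
    grandchild subtree under s's (uniformly chosen) internal child.
    Raises :class:`MoveNotApplicable` if both children of s are leaves.
    """
    rng = np.random.default_rng(rng)
    out = tree.copy()
    a, c = _pick_config(out, s, rng)
    g = int(out.left[c]) if rng.random() < 0.5 else int(out.right[c])
    _apply_exchange(out, s, c, a, g)
    return out


def rotate(tree: Dendrogram, s: int, rng: np.random.Generator | None = None) -> Dendrogram:
    """Rotate move at internal node s; returns a new tree.

    Regroups the configuration (A, (B, C)) at s into ((A, B), C) or
    ((A, C), B), chosen uniformly.
    """
    rng = np.random.default_rng(rng)
    out = tree.copy()
    a, c = _pick_config(out, s, rng)
    keep = int(out.left[c]) if rng.random() < 0.5 else int(out.right[c])
    _apply_rotate(out, s, c, a, keep)
    return out


def neighbors(tree: Dendrogram) -> list[Dendrogram]:
    """All trees reachable by one Exchange or Rotate variant at any node."""
    out = []
    for s in tree.internal_nodes():
        l, r = int(tree.left[s]), int(tree.right[s])
        for c in (l, r):
            if tree.is_leaf(c):
                continue
            a = r if c == l else l
            for g in (int(tree.left[c]), int(tree.right[c])):
                t = tree.copy()
                _apply_exchange(t, s, c, a, g)
                out.append(t)
                t = tree.copy()
                _apply_rotate(t, s, c, a, g)
                out.append(t)
    return out


# ---------------------------------------------------------------------------
# Incremental objective bookkeeping
# ---------------------------------------------------------------------------


class _State:
    """Mutable tree + cached per-node statistics for fast move evaluation.

    A move at node s with internal child c only redistributes LCAs among the
    pairs crossing the three subtrees below s, so only nodes s and c change
    their (leafset, L*R, E, log-likelihood) entries; everything above s is
    untouched.  Each proposal is evaluated by recomputing those two nodes.
    """

    def __init__(self, tree: Dendrogram, ens: NetworkEnsemble):
        self.tree = tree
        self.ng = ens.n_networks
        gene_to_leaf = {g: i for i, g in enumerate(tree.genes)}
        # adjacency over leaf indices with ensemble weights
        self.adj: list[dict[int, int]] = [dict() for _ in tree.genes]
        for (u, v), w in ens.weights.items():
            iu, iv = gene_to_leaf[u], gene_to_leaf[v]
            self.adj[iu][iv] = w
            self.adj[iv][iu] = w
        self.leafset: dict[int, set[int]] = {}
        self.nl: dict[int, int] = {}  # leaves below node
        self.E: dict[int, int] = {}
        self.prod: dict[int, int] = {}
        self.ll: dict[int, float] = {}
        for node in tree.postorder_internal():
            self._init_node(node)
        self.total_ll = sum(self.ll.values())

    def _leaves(self, node: int) -> set[int]:
        return {node} if self.tree.is_leaf(node) else self.leafset[node]

    def _nl(self, node: int) -> int:
        return 1 if self.tree.is_leaf(node) else self.nl[node]

    def _cross_edges(self, ls: set[int], rs: set[int]) -> int:
        if len(rs) < len(ls):
            ls, rs = rs, ls
        total = 0
        for u in ls:
            adj_u = self.adj[u]
            if len(adj_u) < len(rs):
                for v, w in adj_u.items():
                    if v in rs:
                        total += w
            else:
                for v in rs:
                    w = adj_u.get(v)
                    if w is not None:
                        total += w
        return total

    def _init_node(self, node: int) -> None:
        t = self.tree
        ls, rs = self._leaves(int(t.left[node])), self._leaves(int(t.right[node]))
        self.leafset[node] = ls | rs
        self.nl[node] = len(ls) + len(rs)
        self.prod[node] = len(ls) * len(rs)
        self.E[node] = self._cross_edges(ls, rs)
        self.ll[node] = node_log_likelihood(self.E[node], self.ng * self.prod[node])

    def refresh_node(self, node: int) -> None:
        self._init_node(node)

    def snapshot(self, nodes: Sequence[int]) -> dict:
        t = self.tree
        return {
            "ptr": [(n, int(t.left[n]), int(t.right[n])) for n in nodes],
            "parent": [(int(t.left[n]), int(t.parent[t.left[n]])) for n in nodes]
            + [(int(t.right[n]), int(t.parent[t.right[n]])) for n in nodes],
            "stats": {
                n: (self.leafset[n], self.nl[n], self.E[n], self.prod[n], self.ll[n])
                for n in nodes
            },
            "total": self.total_ll,
        }

    def restore(self, snap: dict) -> None:
        t = self.tree
        for n, l, r in snap["ptr"]:
            t.left[n], t.right[n] = l, r
        for child, p in snap["parent"]:
            t.parent[child] = p
        for n, (ls, nl, e, prod, ll) in snap["stats"].items():
            self.leafset[n] = ls
            self.nl[n] = nl
            self.E[n] = e
            self.prod[n] = prod
            self.ll[n] = ll
        self.total_ll = snap["total"]

    def apply_move(self, s: int, c: int, a: int, g: int, op: str) -> dict:
        """Apply a move, update stats for s and c, return an undo snapshot."""
        snap = self.snapshot([s, c])
        if op == "exchange":
            _apply_exchange(self.tree, s, c, a, g)
        else:
            _apply_rotate(self.tree, s, c, a, g)
        old = self.ll[s] + self.ll[c]
        self.refresh_node(c)
        self.refresh_node(s)
        self.total_ll += (self.ll[s] + self.ll[c]) - old
        return snap


def anneal(
    ens: NetworkEnsemble,
    schedule: AnnealSchedule | None = None,
    *,
    restart_from_best: bool = True,
    incremental: bool = True,
    initial_tree: Dendrogram | None = None,
) -> tuple[HRGModel, AnnealTrace]:
    """Maximize the ensemble log-likelihood over dendrograms.

    Returns the best tree seen, with theta refit by the closed form, plus a
    per-epoch trace.  ``incremental=False`` recomputes the full objective at
    every proposal (slow; kept as a correctness cross-check of the cached
    path).  ``restart_from_best=False`` disables the per-epoch reset of the
    current tree to the best tree.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(schedule.seed)
    genes = ens.genes
    n = len(genes)
    if n < 2:
        raise ValueError("annealing needs at least 2 genes")
    trace = AnnealTrace()
    if n == 2:
        # only one dendrogram exists
        tree = random_dendrogram(genes, rng)
        return HRGModel.fit(tree, ens), trace

    tree = (initial_tree.copy() if initial_tree is not None else random_dendrogram(genes, rng))
    state = _State(tree, ens)
    best_tree = tree.copy()
    best_obj = state.total_ll
    internal_lo, internal_hi = n, 2 * n - 1
    n_max = schedule.proposals_per_epoch(n)

    temperature = schedule.t_start
    while temperature > schedule.t_end:
        if restart_from_best:
            tree = best_tree.copy()
            state = _State(tree, ens)
        current_obj = state.total_ll
        accepted = noop = 0
        for _ in range(n_max):
            s = int(rng.integers(internal_lo, internal_hi))
            try:
                a, c = _pick_config(tree, s, rng)
            except MoveNotApplicable:
                noop += 1
                continue
            op = "exchange" if rng.random() < 0.5 else "rotate"
            g = int(tree.left[c]) if rng.random() < 0.5 else int(tree.right[c])
            snap = state.apply_move(s, c, a, g, op)
            test_obj = (
                state.total_ll if incremental else log_likelihood(tree, ens)
            )
            if test_obj > best_obj:
                best_obj = test_obj
                best_tree = tree.copy()
            if rng.random() < accept_probability(current_obj, test_obj, temperature):
                current_obj = test_obj
                accepted += 1
            else:
                state.restore(snap)
        trace.temperature.append(temperature)
        trace.obj_current.append(current_obj)
        trace.obj_best.append(best_obj)
        trace.n_accepted.append(accepted)
        trace.n_noop.append(noop)
        temperature *= schedule.gamma

    return HRGModel.fit(best_tree, ens), trace


# ---------------------------------------------------------------------------
# Exhaustive oracle (small N)
# ---------------------------------------------------------------------------

_MAX_EXHAUSTIVE_N = 8


@dataclass(frozen=True)
class ExhaustiveResult:
    model: HRGModel
    objective: float
    table: tuple[tuple[str, float], ...]  # (canonical signature, log-likelihood)
    ties: frozenset[str]  # signatures within tolerance of the optimum

    @property
    def n_shapes(self) -> int:
        return len(self.table)


def exhaustive_search(ens: NetworkEnsemble, tie_tol: float = 1e-9) -> ExhaustiveResult:
    """Enumerate every dendrogram shape and return the global optimum.

    Refuses N > 8 (10395 shapes at N = 8 is the practical ceiling).  Ties —
    shapes whose objective is within ``tie_tol`` of the maximum — are
    reported as a set of canonical signatures.
    """
    n = ens.n_genes
    if n > _MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive search is limited to N <= {_MAX_EXHAUSTIVE_N}, got {n}")
    best_tree = None
    best_obj = -math.inf
    table = []
    for tree in enumerate_dendrograms(ens.genes):
        obj = log_likelihood(tree, ens)
        table.append((tree.canonical_signature(), obj))
        if obj > best_obj:
            best_obj = obj
            best_tree = tree
    ties = frozenset(sig for sig, obj in table if obj >= best_obj - tie_tol)
    model = HRGModel.fit(best_tree, ens)
    return ExhaustiveResult(model, best_obj, tuple(table), ties)
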