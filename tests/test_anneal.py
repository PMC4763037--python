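import math

import numpy as np
import pytest

from hrgnet import (
    AnnealSchedule,
    MoveNotApplicable,
    accept_probability,
    anneal,
    exchange,
    exhaustive_search,
    neighbors,
    rotate,
)
from hrgnet.anneal import REDUCED_SCHEDULE, _apply_exchange
from hrgnet.dendrogram import from_nested, random_dendrogram
from hrgnet.hrg import subtree_leaf_counts
from hrgnet.networks import DirectedNetwork, build_ensemble

from conftest import random_ensemble


def leaf_multiset(tree):
    return sorted(tree.genes[l] for l in tree.leaves_below(tree.root))


class TestSchedule:
    def test_defaults_are_the_full_scale_settings(self):
        s = AnnealSchedule()
        assert (s.t_start, s.t_end, s.gamma) == (1000.0, 0.1, 0.99)
        assert s.proposals_per_epoch(100) == 100_000  # 1000 * N

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_start=1.0, t_end=2.0),
            dict(t_end=-0.5),
            dict(gamma=1.0),
            dict(gamma=0.0),
            dict(n_max=0),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnnealSchedule(**kwargs)


class TestAcceptProbability:
    def test_improving_moves_always_accepted(self):
        assert accept_probability(-10.0, -5.0, 1.0) == 1.0
        assert accept_probability(-10.0, -10.0, 1.0) == 1.0

    def test_closed_form_at_gap_equal_to_temperature(self):
        assert accept_probability(-1.0, -3.0, 2.0) == pytest.approx(math.exp(-1))

    def test_vanishes_for_huge_gaps(self):
        assert accept_probability(0.0, -1e6, 0.5) == pytest.approx(0.0, abs=1e-300)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            accept_probability(0.0, -1.0, 0.0)


class TestMoves:
    def test_exchange_at_root_of_three_subtree_config(self):
        # (A,(B,C)) with A=a, B=b, C=c: swapping A with a grandchild regroups the cherry
        tree = from_nested(("a", ("b", "c")))
        out = exchange(tree, tree.root, np.random.default_rng(0))
        assert out.canonical_signature() in {"((a,c),b)", "((a,b),c)"}
        out.validate()

    def test_rotate_produces_a_regrouping(self):
        tree = from_nested(("a", ("b", "c")))
        out = rotate(tree, tree.root, np.random.default_rng(0))
        assert out.canonical_signature() in {"((a,b),c)", "((a,c),b)"}
        out.validate()

    def test_exchange_is_an_involution(self, rng):
        tree = random_dendrogram([f"g{i}" for i in range(8)], rng)
        s = tree.root
        c = next(
            ch for ch in (int(tree.left[s]), int(tree.right[s])) if not tree.is_leaf(ch)
        )
        a = int(tree.right[s]) if c == tree.left[s] else int(tree.left[s])
        g = int(tree.left[c])
        once = tree.copy()
        _apply_exchange(once, s, c, a, g)
        twice = once.copy()
        _apply_exchange(twice, s, c, g, a)  # the swapped subtrees traded places
        assert twice.canonical_signature() == tree.canonical_signature()

    def test_moves_preserve_leaves_and_pair_partition(self, rng):
        n = 9
        for _ in range(20):
            tree = random_dendrogram([f"g{i}" for i in range(n)], rng)
            s = int(rng.integers(n, 2 * n - 1))
            try:
                out = exchange(tree, s, rng) if rng.random() < 0.5 else rotate(tree, s, rng)
            except MoveNotApplicable:
                continue
            out.validate()
            assert leaf_multiset(out) == leaf_multiset(tree)
            L, R = subtree_leaf_counts(out)
            prods = sum(int(L[i] * R[i]) for i in out.internal_nodes())
            assert prods == n * (n - 1) // 2

    def test_node_with_two_leaf_children_signals_no_op(self):
        tree = from_nested((("a", "b"), ("c", "d")))
        cherry = tree.parent[tree.gene_index("a")]
        with pytest.raises(MoveNotApplicable):
            exchange(tree, cherry, np.random.default_rng(0))
        with pytest.raises(MoveNotApplicable):
            rotate(tree, cherry, np.random.default_rng(0))

    @pytest.mark.parametrize("n, n_shapes", [(4, 15), (5, 105)])
    def test_breadth_first_closure_reaches_every_shape(self, n, n_shapes, rng):
        start = random_dendrogram([f"g{i}" for i in range(n)], rng)
        seen = {start.canonical_signature()}
        frontier = [start]
        while frontier:
            tree = frontier.pop()
            for nb in neighbors(tree):
                sig = nb.canonical_signature()
                if sig not in seen:
                    seen.add(sig)
                    frontier.append(nb)
        assert len(seen) == n_shapes


class TestAnneal:
    def test_worked_example_attains_enumerated_optimum(self, toy_ensemble):
        model, trace = anneal(
            toy_ensemble,
            AnnealSchedule(t_start=10, t_end=0.1, gamma=0.9, n_max=100, seed=11),
        )
        expected = math.log(0.25) + 3 * math.log(0.75)
        assert trace.obj_best[-1] == pytest.approx(expected, abs=1e-10)
        assert model.tree.canonical_signature() in {"((a,c),b)", "((a,b),c)"}

    def test_two_cliques_give_saturated_and_empty_thetas(self):
        genes = [f"g{i}" for i in range(6)]
        block1, block2 = genes[:3], genes[3:]
        regs = [(u, v) for blk in (block1, block2) for u in blk for v in blk if u != v]
        ens = build_ensemble([DirectedNetwork(genes, regs)])
        model, trace = anneal(
            ens, AnnealSchedule(t_start=10, t_end=0.1, gamma=0.8, n_max=600, seed=3)
        )
        assert trace.obj_best[-1] == pytest.approx(exhaustive_search(ens).objective, abs=1e-9)
        # cross-clique pairs meet at theta 0; within-clique cherries at theta 1
        for u in block1:
            for v in block2:
                assert model.edge_probability(u, v) == pytest.approx(0.0, abs=1e-12)
        for blk in (block1, block2):
            for u in blk:
                for v in blk:
                    if u != v:
                        assert model.edge_probability(u, v) == pytest.approx(1.0)

    def test_best_objective_is_monotone(self, rng):
        ens = random_ensemble(6, 10, 0.3, rng)
        _, trace = anneal(
            ens, AnnealSchedule(t_start=5, t_end=0.2, gamma=0.8, n_max=100, seed=9)
        )
        best = np.array(trace.obj_best)
        assert np.all(np.diff(best) >= 0)

    def test_identical_seed_gives_identical_run(self, rng):
        ens = random_ensemble(7, 10, 0.3, rng)
        sched = AnnealSchedule(t_start=5, t_end=0.2, gamma=0.8, n_max=200, seed=77)
        m1, t1 = anneal(ens, sched)
        m2, t2 = anneal(ens, sched)
        assert m1.tree.canonical_signature() == m2.tree.canonical_signature()
        assert np.array_equal(m1.theta, m2.theta)
        assert t1.obj_best == t2.obj_best and t1.obj_current == t2.obj_current

    def test_incremental_objective_tracks_full_recompute(self, rng):
        """The cached per-node bookkeeping equals a from-scratch evaluation
        after arbitrary sequences of applied and reverted moves."""
        from hrgnet.anneal import _State, _pick_config
        from hrgnet.hrg import log_likelihood

        ens = random_ensemble(8, 8, 0.35, rng)
        tree = random_dendrogram(ens.genes, rng)
        state = _State(tree, ens)
        n = tree.n_leaves
        for step in range(300):
            s = int(rng.integers(n, 2 * n - 1))
            try:
                a, c = _pick_config(tree, s, rng)
            except MoveNotApplicable:
                continue
            g = int(tree.left[c]) if rng.random() < 0.5 else int(tree.right[c])
            op = "exchange" if rng.random() < 0.5 else "rotate"
            snap = state.apply_move(s, c, a, g, op)
            if rng.random() < 0.3:  # revert some moves, as the annealer does
                state.restore(snap)
            assert state.total_ll == pytest.approx(log_likelihood(tree, ens), abs=1e-9)
            if step % 100 == 0:
                tree.validate()

    def test_two_gene_problem_returns_unique_tree_without_search(self):
        ens = build_ensemble([DirectedNetwork("ab", [("a", "b")])])
        model, trace = anneal(ens, REDUCED_SCHEDULE)
        assert model.tree.canonical_signature() == "(a,b)"
        assert trace.n_epochs == 0

    def test_trace_tsv_output(self, tmp_path, toy_ensemble):
        _, trace = anneal(
            toy_ensemble, AnnealSchedule(t_start=2, t_end=0.5, gamma=0.5, n_max=20, seed=0)
        )
        path = tmp_path / "trace.tsv"
        trace.write_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "epoch", "temperature", "obj_current", "obj_best", "n_accepted", "n_noop",
        ]
        assert len(lines) == trace.n_epochs + 1


class TestExhaustive:
    @pytest.mark.parametrize("n, expected", [(3, 3), (4, 15)])
    def test_shape_counts(self, n, expected, rng):
        ens = random_ensemble(n, 4, 0.4, rng)
        assert exhaustive_search(ens).n_shapes == expected

    def test_worked_example_two_way_tie(self, toy_ensemble):
        res = exhaustive_search(toy_ensemble)
        assert res.objective == pytest.approx(math.log(0.25) + 3 * math.log(0.75), abs=1e-10)
        assert res.ties == frozenset({"((a,b),c)", "((a,c),b)"})

    def test_refuses_large_problems(self, rng):
        ens = random_ensemble(9, 2, 0.3, rng)
        with pytest.raises(ValueError, match="N <= 8"):
            exhaustive_search(ens)
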