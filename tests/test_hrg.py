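import math

import numpy as np
import pytest

from hrgnet import (
    DirectedNetwork,
    HRGModel,
    build_ensemble,
    edge_counts,
    edge_probability,
    fit_theta,
    from_newick,
    log_likelihood,
    subtree_leaf_counts,
    to_newick,
)
from hrgnet.dendrogram import from_nested, random_dendrogram
from hrgnet.networks import NetworkEnsemble

from conftest import random_ensemble


def internal(tree):
    return list(tree.internal_nodes())


class TestLeafCounts:
    def test_three_leaf_tree_by_hand(self):
        tree = from_nested(("a", ("b", "c")))
        L, R = subtree_leaf_counts(tree)
        prods = sorted(int(L[i] * R[i]) for i in internal(tree))
        assert prods == [1, 2]  # cherry 1*1, root 1*2
        assert sum(prods) == 3

    def test_caterpillar_n4_by_hand(self):
        tree = from_nested((((("a", "b"), "c"), "d")))
        L, R = subtree_leaf_counts(tree)
        prods = sorted(int(L[i] * R[i]) for i in internal(tree))
        assert prods == [1, 2, 3]
        assert sum(prods) == 6  # 4*3/2

    @pytest.mark.parametrize("n", [2, 5, 16, 64])
    def test_products_partition_all_pairs(self, n, rng):
        tree = random_dendrogram([f"g{i}" for i in range(n)], rng)
        L, R = subtree_leaf_counts(tree)
        assert sum(int(L[i] * R[i]) for i in internal(tree)) == n * (n - 1) // 2

    def test_cherry_nodes_are_one_one(self, rng):
        tree = random_dendrogram([f"g{i}" for i in range(10)], rng)
        L, R = subtree_leaf_counts(tree)
        for i in internal(tree):
            if tree.is_leaf(tree.left[i]) and tree.is_leaf(tree.right[i]):
                assert (L[i], R[i]) == (1, 1)


class TestEdgeCounts:
    def test_worked_example_counts(self, toy_ensemble):
        tree = from_nested(("a", ("b", "c")))
        E = edge_counts(tree, toy_ensemble)
        cherry = tree.parent[tree.gene_index("b")]
        assert E[tree.root] == 2  # a-b in both networks
        assert E[cherry] == 1  # b-c in one network

    def test_empty_ensemble_edges(self):
        ens = build_ensemble([DirectedNetwork("abc", [])])
        tree = from_nested(("a", ("b", "c")))
        assert edge_counts(tree, ens).sum() == 0

    def test_complete_members_saturate(self):
        genes = ["a", "b", "c", "d"]
        complete = DirectedNetwork(genes, [(u, v) for u in genes for v in genes if u != v])
        ens = build_ensemble([complete] * 3)
        tree = from_nested((("a", "b"), ("c", "d")))
        E = edge_counts(tree, ens)
        L, R = subtree_leaf_counts(tree)
        for i in internal(tree):
            assert E[i] == 3 * L[i] * R[i]

    def test_per_network_counts_conserve_edges(self, rng):
        ens = random_ensemble(6, 5, 0.4, rng)
        tree = random_dendrogram(ens.genes, rng)
        per = edge_counts(tree, ens, per_network=True)
        for j, net in enumerate(ens.networks):
            assert per[j].sum() == len(net.edges)
        assert np.array_equal(per.sum(axis=0), edge_counts(tree, ens))

    def test_gene_mismatch_rejected(self, toy_ensemble):
        tree = from_nested(("a", ("b", "x")))
        with pytest.raises(ValueError, match="gene"):
            edge_counts(tree, toy_ensemble)


class TestFitTheta:
    def test_worked_example_theta(self, toy_ensemble):
        tree = from_nested(("a", ("b", "c")))
        theta = fit_theta(tree, toy_ensemble)
        cherry = tree.parent[tree.gene_index("b")]
        assert theta[tree.root] == pytest.approx(0.5)  # 2 / (2*1*2)
        assert theta[cherry] == pytest.approx(0.5)  # 1 / (2*1*1)

    def test_extreme_ensembles(self):
        genes = ["a", "b", "c"]
        tree = from_nested(("a", ("b", "c")))
        empty = build_ensemble([DirectedNetwork(genes, [])] * 4)
        assert np.all(fit_theta(tree, empty)[internal(tree)] == 0.0)
        complete = DirectedNetwork(genes, [(u, v) for u in genes for v in genes if u != v])
        full = build_ensemble([complete] * 4)
        assert np.all(fit_theta(tree, full)[internal(tree)] == 1.0)

    def test_mle_optimality_under_perturbation(self, rng):
        """Perturbing any theta_i away from the closed form never improves the objective."""
        eps = 1e-3
        for _ in range(5):
            ens = random_ensemble(6, 8, 0.3, rng)
            tree = random_dendrogram(ens.genes, rng)
            theta = fit_theta(tree, ens)
            E = edge_counts(tree, ens)
            from hrgnet.hrg import subtree_leaf_counts as slc

            L, R = slc(tree)

            def objective(th):
                total = 0.0
                for i in internal(tree):
                    big = ens.n_networks * L[i] * R[i]
                    e = E[i]
                    if e > 0:
                        total += e * math.log(th[i])
                    if big - e > 0:
                        total += (big - e) * math.log(1 - th[i])
                return total

            base = objective(np.clip(theta, 1e-12, 1 - 1e-12))
            for i in internal(tree):
                for sign in (+1, -1):
                    pert = theta.copy()
                    pert[i] = np.clip(theta[i] + sign * eps, 1e-9, 1 - 1e-9)
                    assert objective(pert) <= base + 1e-12

    def test_generative_estimation_consistency(self, rng):
        """fit_theta at the planted tree recovers the planted theta from samples."""
        tree = from_nested((("a", "b"), ("c", ("d", "e"))))
        theta = np.zeros(tree.n_nodes)
        planted = {i: t for i, t in zip(internal(tree), [0.1, 0.8, 0.3, 0.6])}
        for i, t in planted.items():
            theta[i] = t
        model = HRGModel(tree, theta)
        ng = 100
        ens = NetworkEnsemble([model.sample(rng) for _ in range(ng)])
        est = fit_theta(tree, ens)
        from hrgnet.hrg import subtree_leaf_counts as slc

        L, R = slc(tree)
        for i, t in planted.items():
            se = math.sqrt(t * (1 - t) / (ng * L[i] * R[i]))
            assert abs(est[i] - t) <= 3 * se + 1e-12


class TestLogLikelihood:
    def test_worked_example_values(self, toy_ensemble):
        assert log_likelihood(from_nested(("a", ("b", "c"))), toy_ensemble) == pytest.approx(
            6 * math.log(0.5), abs=1e-10
        )
        assert log_likelihood(from_nested(("b", ("a", "c"))), toy_ensemble) == pytest.approx(
            math.log(0.25) + 3 * math.log(0.75), abs=1e-10
        )

    def test_consistent_ensemble_has_zero_log_likelihood(self):
        net = DirectedNetwork("abcd", [("a", "b"), ("c", "d")])
        ens = build_ensemble([net] * 5)
        tree = from_nested((("a", "b"), ("c", "d")))
        assert log_likelihood(tree, ens) == 0.0

    def test_always_nonpositive(self, rng):
        for _ in range(10):
            ens = random_ensemble(5, 6, 0.4, rng)
            tree = random_dendrogram(ens.genes, rng)
            assert log_likelihood(tree, ens) <= 0.0

    def test_aggregated_equals_per_network_double_sum(self, rng):
        ens = random_ensemble(6, 7, 0.3, rng)
        tree = random_dendrogram(ens.genes, rng)
        per = edge_counts(tree, ens, per_network=True)
        theta = fit_theta(tree, ens)
        from hrgnet.hrg import subtree_leaf_counts as slc

        L, R = slc(tree)
        total = 0.0
        for j in range(ens.n_networks):
            for i in internal(tree):
                e, th = per[j, i], theta[i]
                if e > 0:
                    total += e * math.log(th)
                if L[i] * R[i] - e > 0 and th < 1:
                    total += (L[i] * R[i] - e) * math.log(1 - th)
        assert log_likelihood(tree, ens) == pytest.approx(total, abs=1e-9)


class TestModel:
    def make_model(self):
        tree = from_nested(("a", ("b", "c")))
        theta = np.zeros(tree.n_nodes)
        theta[tree.root] = 0.5
        theta[tree.parent[tree.gene_index("b")]] = 0.9
        return HRGModel(tree, theta)

    def test_edge_probability_symmetric_and_from_lca(self):
        model = self.make_model()
        assert edge_probability(model, "a", "b") == pytest.approx(0.5)
        assert edge_probability(model, "b", "a") == pytest.approx(0.5)
        assert edge_probability(model, "b", "c") == pytest.approx(0.9)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-regulation"):
            edge_probability(self.make_model(), "a", "a")

    def test_extreme_theta_sampling(self, rng):
        tree = from_nested(("a", ("b", "c")))
        zeros = HRGModel(tree, np.zeros(tree.n_nodes))
        assert zeros.sample(rng).edges == frozenset()
        ones = np.zeros(tree.n_nodes)
        ones[list(tree.internal_nodes())] = 1.0
        assert len(HRGModel(tree, ones).sample(rng).edges) == 3

    def test_monte_carlo_edge_count_matches_expectation(self, rng):
        model = self.make_model()
        n_draws = 10_000
        counts = np.array([len(model.sample(rng).edges) for _ in range(n_draws)])
        expected = model.expected_edge_count()  # sum L_i R_i theta_i
        var = 2 * 0.5 * 0.5 + 0.9 * 0.1  # Bernoulli variances per pair
        se = math.sqrt(var / n_draws)
        assert abs(counts.mean() - expected) <= 3 * se

    def test_theta_out_of_range_rejected(self):
        tree = from_nested(("a", ("b", "c")))
        theta = np.zeros(tree.n_nodes)
        theta[tree.root] = 1.5
        with pytest.raises(ValueError):
            HRGModel(tree, theta)


class TestNewick:
    def test_round_trip_identity(self, rng):
        ens = random_ensemble(7, 5, 0.3, rng)
        tree = random_dendrogram(ens.genes, rng)
        model = HRGModel(tree, fit_theta(tree, ens))
        back = from_newick(to_newick(model))
        assert back.tree.canonical_signature() == model.tree.canonical_signature()
        assert set(back.genes) == set(model.genes)

        def by_leaf_labels(m):
            return {
                frozenset(m.genes[l] for l in m.tree.leaves_below(i)): m.theta[i]
                for i in m.tree.internal_nodes()
            }

        original, parsed = by_leaf_labels(model), by_leaf_labels(back)
        assert original.keys() == parsed.keys()
        for key, value in original.items():
            assert parsed[key] == pytest.approx(value, rel=1e-12, abs=1e-12)

    def test_leaf_names_with_spaces_are_quoted(self):
        tree = from_nested(("gene one", ("b", "c")))
        model = HRGModel(tree, np.full(tree.n_nodes, 0.25))
        text = to_newick(model)
        assert "'gene one'" in text
        assert from_newick(text).genes[0] == "gene one"

    @pytest.mark.parametrize(
        "bad",
        ["(a,(b,c);", "(a,b", "not newick at all ;;;", "(a,(b,c,d));"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(ValueError):
            from_newick(bad)
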