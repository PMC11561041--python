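import numpy as np
import pytest

from pugrank.gat import EdgeIndex, GraphAttentionClassifier, soft_label_nll
from pugrank.network_io import GeneNetwork
from pugrank.pu_grab import (
    PUGraphModel,
    PUInstance,
    Potentials,
    default_features,
    grab_rank,
    init_potentials,
    lbp_marginalize,
    make_soft_targets,
    train_classifier,
    update_prior,
)
from conftest import enumerate_marginals, random_tree


def make_instance(network, positives, n_features=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(network.n_genes, n_features))
    return PUInstance(
        network=network, positives=tuple(positives), features=X,
        feature_names=tuple(f"f{i}" for i in range(n_features)),
    )


class TestPotentials:
    def test_unlabeled_node_potential_is_prior(self, chain_network):
        inst = make_instance(chain_network, ["a"])
        pot = init_potentials(inst, prior=0.3, h=0.9)
        i = chain_network.gene_index["b"]
        assert pot.node[i] == pytest.approx([0.3, 0.7])

    def test_zero_prior_floored(self, chain_network):
        inst = make_instance(chain_network, ["a"])
        pot = init_potentials(inst, prior=0.0, h=0.9)
        i = chain_network.gene_index["b"]
        assert pot.node[i, 0] == pytest.approx(1e-12)
        assert pot.node[i, 1] == pytest.approx(1 - 1e-12)

    def test_positive_clamped_regardless_of_prior(self, chain_network):
        inst = make_instance(chain_network, ["a"])
        pot = init_potentials(inst, prior=0.3, h=0.9)
        i = chain_network.gene_index["a"]
        assert pot.node[i] == pytest.approx([1 - 1e-6, 1e-6])
        assert pot.observed[i]

    def test_non_homophilous_h_rejected(self, chain_network):
        inst = make_instance(chain_network, ["a"])
        for h in (0.5, 0.3, 1.0):
            with pytest.raises(ValueError):
                init_potentials(inst, prior=0.1, h=h)


class TestLBP:
    def test_isolated_gene_belief_equals_potential(self):
        net = GeneNetwork(genes=("a", "b", "z"), edges={("a", "b"): 1.0})
        node = np.array([[0.5, 0.5], [0.5, 0.5], [0.3, 0.7]])
        beliefs = lbp_marginalize(net, Potentials(node=node, homophily=0.9))
        i = net.gene_index["z"]
        assert beliefs[i] == pytest.approx([0.3, 0.7])

    def test_two_node_clamped_neighbor(self, chain_network):
        """A labeled positive pulls a uniform-prior neighbour to (0.9, 0.1)."""
        inst = make_instance(chain_network, ["a"])
        pot = init_potentials(inst, prior=0.5, h=0.9)
        beliefs = lbp_marginalize(inst, pot, tol=1e-10)
        i = chain_network.gene_index["b"]
        assert beliefs[i, 0] == pytest.approx(0.9, abs=1e-4)
        assert beliefs[i, 1] == pytest.approx(0.1, abs=1e-4)

    def test_exact_on_random_trees(self):
        """LBP beliefs equal enumeration marginals on trees within 1e-6."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(2, 13))
            edges = random_tree(rng, n)
            names = [f"n{i:02d}" for i in range(n)]
            net = GeneNetwork.from_edges((names[a], names[b], 1.0) for a, b in edges)
            pos = rng.uniform(0.05, 0.95, size=n)
            node = np.column_stack([pos, 1 - pos])
            h = 0.6 if trial % 2 else 0.9
            idx = net.gene_index
            order = [names.index(g) for g in net.genes]
            pot = Potentials(node=node[order], homophily=h)
            beliefs = lbp_marginalize(net, pot, tol=1e-12, max_iter=500)
            exact = enumerate_marginals(
                n,
                [(idx[names[a]], idx[names[b]]) for a, b in edges],
                pot.node,
                h,
            )
            assert np.abs(beliefs - exact).max() < 1e-6

    def test_beliefs_normalized(self, line_network):
        inst = make_instance(line_network, ["a", "c"])
        beliefs = lbp_marginalize(inst, init_potentials(inst, 0.2, 0.8))
        assert beliefs.sum(axis=1) == pytest.approx(np.ones(5))
        assert (beliefs >= 0).all()

    def test_homophily_monotone_on_two_node_fixture(self, chain_network):
        """The unlabeled neighbour's positive belief increases with h."""
        inst = make_instance(chain_network, ["a"])
        i = chain_network.gene_index["b"]
        vals = []
        for h in (0.55, 0.65, 0.75, 0.85, 0.95):
            pot = init_potentials(inst, prior=0.5, h=h)
            vals.append(lbp_marginalize(inst, pot, tol=1e-10)[i, 0])
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_max_iter_warns_but_returns(self, line_network, caplog):
        inst = make_instance(line_network, ["a"])
        pot = init_potentials(inst, 0.3, 0.9)
        import logging

        with caplog.at_level(logging.WARNING, logger="pugrank.pu_grab"):
            beliefs = lbp_marginalize(inst, pot, tol=0.0, max_iter=3)
        assert beliefs.shape == (5, 2)
        assert any("max_iter" in r.message for r in caplog.records)


class TestClassifier:
    def edge_index(self):
        rng = np.random.default_rng(0)
        n = 9
        edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
        src = np.array([a for a, b in edges] + [b for a, b in edges])
        dst = np.array([b for a, b in edges] + [a for a, b in edges])
        return EdgeIndex.with_self_loops(src, dst, n), n

    def test_gradients_match_finite_differences(self):
        """Hand-derived backprop agrees with central differences."""
        ei, n = self.edge_index()
        rng = np.random.default_rng(3)
        X = rng.normal(size=(n, 4))
        clf = GraphAttentionClassifier(n_features=4, hidden=8, heads=2, seed=1)
        targets = rng.dirichlet([1, 1], size=n)
        weights = rng.uniform(0.5, 1.5, size=n)
        _, grads, _ = clf.loss_and_grads(X, ei, targets, weights)
        eps = 1e-6
        for li, layer in enumerate(clf._params):
            for hi, p in enumerate(layer):
                for attr in ("W", "a_dst", "a_src"):
                    arr = getattr(p, attr)
                    g = getattr(grads[li][hi], attr)
                    it = np.nditer(arr, flags=["multi_index"])
                    for _ in range(min(arr.size, 4)):
                        mi = it.multi_index
                        old = arr[mi]
                        arr[mi] = old + eps
                        lp, _, _ = clf.loss_and_grads(X, ei, targets, weights)
                        arr[mi] = old - eps
                        lm, _, _ = clf.loss_and_grads(X, ei, targets, weights)
                        arr[mi] = old
                        num = (lp - lm) / (2 * eps)
                        assert abs(num - g[mi]) < 1e-6 * max(1.0, abs(num))
                        next(it, None)

    def test_loss_terms(self):
        """Soft-label NLL: -log 0.5 = ln 2 for a 50/50 prediction; 0 when exact."""
        assert soft_label_nll(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == (
            pytest.approx(np.log(2), abs=1e-10)
        )
        assert soft_label_nll(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_belief_one_hot_equals_hard_label(self):
        pred = np.array([0.7, 0.3])
        assert soft_label_nll(np.array([1.0, 0.0]), pred) == pytest.approx(
            -np.log(0.7)
        )

    def test_training_probabilities_on_simplex(self, line_network):
        inst = make_instance(line_network, ["a"])
        beliefs = np.tile([0.2, 0.8], (5, 1))
        probs, _ = train_classifier(inst, beliefs, epochs=20, seed=0)
        assert probs.shape == (5, 2)
        assert probs.sum(axis=1) == pytest.approx(np.ones(5))

    def test_soft_targets_weighting(self, line_network):
        inst = make_instance(line_network, ["a", "b"])
        beliefs = np.tile([0.3, 0.7], (5, 1))
        targets, weights = make_soft_targets(inst, beliefs)
        mask = inst.positive_mask()
        assert (targets[mask] == [1.0, 0.0]).all()
        assert weights[mask] == pytest.approx(np.full(2, 1 / 2))
        assert weights[~mask] == pytest.approx(np.full(3, 1 / 3))


class TestUpdatePrior:
    def test_indicator_mean(self):
        assert update_prior(np.array([0.6, 0.4, 0.7, 0.2])) == 0.5

    def test_extremes(self):
        assert update_prior(np.array([0.1, 0.5, 0.49])) == 0.0
        assert update_prior(np.array([0.9, 0.51])) == 1.0

    def test_threshold_is_strict(self):
        assert update_prior(np.array([0.5])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            update_prior(np.array([]))

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=200)
        expected = sum(1 for v in vals if v > 0.5) / len(vals)
        assert update_prior(vals) == expected


class TestDefaultFeatures:
    def test_standardized_and_imputed(self, line_network):
        scores = {g: s for g, s in zip(line_network.genes, [0.5, 0.2, 0.1, 0.1, 0.1])}
        import pandas as pd

        deg = pd.DataFrame(
            {"gene": ["a"], "log2FC": [2.0], "pvalue": [0.001], "padj": [0.01]}
        )
        X, names = default_features(line_network, scores, deg)
        assert X.shape == (5, len(names))
        assert X.mean(axis=0) == pytest.approx(np.zeros(len(names)), abs=1e-9)
        # gene absent from the DEG table gets |log2FC| imputed as 0 (pre-scaling)
        col = names.index("abs_log2fc")
        raw = X[:, col]
        absent = [i for i, g in enumerate(line_network.genes) if g != "a"]
        assert len({round(raw[i], 12) for i in absent}) == 1


class TestGrabRank:
    def build_module_fixture(self, seed=0):
        """30 genes: a 8-gene module wired to 4 labeled positives, plus a
        degree-matched background; module genes touch >=2 positives,
        background genes touch none."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(30)]
        positives = genes[:4]
        module = genes[4:12]
        background = genes[12:]
        edges = []
        for m in module:
            for p in rng.choice(positives, size=2, replace=False):
                edges.append((p, m, 0.9))
        # background chain with similar degrees, no positive contact
        for i in range(len(background) - 1):
            edges.append((background[i], background[i + 1], 0.9))
        edges.append((module[0], background[0], 0.9))  # connect components
        net = GeneNetwork.from_edges(edges)
        return net, [g for g in positives if g in net], module, background

    def test_module_genes_outrank_background(self):
        """Genes adjacent to >=2 labeled positives outrank background genes."""
        net, positives, module, background = self.build_module_fixture()
        inst = make_instance(net, positives, seed=1)
        ranking = grab_rank(inst, seed=0, outer_max=5)
        module_ranks = [ranking.rank_of(g) for g in module if g in net]
        bg_ranks = [ranking.rank_of(g) for g in background if g in net]
        assert np.median(module_ranks) < np.median(bg_ranks)

    def test_matches_exact_marginal_ordering_on_fixture(self):
        """On the module fixture, the exact-MRF marginal ordering also puts
        the module above the background (oracle agreement at group level)."""
        net, positives, module, background = self.build_module_fixture()
        inst = make_instance(net, positives, seed=1)
        pot = init_potentials(inst, prior=0.1, h=0.9)
        beliefs = lbp_marginalize(inst, pot, tol=1e-10, max_iter=1000)
        idx = net.gene_index
        mod_b = [beliefs[idx[g], 0] for g in module if g in net]
        bg_b = [beliefs[idx[g], 0] for g in background if g in net]
        assert np.median(mod_b) > np.median(bg_b)

    def test_outer_max_one_single_cycle(self, line_network):
        inst = make_instance(line_network, ["a"])
        model = PUGraphModel(instance=inst, outer_max=1, epochs=5)
        res = model.fit(seed=0)
        assert res.n_outer == 1
        assert len(res.prior_history) == 2  # initial 0 plus one update
        assert res.prior_history[0] == 0.0

    def test_same_seed_identical_ranking(self, line_network):
        inst = make_instance(line_network, ["a"])
        r1 = grab_rank(inst, seed=5, outer_max=3, epochs=10)
        r2 = grab_rank(inst, seed=5, outer_max=3, epochs=10)
        assert r1 == r2

    def test_summary_mentions_key_quantities(self, line_network):
        inst = make_instance(line_network, ["a"])
        res = PUGraphModel(instance=inst, outer_max=2, epochs=5).fit(seed=0)
        text = res.summary()
        assert "labeled positives: 1" in text
        assert "genes:" in text and "homophily" in text


class TestPriorRecovery:
    @pytest.mark.parametrize("planted_fraction", [0.05, 0.1, 0.2])
    def test_prior_estimate_tracks_planted_fraction(self, planted_fraction):
        """With strong homophily, pi-hat lands within +/-50% of the planted
        positive fraction among unlabeled genes on >= 2 of 3 seeds."""
        hits = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n = 250
            genes = [f"g{i:03d}" for i in range(n)]
            n_module = max(4, int(round(2 * planted_fraction * n)))
            module = genes[:n_module]
            labeled = module[: n_module // 2]
            edges = []
            for i, a in enumerate(module):  # dense homophilous module
                for b in module[i + 1 :]:
                    if rng.random() < 0.4:
                        edges.append((a, b, 0.9))
            rest = genes[n_module:]
            for i in range(len(rest) - 1):
                edges.append((rest[i], rest[i + 1], 0.9))
                if rng.random() < 0.05:
                    edges.append((rest[i], module[int(rng.integers(n_module))], 0.9))
            net = GeneNetwork.from_edges(edges)
            labeled = [g for g in labeled if g in net]
            unlabeled_truth = [g for g in module[n_module // 2 :] if g in net]
            n_unlabeled = net.n_genes - len(labeled)
            truth_frac = len(unlabeled_truth) / n_unlabeled
            inst = make_instance(net, labeled, seed=seed)
            res = PUGraphModel(instance=inst, outer_max=10, epochs=50).fit(seed=seed)
            if abs(res.prior - truth_frac) <= 0.5 * truth_frac:
                hits += 1
        assert hits >= 2
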