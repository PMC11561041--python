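import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pugrank.network_io import GeneNetwork
from pugrank.positive_selection import (
    bh_adjust,
    build_positive_set,
    filter_degs,
    rwr,
    top_k,
    wilcoxon_deg,
)


def deg_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2FC", "pvalue", "padj"])


class TestFilterDegs:
    def test_strict_cutoffs(self):
        """|log2FC| > 1 and padj < .05 are both strict inequalities."""
        table = deg_table(
            [
                ("gA", 2.3, 0.001, 0.01),   # kept
                ("gB", 1.0, 0.0001, 0.001), # |lfc| not > 1
                ("gC", -1.7, 0.01, 0.05),   # padj not < .05
                ("gD", -1.2, 0.001, 0.02),  # kept (negative lfc)
            ]
        )
        kept = filter_degs(table)
        assert list(kept["gene"]) == ["gA", "gD"]

    def test_sorted_by_padj_ties_by_abs_lfc_then_gene(self):
        table = deg_table(
            [
                ("gB", 1.5, 0.001, 0.01),
                ("gA", 1.5, 0.001, 0.01),
                ("gC", 3.0, 0.001, 0.01),
                ("gD", 2.0, 0.0001, 0.002),
            ]
        )
        kept = filter_degs(table)
        assert list(kept["gene"]) == ["gD", "gC", "gA", "gB"]

    def test_empty_result_allowed(self):
        assert len(filter_degs(deg_table([("g", 0.5, 0.5, 0.9)]))) == 0


class TestTopK:
    def test_exhaustion_returns_fewer(self):
        assert top_k(["a", "b", "c"], k=50) == ("a", "b", "c")

    def test_exclusion_skips_to_next(self):
        assert top_k(["a", "b", "c"], k=2, exclude={"a"}) == ("b", "c")

    def test_mapping_sorted_desc_ties_by_id(self):
        assert top_k({"b": 2.0, "c": 1.0, "a": 2.0}, k=2) == ("a", "b")

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_k(["a"], k=0)

    @given(k1=st.integers(1, 10), k2=st.integers(1, 10))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_monotone_in_k(self, k1, k2):
        """Enlarging k never removes a previously selected gene."""
        genes = [f"g{i}" for i in range(12)]
        if k1 > k2:
            k1, k2 = k2, k1
        assert set(top_k(genes, k=k1)) <= set(top_k(genes, k=k2))


class TestRWR:
    def test_single_isolated_seed_keeps_all_mass(self):
        # one connected pair plus the seed's own component
        net = GeneNetwork(genes=("a", "b", "s"), edges={("a", "b"): 1.0})
        scores = rwr(net, ["s"], restart_prob=0.5)
        assert scores["s"] == pytest.approx(1.0)

    def test_two_node_chain_fixed_point(self, chain_network):
        """p = r p0 + (1-r) W^T p on a-b with seed a gives (2/3, 1/3)."""
        scores = rwr(chain_network, ["a"], restart_prob=0.5)
        assert scores["a"] == pytest.approx(2 / 3, abs=1e-4)
        assert scores["b"] == pytest.approx(1 / 3, abs=1e-4)

    def test_restart_one_returns_seed_distribution(self, line_network):
        scores = rwr(line_network, ["a", "b"], restart_prob=1.0)
        assert scores["a"] == pytest.approx(0.5)
        assert scores["b"] == pytest.approx(0.5)
        assert scores["c"] == 0.0

    def test_missing_seeds_dropped_all_missing_is_error(self, line_network):
        scores = rwr(line_network, ["a", "zzz"])
        assert sum(scores.values()) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rwr(line_network, ["zzz"])

    def test_matches_direct_linear_solve_on_random_graphs(self):
        """Iterative fixed point equals r (I - (1-r) W^T)^-1 p0 within 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            names = [f"g{i}" for i in range(n)]
            edges = []
            for i in range(1, n):
                j = int(rng.integers(0, i))
                edges.append((names[j], names[i], float(rng.uniform(0.2, 1.0))))
            for _ in range(n):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    edges.append((names[i], names[j], float(rng.uniform(0.2, 1.0))))
            net = GeneNetwork.from_edges(edges)
            seeds = list(rng.choice(net.genes, size=3, replace=False))
            r = 0.4
            scores = rwr(net, seeds, restart_prob=r)
            # independent dense solve
            idx = net.gene_index
            adj = net.adjacency().toarray()
            w = adj / adj.sum(axis=0, keepdims=True)  # column-stochastic
            p0 = np.zeros(net.n_genes)
            p0[[idx[s] for s in seeds]] = 1 / len(seeds)
            direct = r * np.linalg.solve(np.eye(net.n_genes) - (1 - r) * w, p0)
            got = np.array([scores[g] for g in net.genes])
            assert np.abs(got - direct).max() < 1e-8
            assert got.sum() == pytest.approx(1.0)


class TestBuildPositiveSet:
    def make_net(self):
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(30)]
        edges = [(names[int(rng.integers(0, i))], names[i], 0.9) for i in range(1, 30)]
        return GeneNetwork.from_edges(edges)

    def test_disjoint_sources_sum_and_provenance(self):
        net = self.make_net()
        deg_top = [g for g in net.genes[:5] if g != "g0"]
        positives, np_scores = build_positive_set(deg_top, net, "g0", k_np=5)
        assert len(positives) <= len(deg_top) + 5
        np_only = [g for g, t in positives.provenance.items() if t == "NP"]
        assert len(np_only) == 5
        # NP picks exclude the seeds themselves
        assert not (set(np_only) & (set(deg_top) | {"g0"}))
        assert sum(np_scores.values()) == pytest.approx(1.0)

    def test_ko_gene_never_positive(self):
        net = self.make_net()
        positives, _ = build_positive_set(list(net.genes[1:4]), net, net.genes[0], k_np=3)
        assert net.genes[0] not in positives.genes


class TestWilcoxonDeg:
    def make_matrix(self, rng, shift):
        # 8 v 8 samples: the smallest exact rank-sum p-value (2/C(16,8))
        # survives BH over 40 genes at the 0.05 level
        genes = [f"g{i}" for i in range(40)]
        wt = rng.lognormal(3, 0.2, size=(40, 8))
        ko = rng.lognormal(3, 0.2, size=(40, 8))
        ko[0] *= 2 ** shift
        cols = [f"W{i}" for i in range(8)] + [f"K{i}" for i in range(8)]
        expr = pd.DataFrame(np.hstack([wt, ko]), index=genes, columns=cols)
        design = pd.Series(["WT"] * 8 + ["KO"] * 8, index=cols)
        return expr, design

    def test_identical_conditions_give_zero_lfc(self):
        expr = pd.DataFrame(
            {"W1": [4.0], "W2": [4.0], "K1": [4.0], "K2": [4.0]}, index=["g"]
        )
        design = pd.Series(["WT", "WT", "KO", "KO"], index=expr.columns)
        out = wilcoxon_deg(expr, design)
        assert out.loc[0, "log2FC"] == 0.0

    def test_doubling_plus_one_gives_exact_lfc_one(self):
        """mean_KO = 2*mean_WT + 1 with pseudo-count 1 gives log2FC = 1 exactly."""
        m = 5.0
        expr = pd.DataFrame(
            {"W1": [m], "W2": [m], "K1": [2 * m + 1], "K2": [2 * m + 1]}, index=["g"]
        )
        design = pd.Series(["WT", "WT", "KO", "KO"], index=expr.columns)
        out = wilcoxon_deg(expr, design)
        assert out.loc[0, "log2FC"] == pytest.approx(1.0)

    def test_shifted_gene_detected(self):
        expr, design = self.make_matrix(np.random.default_rng(0), shift=3.0)
        out = wilcoxon_deg(expr, design).set_index("gene")
        assert out.loc["g0", "log2FC"] > 2
        assert out.loc["g0", "padj"] < 0.05

    def test_single_sample_condition_rejected(self):
        expr = pd.DataFrame({"W1": [1.0], "K1": [1.0], "K2": [1.0]}, index=["g"])
        design = pd.Series(["WT", "KO", "KO"], index=expr.columns)
        with pytest.raises(ValueError):
            wilcoxon_deg(expr, design)


class TestBHAdjust:
    def test_step_up_example(self):
        """BH on (0.01, 0.02, 0.03) with m=3 gives (0.03, 0.03, 0.03)."""
        assert bh_adjust(np.array([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
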