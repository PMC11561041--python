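"""Shared fixtures: tiny hand-built networks and the synthetic benchmark runs.

The benchmark fixture runs the full pipeline (three presets x three seeds,
2x5-fold CV each) once per session; the acceptance tests read from it.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pugrank import GeneNetwork, run_synthetic_benchmark

BENCHMARK_SEEDS = (1, 2, 3)
BENCHMARK_PRESETS = ("default", "inflated_fp", "secondary_top")


@pytest.fixture()
def chain_network() -> GeneNetwork:
    """Two genes joined by a unit-confidence edge."""
    return GeneNetwork.from_edges([("a", "b", 1.0)])


@pytest.fixture()
def line_network() -> GeneNetwork:
    """Five-gene path a-b-c-d-e with unit confidences."""
    pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    return GeneNetwork.from_edges([(x, y, 1.0) for x, y in pairs])


def random_tree(rng: np.random.Generator, n: int) -> list[tuple[int, int]]:
    """Uniform-ish random tree: each node attaches to a random predecessor."""
    return [(int(rng.integers(0, i)), i) for i in range(1, n)]


def enumerate_marginals(n, edges, node_pot, h):
    """Brute-force marginals of the binary pairwise MRF by full enumeration."""
    psi = np.array([[h, 1 - h], [1 - h, h]])
    probs = np.zeros((n, 2))
    for assign in itertools.product([0, 1], repeat=n):
        w = 1.0
        for i, a in enumerate(assign):
            w *= node_pot[i][a]
        for i, j in edges:
            w *= psi[assign[i], assign[j]]
        for i, a in enumerate(assign):
            probs[i, a] += w
    return probs / probs.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def benchmark_runs() -> dict:
    """Pipeline results for every (preset, seed) study condition.

    2x5-fold cross-validation with DIBRA aggregation on the 2000-gene
    presets; this is the scaled-down benchmark protocol shared by the
    head-to-head, loose-cutoff and secondary-top acceptance tests.
    """
    runs: dict[tuple[str, int], dict] = {}
    for preset in BENCHMARK_PRESETS:
        for seed in BENCHMARK_SEEDS:
            runs[(preset, seed)] = run_synthetic_benchmark(
                preset, seed=seed, repeats=2, folds=5
            )
    return runs
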