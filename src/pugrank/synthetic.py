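"""Synthetic knock-out benchmarks: a network with a planted phenotype module
and matching WT/KO expression.

The generator emulates the situation the pipeline is built for: a KO gene
whose phenotype-related genes form a connected module in the interaction
network (neighbouring genes tend to share phenotype responsibility), with
expression shifts of mixed strength.  A configurable fraction of the
module responds strongly (these pass strict DEG cutoffs), the rest shift
by only a third of the effect (sub-threshold — the false negatives the PU
stage is supposed to rescue), and a small set of off-module background
genes also shifts strongly (confounders — the false positives a loose
cutoff would admit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .network_io import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class SyntheticInstance:
    """A generated benchmark: network, KO gene, planted truth, expression."""

    network: GeneNetwork
    ko_gene: str
    truth: frozenset[str]
    strong_truth: frozenset[str]
    subthreshold_truth: frozenset[str]
    confounders: frozenset[str]
    expression: pd.DataFrame
    design: pd.Series
    params: dict = field(hash=False)
    seed: int = 0


def simulate_network(
    n_genes: int = 2000,
    module_size: int = 100,
    p_in: float = 0.12,
    p_out: float = 0.003,
    background_degree: float = 8.0,
    seed: int = 0,
) -> tuple[GeneNetwork, str, set[str]]:
    """Planted-partition gene network with a phenotype module around the KO gene.

    The module genes connect among themselves and to the KO gene with
    probability ``p_in``; background genes form an Erdős–Rényi graph with
    the given expected degree; module–background (and KO–background) pairs
    connect with probability ``p_out``.  Edge confidences are drawn from
    Uniform(0.75, 1), so a STRING-style > 0.700 filter keeps them all but
    is exercised.  Only the largest connected component is retained; the
    KO gene must survive (up to 10 regeneration attempts).
    """
    if module_size >= n_genes:
        raise ValueError("module_size must be smaller than n_genes")
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        network, ko, truth = _simulate_once(
            n_genes, module_size, p_in, p_out, background_degree, rng
        )
        if ko in network:
            if attempt:
                logger.info("network regenerated %d time(s)", attempt)
            return network, ko, truth
    raise RuntimeError("KO gene disconnected in 10 consecutive attempts")


def _simulate_once(n_genes, module_size, p_in, p_out, background_degree, rng):
    width = len(str(n_genes))
    ids = np.array([f"g{i:0{width}d}" for i in range(n_genes)], dtype=object)
    ko = str(ids[0])
    module = ids[1 : module_size + 1]
    background = ids[module_size + 1 :]
    n_bg = len(background)

    edges: list[tuple[str, str]] = []

    def sample_pairs(left, right, p, cross):
        if p <= 0:
            return
        if cross:
            mask = rng.random((len(left), len(right))) < p
            li, ri = np.nonzero(mask)
            edges.extend(zip(left[li], right[ri]))
        else:
            iu, ju = np.triu_indices(len(left), k=1)
            mask = rng.random(iu.size) < p
            edges.extend(zip(left[iu[mask]], left[ju[mask]]))

    mod_and_ko = np.concatenate([[ko], module])
    sample_pairs(mod_and_ko, None, p_in, cross=False)
    p_bg = min(background_degree / max(n_bg - 1, 1), 1.0)
    sample_pairs(background, None, p_bg, cross=False)
    sample_pairs(mod_and_ko, background, p_out, cross=True)

    confidences = rng.uniform(0.75, 1.0, size=len(edges))
    network = GeneNetwork.from_edges(
        (a, b, c) for (a, b), c in zip(edges, confidences)
    )
    # keep the largest connected component
    import networkx as nx

    g = network.to_networkx()
    lcc = max(nx.connected_components(g), key=len)
    kept_edges = [
        (a, b, d["confidence"])
        for a, b, d in g.edges(data=True)
        if a in lcc and b in lcc
    ]
    network = GeneNetwork.from_edges(kept_edges)
    truth = {str(m) for m in module if m in network}
    if len(truth) < module_size:
        logger.info(
            "planted module trimmed from %d to %d genes by LCC", module_size, len(truth)
        )
    return network, ko, truth


def simulate_expression(
    network: GeneNetwork,
    ko_gene: str,
    truth: Iterable[str],
    n_wt: int = 10,
    n_ko: int = 10,
    effect_lfc: float = 2.0,
    noise_sd: float = 0.5,
    dropout: float = 0.0,
    strong_fraction: float = 0.6,
    confounder_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, frozenset[str]]]:
    """WT/KO expression with mixed-strength shifts on the planted module.

    Per-gene baseline log2-expression is Uniform(2, 8) with Gaussian noise
    of ``noise_sd`` per sample.  In KO samples: the KO gene is forced to 0;
    a ``strong_fraction`` of truth genes shift by ±effect_lfc (sign random
    per gene); the remaining truth genes shift by ±effect_lfc/3
    (sub-threshold); a ``confounder_fraction`` of background genes shift by
    ±effect_lfc (off-module confounders).  Values are exponentiated to a
    positive scale; optional dropout zeroes entries independently.

    Returns (expression genes × samples, design sample → condition,
    group dict with strong/subthreshold/confounder gene sets).
    """
    if n_wt < 3 or n_ko < 3:
        raise ValueError("need at least 3 samples per condition")
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must be in [0, 1)")
    if not (0.0 <= strong_fraction <= 1.0 and 0.0 <= confounder_fraction <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(network.genes)
    truth = [g for g in truth if g in network]
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    n_strong = int(round(strong_fraction * len(truth)))
    perm = rng.permutation(len(truth))
    strong = frozenset(truth[i] for i in perm[:n_strong])
    subthreshold = frozenset(truth[i] for i in perm[n_strong:])
    background = [g for g in genes if g not in set(truth) and g != ko_gene]
    n_conf = int(round(confounder_fraction * len(background)))
    conf_idx = rng.permutation(len(background))[:n_conf]
    confounders = frozenset(background[i] for i in conf_idx)

    shift = np.zeros(n)
    for gene_set, magnitude in ((strong, effect_lfc), (subthreshold, effect_lfc / 3.0),
                                (confounders, effect_lfc)):
        for g in sorted(gene_set):  # sorted: frozenset order is hash-dependent
            shift[gene_pos[g]] = magnitude * (1 if rng.random() < 0.5 else -1)

    mu = rng.uniform(2.0, 8.0, size=n)
    wt_log = mu[:, None] + rng.normal(0.0, noise_sd, size=(n, n_wt))
    ko_log = (mu + shift)[:, None] + rng.normal(0.0, noise_sd, size=(n, n_ko))
    expr = np.concatenate([2.0**wt_log, 2.0**ko_log], axis=1)
    if ko_gene in gene_pos:
        expr[gene_pos[ko_gene], n_wt:] = 0.0
    if dropout > 0:
        expr[rng.random(expr.shape) < dropout] = 0.0

    samples = [f"WT_{i+1}" for i in range(n_wt)] + [f"KO_{i+1}" for i in range(n_ko)]
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    design = pd.Series(
        ["WT"] * n_wt + ["KO"] * n_ko, index=samples, name="condition"
    )
    groups = {
        "strong": strong,
        "subthreshold": subthreshold,
        "confounders": confounders,
    }
    return expression, design, groups


PRESETS: dict[str, dict] = {
    "small": dict(n_genes=500, module_size=40, k_deg=50, k_np=50, deg_rank_offset=0),
    "default": dict(n_genes=2000, module_size=100, k_deg=50, k_np=50, deg_rank_offset=0),
    # ten-times-looser positive selection, admitting the planted confounders
    "inflated_fp": dict(n_genes=2000, module_size=100, k_deg=500, k_np=500,
                        deg_rank_offset=0, relax_deg_filter=True),
    # take DEG ranks 51-100 instead of the top 50
    "secondary_top": dict(n_genes=2000, module_size=100, k_deg=50, k_np=50,
                          deg_rank_offset=50),
}

_GENERATOR_DEFAULTS = dict(
    p_in=0.12,
    p_out=0.003,
    background_degree=8.0,
    n_wt=10,
    n_ko=10,
    effect_lfc=2.0,
    noise_sd=0.5,
    dropout=0.0,
    strong_fraction=0.6,
    confounder_fraction=0.02,
)


def make_benchmark(preset: str = "default", seed: int = 0) -> SyntheticInstance:
    """Generate a full benchmark instance for a named preset.

    The preset fixes the network size and the downstream positive-selection
    parameters (k_deg, k_np, and for ``secondary_top`` the DEG rank offset;
    ``inflated_fp`` additionally disables the strict DEG filter so the
    unfiltered ranking is used, mirroring a ten-times-looser cutoff).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = dict(_GENERATOR_DEFAULTS)
    params.update(PRESETS[preset])
    params["preset"] = preset
    network, ko, truth = simulate_network(
        n_genes=params["n_genes"],
        module_size=params["module_size"],
        p_in=params["p_in"],
        p_out=params["p_out"],
        background_degree=params["background_degree"],
        seed=seed,
    )
    expression, design, groups = simulate_expression(
        network,
        ko,
        sorted(truth),
        n_wt=params["n_wt"],
        n_ko=params["n_ko"],
        effect_lfc=params["effect_lfc"],
        noise_sd=params["noise_sd"],
        dropout=params["dropout"],
        strong_fraction=params["strong_fraction"],
        confounder_fraction=params["confounder_fraction"],
        seed=seed + 1,
    )
    return SyntheticInstance(
        network=network,
        ko_gene=ko,
        truth=frozenset(truth),
        strong_truth=groups["strong"],
        subthreshold_truth=groups["subthreshold"],
        confounders=groups["confounders"],
        expression=expression,
        design=design,
        params=params,
        seed=seed,
    )
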