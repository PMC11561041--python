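"""Positive-unlabeled learning on the gene network (GRAB-style).

The gene interaction network is treated as a pairwise Markov network over
binary labels (phenotype-related / not).  Each outer iteration alternates:

* a *marginalization step*: loopy belief propagation (sum-product) under
  node potentials built from the current class-prior estimate, with
  labeled positives clamped, yielding per-gene beliefs b_j — approximate
  marginal probabilities of being positive;
* an *update step*: a graph attention classifier is trained on a soft-label
  negative log likelihood, (1/|R|) Σ_{i∈R} l(ȳ_i, ŷ_i) +
  (1/|U|) Σ_{j∈U} l(b_j, ŷ_j), after which the class prior is re-estimated
  as the fraction of unlabeled genes the classifier calls positive,
  π̂p' = (1/|U|) Σ_{j∈U} 1[ŷ_j(+) > 0.5].

The prior starts at 0 (all unlabeled genes presumed negative) and the loop
stops when it settles.  The final ranking orders all genes by the
classifier's positive-class probability.

Class order convention: index 0 = positive, index 1 = negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gat import EdgeIndex, GraphAttentionClassifier
from .network_io import GeneNetwork, RankedGeneList
from .positive_selection import PositiveGeneSet

logger = logging.getLogger(__name__)

POSITIVE_CLAMP = 1e-6   # labeled positives get node potential (1-δ, δ)
PRIOR_FLOOR = 1e-12     # keeps a π̂p = 0 node potential strictly positive


# ---------------------------------------------------------------------------
# Instances and potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PUInstance:
    """A PU problem: network, labeled positives R, unlabeled U, features X.

    ``features`` is an (n_genes, n_features) array aligned with
    ``network.genes``; feature_names describe its columns.
    """

    network: GeneNetwork
    positives: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        gene_set = set(self.network.genes)
        if not set(self.positives) <= gene_set:
            raise ValueError("positives must be network genes")
        if len(set(self.positives)) != len(self.positives):
            raise ValueError("duplicate positives")
        if self.features.shape[0] != self.network.n_genes:
            raise ValueError("features not aligned with network genes")

    @property
    def unlabeled(self) -> tuple[str, ...]:
        pos = set(self.positives)
        return tuple(g for g in self.network.genes if g not in pos)

    def positive_mask(self) -> np.ndarray:
        idx = self.network.gene_index
        mask = np.zeros(self.network.n_genes, dtype=bool)
        mask[[idx[g] for g in self.positives]] = True
        return mask

    @classmethod
    def from_positive_set(
        cls,
        network: GeneNetwork,
        positives: PositiveGeneSet | Iterable[str],
        features: np.ndarray,
        feature_names: Sequence[str] = (),
    ) -> "PUInstance":
        genes = tuple(positives.genes if isinstance(positives, PositiveGeneSet) else positives)
        genes = tuple(g for g in genes if g in network)
        return cls(
            network=network,
            positives=genes,
            features=features,
            feature_names=tuple(feature_names),
        )


@dataclass(frozen=True)
class Potentials:
    """Node potentials (n, 2) on the simplex plus a global edge potential.

    The edge potential is the homophily matrix [[h, 1-h], [1-h, h]] with
    h in (0.5, 1): neighbouring genes prefer to share a label.

    ``observed`` flags nodes whose label is evidence (the clamped labeled
    positives): their outgoing messages are determined by their own
    potential alone, not by incoming messages.  Without this, a soft clamp
    is overwhelmed on high-degree nodes — at homophily h a node with d
    negative-leaning neighbours accumulates a (h/(1-h))^d pull that dwarfs
    any fixed clamp ratio, so labeled positives would start voting
    negative.  (With an exact one-hot potential the incoming product
    cancels out of the message anyway; this reproduces that behaviour
    while keeping potentials strictly positive.)
    """

    node: np.ndarray
    homophily: float
    observed: np.ndarray | None = None

    @property
    def edge_matrix(self) -> np.ndarray:
        h = self.homophily
        return np.array([[h, 1.0 - h], [1.0 - h, h]])


def init_potentials(
    instance: PUInstance, prior: float, h: float = 0.9
) -> Potentials:
    """Node potentials from the current prior; labeled positives clamped.

    Unlabeled genes get (π̂p, 1-π̂p) floored at PRIOR_FLOOR so that the
    initial π̂p = 0 (all-unlabeled-negative assumption) stays numerically
    defined; positives get (1-1e-6, 1e-6).
    """
    if not (0.5 < h < 1.0):
        raise ValueError("homophily must be in (0.5, 1)")
    if not (0.0 <= prior <= 1.0):
        raise ValueError("prior must be in [0, 1]")
    p = min(max(prior, PRIOR_FLOOR), 1.0 - PRIOR_FLOOR)
    n = instance.network.n_genes
    node = np.tile([p, 1.0 - p], (n, 1))
    mask = instance.positive_mask()
    node[mask] = [1.0 - POSITIVE_CLAMP, POSITIVE_CLAMP]
    return Potentials(node=node, homophily=h, observed=mask)


# ---------------------------------------------------------------------------
# Loopy belief propagation (marginalization step)
# ---------------------------------------------------------------------------

def _directed_edges(network: GeneNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed edge arrays (src, dst) with the reverse-edge index (cached)."""
    cached = network.__dict__.get("_directed_edges")
    if cached is not None:
        return cached
    idx = network.gene_index
    m = network.n_edges
    src = np.empty(2 * m, dtype=np.int64)
    dst = np.empty(2 * m, dtype=np.int64)
    for e, (a, b) in enumerate(network.edges):
        ia, ib = idx[a], idx[b]
        src[e], dst[e] = ia, ib
        src[m + e], dst[m + e] = ib, ia
    rev = np.concatenate([np.arange(m, 2 * m), np.arange(0, m)])
    network.__dict__["_directed_edges"] = (src, dst, rev)
    return src, dst, rev


def lbp_marginalize(
    instance: PUInstance | GeneNetwork,
    potentials: Potentials,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Sum-product loopy belief propagation; returns beliefs (n, 2).

    Messages are initialized uniform, updated synchronously in log space
    with damping applied on the normalized probabilities, and iterated
    until the largest absolute message change drops below ``tol``.
    Reaching ``max_iter`` logs a warning rather than failing: on cyclic
    graphs LBP carries no exactness guarantee anyway.  On trees the
    beliefs are the exact marginals.
    """
    network = instance.network if isinstance(instance, PUInstance) else instance
    if not (0.0 <= damping < 1.0):
        raise ValueError("damping must be in [0, 1)")
    n = network.n_genes
    node = np.asarray(potentials.node, float)
    if node.shape != (n, 2):
        raise ValueError("node potentials not aligned with network genes")
    log_phi = np.log(np.clip(node, 1e-300, None))
    log_psi = np.log(potentials.edge_matrix)

    observed = potentials.observed
    if observed is not None:
        observed = np.asarray(observed, bool)

    src, dst, rev = _directed_edges(network)
    n_dir = src.size
    if n_dir == 0:
        beliefs = node / node.sum(axis=1, keepdims=True)
        return beliefs

    msgs = np.full((n_dir, 2), 0.5)
    converged = False
    for _ in range(max_iter):
        log_m = np.log(msgs)
        incoming = np.zeros((n, 2))
        np.add.at(incoming, dst, log_m)
        # product of messages into src, excluding the reverse edge dst->src;
        # observed senders use their own potential only (evidence nodes)
        excl = log_phi[src] + incoming[src] - log_m[rev]
        if observed is not None and observed.any():
            obs_edge = observed[src]
            excl[obs_edge] = log_phi[src[obs_edge]]
        # logsumexp over the sender's label y_i for each receiver label y_j
        cand = excl[:, :, None] + log_psi[None, :, :]   # (edges, y_i, y_j)
        mx = cand.max(axis=1)
        new_log = mx + np.log(np.exp(cand - mx[:, None, :]).sum(axis=1))
        new = np.exp(new_log - new_log.max(axis=1, keepdims=True))
        new /= new.sum(axis=1, keepdims=True)
        updated = (1.0 - damping) * new + damping * msgs
        delta = np.abs(updated - msgs).max()
        msgs = updated
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("LBP reached max_iter=%d (last delta %.3e)", max_iter, delta)

    log_m = np.log(msgs)
    incoming = np.zeros((n, 2))
    np.add.at(incoming, dst, log_m)
    log_b = log_phi + incoming
    log_b -= log_b.max(axis=1, keepdims=True)
    beliefs = np.exp(log_b)
    beliefs /= beliefs.sum(axis=1, keepdims=True)
    return beliefs


# ---------------------------------------------------------------------------
# Update step
# ---------------------------------------------------------------------------

def make_soft_targets(instance: PUInstance, beliefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Targets and per-gene loss weights for the soft-label objective.

    Labeled positives contribute one-hot targets weighted 1/|R|; unlabeled
    genes contribute their belief vectors weighted 1/|U|.
    """
    n = instance.network.n_genes
    mask = instance.positive_mask()
    n_pos = int(mask.sum())
    n_unl = n - n_pos
    if n_pos == 0 or n_unl == 0:
        raise ValueError("need both labeled positives and unlabeled genes")
    targets = np.asarray(beliefs, float).copy()
    targets[mask] = [1.0, 0.0]
    weights = np.where(mask, 1.0 / n_pos, 1.0 / n_unl)
    return targets, weights


def train_classifier(
    instance: PUInstance,
    beliefs: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 0.01,
    seed: int = 0,
    classifier: GraphAttentionClassifier | None = None,
    hidden: int = 16,
    heads: int = 4,
) -> tuple[np.ndarray, GraphAttentionClassifier]:
    """Train (or continue training) the GAT on the soft-label objective.

    Returns per-gene probability 2-vectors (positive, negative) and the
    classifier, which callers may pass back in to warm-start the next
    outer iteration.
    """
    X = instance.features
    network = instance.network
    ei = network.__dict__.get("_edge_index")
    if ei is None:
        src, dst, _ = _directed_edges(network)
        # self-loops so every gene attends to itself
        ei = EdgeIndex.with_self_loops(src, dst, network.n_genes)
        network.__dict__["_edge_index"] = ei
    if classifier is None:
        classifier = GraphAttentionClassifier(
            n_features=X.shape[1],
            hidden=hidden,
            heads=heads,
            learning_rate=learning_rate,
            seed=seed,
        )
    targets, weights = make_soft_targets(instance, beliefs)
    probs = classifier.fit_epochs(X, ei, targets, weights, epochs=epochs)
    return probs, classifier


def update_prior(positive_probs: np.ndarray | Mapping[str, float], unlabeled_mask: np.ndarray | None = None) -> float:
    """π̂p' = fraction of unlabeled genes with positive probability > 0.5."""
    if isinstance(positive_probs, Mapping):
        vals = np.array(list(positive_probs.values()), float)
    else:
        vals = np.asarray(positive_probs, float)
        if unlabeled_mask is not None:
            vals = vals[np.asarray(unlabeled_mask, bool)]
    if vals.size == 0:
        raise ValueError("no unlabeled genes to estimate the prior from")
    return float((vals > 0.5).mean())


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_NAMES = (
    "log1p_degree",
    "rwr_score",
    "rwr_rank_percentile",
    "abs_log2fc",
    "deg_significant",
)


def default_features(
    network: GeneNetwork,
    np_scores: Mapping[str, float],
    deg_table: pd.DataFrame | None = None,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-gene classifier features, standardized per column.

    Columns: log(1+degree); propagation score; propagation rank percentile
    (1 = best); |log2FC| from the DEG table (0 if the gene is absent or no
    table is given); and an indicator of passing the strict DEG cutoffs.
    """
    genes = network.genes
    n = len(genes)
    deg = network.degrees().astype(float)
    scores = np.array([np_scores.get(g, 0.0) for g in genes])
    order = np.argsort(np.argsort(-scores, kind="stable"), kind="stable")
    percentile = 1.0 - order / max(n - 1, 1)
    abs_lfc = np.zeros(n)
    sig = np.zeros(n)
    if deg_table is not None:
        lfc_map = dict(zip(deg_table["gene"], deg_table["log2FC"]))
        padj_map = dict(zip(deg_table["gene"], deg_table["padj"]))
        for i, g in enumerate(genes):
            if g in lfc_map:
                abs_lfc[i] = abs(lfc_map[g])
                sig[i] = float(
                    abs(lfc_map[g]) > lfc_threshold and padj_map[g] < padj_threshold
                )
    X = np.column_stack([np.log1p(deg), scores, percentile, abs_lfc, sig])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, DEFAULT_FEATURE_NAMES


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class PUGraphResults:
    """Fit results: the ranked gene list plus diagnostics.

    Attributes
    ----------
    ranking
        All network genes ordered by final positive-class probability
        (labeled positives included; evaluation excludes them separately).
    probabilities
        Gene → positive-class probability.
    beliefs
        Gene → final LBP belief of being positive.
    prior_history
        Sequence of π̂p values, starting at the initial 0.
    converged
        Whether the outer loop stopped on |Δπ̂p| < prior_tol.
    """

    model: "PUGraphModel"
    ranking: RankedGeneList
    probabilities: dict[str, float]
    beliefs: dict[str, float]
    prior_history: list[float]
    converged: bool
    n_outer: int

    @property
    def prior(self) -> float:
        return self.prior_history[-1]

    def summary(self) -> str:
        lines = [
            "PU learning on gene network — fit summary",
            "=" * 45,
            f"genes:             {self.model.instance.network.n_genes}",
            f"edges:             {self.model.instance.network.n_edges}",
            f"labeled positives: {len(self.model.instance.positives)}",
            f"homophily h:       {self.model.homophily}",
            f"outer iterations:  {self.n_outer} ({'converged' if self.converged else 'max reached'})",
            f"final prior π̂p:    {self.prior:.4f}",
            "",
            "top 10 genes (positive-class probability):",
        ]
        for g, s in list(zip(self.ranking.genes, self.ranking.scores))[:10]:
            tag = "R" if g in set(self.model.instance.positives) else "U"
            lines.append(f"  {g:<15s} {s:.4f}  [{tag}]")
        return "\n".join(lines)


@dataclass
class PUGraphModel:
    """GRAB-style PU learning model over a gene network.

    Parameters
    ----------
    instance
        The PU problem (network, labeled positives, features).
    homophily
        Edge-potential homophily h in (0.5, 1).
    outer_max, prior_tol
        Outer-loop budget and the convergence tolerance on |Δπ̂p|.
    lbp_damping, lbp_tol, lbp_max_iter
        Message-passing controls for the marginalization step.
    epochs, learning_rate, hidden, heads
        Classifier budget per outer iteration and architecture sizes; the
        classifier is warm-started across outer iterations.
    """

    instance: PUInstance
    homophily: float = 0.9
    outer_max: int = 20
    prior_tol: float = 1e-3
    lbp_damping: float = 0.5
    lbp_tol: float = 1e-6
    lbp_max_iter: int = 200
    epochs: int = 100
    learning_rate: float = 0.01
    hidden: int = 16
    heads: int = 4

    @classmethod
    def from_components(
        cls,
        network: GeneNetwork,
        positives: PositiveGeneSet | Iterable[str],
        np_scores: Mapping[str, float],
        deg_table: pd.DataFrame | None = None,
        **kwargs,
    ) -> "PUGraphModel":
        X, names = default_features(network, np_scores, deg_table)
        inst = PUInstance.from_positive_set(network, positives, X, names)
        return cls(instance=inst, **kwargs)

    def fit(self, seed: int = 0) -> PUGraphResults:
        """Alternate marginalization and update steps until the prior settles."""
        inst = self.instance
        prior = 0.0
        history = [prior]
        classifier: GraphAttentionClassifier | None = None
        converged = False
        probs = None
        n_outer = 0
        for _ in range(self.outer_max):
            n_outer += 1
            potentials = init_potentials(inst, prior, self.homophily)
            beliefs = lbp_marginalize(
                inst,
                potentials,
                damping=self.lbp_damping,
                tol=self.lbp_tol,
                max_iter=self.lbp_max_iter,
            )
            probs, classifier = train_classifier(
                inst,
                beliefs,
                epochs=self.epochs,
                learning_rate=self.learning_rate,
                seed=seed,
                classifier=classifier,
                hidden=self.hidden,
                heads=self.heads,
            )
            new_prior = update_prior(probs[:, 0], ~inst.positive_mask())
            history.append(new_prior)
            if abs(new_prior - prior) < self.prior_tol:
                prior = new_prior
                converged = True
                break
            prior = new_prior

        genes = inst.network.genes
        prob_map = {g: float(probs[i, 0]) for i, g in enumerate(genes)}
        belief_map = {g: float(beliefs[i, 0]) for i, g in enumerate(genes)}
        ranking = RankedGeneList.from_scores(prob_map)
        return PUGraphResults(
            model=self,
            ranking=ranking,
            probabilities=prob_map,
            beliefs=belief_map,
            prior_history=history,
            converged=converged,
            n_outer=n_outer,
        )


def grab_rank(
    instance: PUInstance,
    h: float = 0.9,
    outer_max: int = 20,
    prior_tol: float = 1e-3,
    seed: int = 0,
    **params,
) -> RankedGeneList:
    """Functional wrapper: fit a PUGraphModel and return the ranked list."""
    model = PUGraphModel(
        instance=instance, homophily=h, outer_max=outer_max, prior_tol=prior_tol, **params
    )
    return model.fit(seed=seed).ranking
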