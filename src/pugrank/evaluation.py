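"""Ranking evaluation with partial AUC (ROC_n) and the DIAMOnD baseline.

Partial AUC focuses on the head of a ranking: with n the number of
top-ranked negative (non-truth) genes to cover, R the number of
ground-truth phenotype-related genes, and R_i the number of truth genes
ranked strictly above the i-th highest-ranked negative,

    AUC_n = (1 / (n * R)) * sum_{i=1..n} R_i.

Because phenotype-related genes are a small fraction of the network, even
good rankings give small absolute AUC_n values; the metric is meant for
comparison between methods, not as an absolute quality score.  Input
positives are excluded from the ranking before scoring — the task is to
prioritize genes *not* already used as labeled positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import GeneNetwork, RankedGeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartialAUCResult:
    """AUC_n with its R_i trajectory.

    ``r_truth`` counts all ground-truth genes, including any absent from
    the ranking (those can never rank above a negative, which makes the
    score conservative under coverage loss).
    """

    n: int
    r_truth: int
    r_i: tuple[int, ...]
    auc_n: float

    def __post_init__(self) -> None:
        assert len(self.r_i) == self.n
        assert all(0 <= r <= self.r_truth for r in self.r_i)
        assert all(b >= a for a, b in zip(self.r_i, self.r_i[1:]))


def exclude_input_positives(
    ranking: RankedGeneList, input_positives: Iterable[str]
) -> RankedGeneList:
    """Drop input positives from a ranking, preserving the remaining order."""
    drop = set(input_positives)
    kept = [(g, s) for g, s in zip(ranking.genes, ranking.scores) if g not in drop]
    return RankedGeneList(
        genes=tuple(g for g, _ in kept), scores=tuple(s for _, s in kept)
    )


def partial_auc(
    ranking: RankedGeneList,
    truth: Iterable[str],
    n: int,
    count_missing_truth: bool = True,
) -> PartialAUCResult:
    """Partial AUC over the top-n negatives of a ranking.

    ``count_missing_truth`` keeps truth genes absent from the ranking in
    the denominator R (the default, conservative choice); set it False to
    score only against truth genes the ranking covers.
    """
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    r_total = len(truth) if count_missing_truth else len(truth & set(ranking.genes))
    if r_total == 0:
        raise ValueError("no truth gene is present in the ranking")
    r_i: list[int] = []
    truth_seen = 0
    for g in ranking.genes:
        if g in truth:
            truth_seen += 1
        else:
            r_i.append(truth_seen)
            if len(r_i) == n:
                break
    if len(r_i) < n:
        raise ValueError(
            f"ranking has only {len(r_i)} negatives, need n={n}"
        )
    auc = float(sum(r_i)) / (n * r_total)
    return PartialAUCResult(n=n, r_truth=r_total, r_i=tuple(r_i), auc_n=auc)


def random_auc_expectation(
    n: int, n_negatives: int, truth_coverage: float = 1.0
) -> float:
    """Expected AUC_n of a uniformly random ranking.

    For a random interleaving of the rankable truth genes among
    ``n_negatives`` negatives, each rankable truth gene sits above the
    i-th negative with probability i/(n_negatives + 1), so

        E[AUC_n] = truth_coverage * (n + 1) / (2 * (n_negatives + 1)),

    where ``truth_coverage`` is the fraction of the truth denominator R
    actually present in the ranking (truth genes excluded as input
    positives or missing from the list can never score, whatever the
    ranking order).
    """
    if n_negatives < n:
        raise ValueError("need at least n negatives")
    if not (0.0 <= truth_coverage <= 1.0):
        raise ValueError("truth_coverage must be in [0, 1]")
    return truth_coverage * (n + 1) / (2.0 * (n_negatives + 1))


# ---------------------------------------------------------------------------
# DIAMOnD baseline
# ---------------------------------------------------------------------------

def diamond_rank(network: GeneNetwork, seeds: Iterable[str], k: int) -> RankedGeneList:
    """DIAMOnD: iterative hypergeometric connectivity-significance ranking.

    At each step every non-seed gene is scored by the hypergeometric tail
    probability of having at least its observed number of links into the
    current seed set, given its degree and the network size; the most
    significant gene (ties: more seed links, then gene identifier) joins
    the seed set.  Genes are ranked by order of addition with score
    -log10(p) at addition.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = network.gene_index
    seeds = set(seeds)
    if not seeds <= set(network.genes):
        raise ValueError("seeds must be network genes")
    n = network.n_genes
    adj = network.adjacency()
    adj_bool = (adj > 0).astype(np.int64)
    degree = np.asarray(adj_bool.sum(axis=1)).ravel()

    in_seed = np.zeros(n, dtype=bool)
    in_seed[[idx[s] for s in seeds]] = True
    links = np.asarray(adj_bool[:, in_seed].sum(axis=1)).ravel()

    genes = np.array(network.genes, dtype=object)
    added: list[tuple[str, float]] = []
    for _ in range(k):
        cand = ~in_seed
        if not cand.any():
            logger.warning("network exhausted after %d additions", len(added))
            break
        s0 = int(in_seed.sum())
        # P(X >= links) for X ~ Hypergeom(N=n, K=s0, draws=degree)
        pvals = stats.hypergeom.sf(links[cand] - 1, n, s0, degree[cand])
        cand_idx = np.flatnonzero(cand)
        order = sorted(
            range(len(cand_idx)),
            key=lambda j: (pvals[j], -links[cand_idx[j]], genes[cand_idx[j]]),
        )
        best = cand_idx[order[0]]
        p_best = max(float(pvals[order[0]]), 1e-300)
        added.append((str(genes[best]), -np.log10(p_best)))
        in_seed[best] = True
        nb = adj_bool.indices[adj_bool.indptr[best] : adj_bool.indptr[best + 1]]
        links[nb] += 1
    if not added:
        raise ValueError("no candidate genes to rank")
    # order of addition defines the rank; scores may be non-monotone, so
    # attach strictly decreasing surrogate positions alongside the p-scores
    genes_out = tuple(g for g, _ in added)
    scores_out = tuple(float(len(added) - i) for i in range(len(added)))
    return RankedGeneList(genes=genes_out, scores=scores_out)


def rwr_rank(
    np_scores: Mapping[str, float], exclude: Iterable[str] = ()
) -> RankedGeneList:
    """Rank all genes by propagation score (the RWR baseline ranking)."""
    exclude = set(exclude)
    return RankedGeneList.from_scores(
        {g: s for g, s in np_scores.items() if g not in exclude}
    )


def evaluate_methods(
    rankings: Mapping[str, RankedGeneList],
    truth: Iterable[str],
    input_positives: Iterable[str],
    ns: Sequence[int] = (200, 300),
) -> pd.DataFrame:
    """Partial-AUC table (one row per method, one AUC_n column per n)."""
    truth = set(truth)
    input_positives = set(input_positives)
    rows = []
    for name, ranking in rankings.items():
        cleaned = exclude_input_positives(ranking, input_positives)
        row: dict[str, object] = {"method": name}
        for n in ns:
            row[f"AUC{n}"] = partial_auc(cleaned, truth, n).auc_n
        rows.append(row)
    return pd.DataFrame(rows)


def rank_sum_enrichment(
    ranking: RankedGeneList, group: Iterable[str]
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test that ``group`` ranks above the rest.

    Returns (statistic, p-value); small p means the group sits toward the
    top of the ranking.
    """
    group = set(group)
    ranks_in = [ranking.rank_of(g) for g in group if g in ranking]
    ranks_out = [
        r + 1 for r, g in enumerate(ranking.genes) if g not in group
    ]
    if not ranks_in or not ranks_out:
        raise ValueError("both groups must be non-empty within the ranking")
    stat, p = stats.ranksums(ranks_in, ranks_out, alternative="less")
    return float(stat), float(p)
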