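"""Cross-validation folds over the positive set and rank-list aggregation.

Robustness of the final gene list comes from running PU learning many times
with different subsets of the labeled positives (repeated k-fold splits)
and aggregating the resulting ranked lists.  The default aggregator is a
weighted distance-based scheme (DIBRA-style): lists closer to the current
aggregate get more voting weight, and the lower portion of the final
aggregate is pruned.  Borda and median-rank aggregation are alternatives.

Rank imputation convention shared by all aggregators: a gene absent from a
list of length m is treated as ranked m + 1 there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network_io import RankedGeneList
from .positive_selection import PositiveGeneSet


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Repeated k-fold splits of the positive set.

    ``subsets[r*folds + f]`` is the positive set minus held-out fold f of
    repeat r; ``held_out`` stores the matching fold.  Within one repeat the
    held-out folds partition the positives.
    """

    repeats: int
    folds: int
    subsets: tuple[tuple[str, ...], ...]
    held_out: tuple[tuple[str, ...], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.subsets)


def make_folds(
    positives: PositiveGeneSet | Sequence[str],
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Seeded repeated k-fold plan over the labeled positives."""
    genes = list(positives.genes if isinstance(positives, PositiveGeneSet) else positives)
    if len(genes) < folds:
        raise ValueError(f"need at least {folds} positives, got {len(genes)}")
    rng = np.random.default_rng(seed)
    subsets: list[tuple[str, ...]] = []
    held: list[tuple[str, ...]] = []
    for _ in range(repeats):
        perm = list(np.array(genes, dtype=object)[rng.permutation(len(genes))])
        fold_parts = [perm[f::folds] for f in range(folds)]
        for part in fold_parts:
            part_set = set(part)
            subsets.append(tuple(g for g in genes if g not in part_set))
            held.append(tuple(sorted(part)))
    return FoldPlan(
        repeats=repeats,
        folds=folds,
        subsets=tuple(subsets),
        held_out=tuple(held),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Aggregators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregatedRanking:
    """Final aggregate, per-input-list weights, and the pruned lower portion.

    ``ranking`` is the deliverable (pruned) list; ``full_ranking`` keeps
    the complete aggregate order.  Partial AUC over the top-n negatives is
    identical on both whenever the pruned list is deep enough, and the
    full order stays usable when it is not (e.g. very large positive sets
    on small networks).
    """

    ranking: RankedGeneList
    weights: tuple[float, ...]
    pruned: frozenset[str]
    full_ranking: RankedGeneList | None = None

    @property
    def full(self) -> RankedGeneList:
        return self.full_ranking if self.full_ranking is not None else self.ranking


def _rank_maps(lists: Sequence[RankedGeneList]) -> list[dict[str, int]]:
    return [{g: r + 1 for r, g in enumerate(lst.genes)} for lst in lists]


def borda_aggregate(
    lists: Sequence[RankedGeneList],
    weights: Sequence[float] | None = None,
) -> RankedGeneList:
    """Weighted linear Borda combination with per-list normalization.

    A gene at rank r in a list of length m scores (m - r)/(m - 1) from that
    list (1 for the top, 0 for the bottom; a singleton list contributes 1);
    genes absent from a list score 0 from it.  Scores are summed with the
    list weights and sorted descending, ties by gene identifier.
    """
    if not lists:
        raise ValueError("no rankings to aggregate")
    if any(len(lst) == 0 for lst in lists):
        raise ValueError("cannot aggregate an empty ranking")
    if weights is None:
        weights = [1.0] * len(lists)
    if len(weights) != len(lists):
        raise ValueError("one weight per list required")
    contribs: dict[str, list[float]] = {}
    for lst, w in zip(lists, weights):
        m = len(lst)
        for r, g in enumerate(lst.genes, start=1):
            contrib = 1.0 if m == 1 else (m - r) / (m - 1)
            contribs.setdefault(g, []).append(w * contrib)
    # fsum: exactly rounded, so scores do not depend on the voter order
    scores = {g: math.fsum(vals) for g, vals in contribs.items()}
    return RankedGeneList.from_scores(scores)


def median_rank_aggregate(lists: Sequence[RankedGeneList]) -> RankedGeneList:
    """Order genes by the median of their ranks (absent ⇒ rank m + 1).

    Median ties are broken by mean rank, then gene identifier.  The score
    attached to the output is the negated median rank.
    """
    if not lists:
        raise ValueError("no rankings to aggregate")
    if any(len(lst) == 0 for lst in lists):
        raise ValueError("cannot aggregate an empty ranking")
    maps = _rank_maps(lists)
    universe = sorted({g for lst in lists for g in lst.genes})
    rows = []
    for g in universe:
        ranks = sorted(m.get(g, len(lst) + 1) for m, lst in zip(maps, lists))
        mean = math.fsum(ranks) / len(ranks)  # fsum: voter-order invariant
        rows.append((float(np.median(ranks)), mean, g))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    return RankedGeneList(
        genes=tuple(g for _, _, g in rows),
        scores=tuple(-med for med, _, _ in rows),
    )


def footrule_distance(
    lst: RankedGeneList, aggregate: RankedGeneList, universe: Sequence[str]
) -> float:
    """Normalized Spearman footrule over the universe (absent ⇒ rank m + 1).

    The mean absolute rank difference is divided by its maximum attainable
    value for two orderings of N items, floor(N^2 / 2) / N, and clipped to 1.
    """
    n_u = len(universe)
    if n_u == 0:
        return 0.0
    rl = {g: r + 1 for r, g in enumerate(lst.genes)}
    ra = {g: r + 1 for r, g in enumerate(aggregate.genes)}
    ml, ma = len(lst), len(aggregate)
    total = sum(
        abs(rl.get(g, ml + 1) - ra.get(g, ma + 1)) for g in universe
    )
    max_total = (n_u * n_u) // 2
    if max_total == 0:
        return 0.0
    return min(total / max_total, 1.0)


def dibra_aggregate(
    lists: Sequence[RankedGeneList],
    max_rounds: int = 10,
    prune_keep_fraction: float = 0.5,
) -> AggregatedRanking:
    """Iterative distance-weighted Borda aggregation with tail pruning.

    Round 0 aggregates with unit weights; each subsequent round measures
    the normalized Spearman footrule distance d_l between every input list
    and the current aggregate, re-weights lists as w_l = 1/(1 + d_l), and
    re-aggregates.  Iteration stops when the aggregate order is unchanged
    or after ``max_rounds``.  Finally the genes below the top
    ceil(prune_keep_fraction * |union|) ranks are pruned (a pure suffix cut).
    """
    if not lists:
        raise ValueError("no rankings to aggregate")
    if not (0.0 < prune_keep_fraction <= 1.0):
        raise ValueError("prune_keep_fraction must be in (0, 1]")
    universe = sorted({g for lst in lists for g in lst.genes})
    aggregate = borda_aggregate(lists)
    weights = [1.0] * len(lists)
    for _ in range(max_rounds):
        dists = [footrule_distance(lst, aggregate, universe) for lst in lists]
        weights = [1.0 / (1.0 + d) for d in dists]
        new_aggregate = borda_aggregate(lists, weights)
        if new_aggregate.genes == aggregate.genes:
            aggregate = new_aggregate
            break
        aggregate = new_aggregate
    keep = int(np.ceil(prune_keep_fraction * len(universe)))
    kept = RankedGeneList(
        genes=aggregate.genes[:keep], scores=aggregate.scores[:keep]
    )
    pruned = frozenset(aggregate.genes[keep:])
    return AggregatedRanking(
        ranking=kept, weights=tuple(weights), pruned=pruned, full_ranking=aggregate
    )


AGGREGATORS: dict[str, Callable[..., object]] = {
    "dibra": dibra_aggregate,
    "borda": borda_aggregate,
    "median": median_rank_aggregate,
}


def aggregate_rankings(
    lists: Sequence[RankedGeneList],
    method: str = "dibra",
    **params,
) -> AggregatedRanking:
    """Dispatch to an aggregator; always returns an AggregatedRanking."""
    if method not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {method!r}; choose from {sorted(AGGREGATORS)}")
    if method == "dibra":
        return dibra_aggregate(lists, **params)
    ranking = AGGREGATORS[method](lists, **params)
    return AggregatedRanking(
        ranking=ranking,
        weights=tuple([1.0] * len(lists)),
        pruned=frozenset(),
        full_ranking=ranking,
    )


# ---------------------------------------------------------------------------
# Cross-validated PU runs
# ---------------------------------------------------------------------------

def derive_fold_seed(master_seed: int, repeat: int, fold: int) -> int:
    """Deterministic per-(repeat, fold) seed independent of execution order."""
    ss = np.random.SeedSequence([int(master_seed), int(repeat), int(fold)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cv_aggregate(
    instance,
    fold_plan: FoldPlan,
    aggregator: str = "dibra",
    master_seed: int = 0,
    aggregator_params: dict | None = None,
    **pu_params,
) -> tuple[AggregatedRanking, list[RankedGeneList]]:
    """Run PU learning once per fold subset and aggregate the rankings.

    ``instance`` is a full PUInstance; each run relabels its positives to
    the fold subset (the held-out fold joins the unlabeled genes).  Per-run
    seeds derive from the master seed and the (repeat, fold) index, so
    results do not depend on execution order.
    """
    from .pu_grab import PUInstance, grab_rank

    rankings: list[RankedGeneList] = []
    for i, subset in enumerate(fold_plan.subsets):
        repeat, fold = divmod(i, fold_plan.folds)
        sub_instance = PUInstance(
            network=instance.network,
            positives=tuple(subset),
            features=instance.features,
            feature_names=instance.feature_names,
        )
        seed = derive_fold_seed(master_seed, repeat, fold)
        rankings.append(grab_rank(sub_instance, seed=seed, **pu_params))
    agg = aggregate_rankings(rankings, method=aggregator, **(aggregator_params or {}))
    return agg, rankings
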