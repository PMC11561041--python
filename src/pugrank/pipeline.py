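"""End-to-end orchestration: positives → CV folds → PU runs → aggregation → AUC.

Two entry points:

* :func:`run_synthetic_benchmark` — in-memory benchmark on a generated
  instance, returning the evaluation table and diagnostics (used by the
  test suite and the acceptance script);
* :func:`run_pipeline` — file-based run driven by a :class:`RunConfig`,
  writing positives, per-fold rankings, the aggregate, and the evaluation
  table into an output directory.

All randomness flows from a single master seed; per-stage seeds are
derived deterministically so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import network_io, synthetic
from .evaluation import (
    evaluate_methods,
    exclude_input_positives,
    random_auc_expectation,
    rwr_rank,
)
from .network_io import GeneNetwork, RankedGeneList
from .positive_selection import (
    PositiveGeneSet,
    build_positive_set,
    filter_degs,
    rwr,
    top_k,
    wilcoxon_deg,
)
from .pu_grab import PUInstance, default_features
from .rank_aggregation import (
    aggregate_rankings,
    derive_fold_seed,
    make_folds,
    run_cv_aggregate,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully materialized pipeline configuration.

    Either ``preset`` (synthetic benchmark) or the input paths must be set.
    """

    outdir: str = "pugrank_run"
    seed: int = 0
    # inputs: synthetic preset, or files
    preset: str | None = None
    network: str | None = None
    deg_table: str | None = None
    expression: str | None = None
    design: str | None = None
    ko_gene: str | None = None
    truth: str | None = None
    # positive selection
    min_confidence: float = 0.7
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    k_deg: int = 50
    k_np: int = 50
    deg_rank_offset: int = 0
    relax_deg_filter: bool = False
    restart_prob: float = 0.5
    # PU learning
    homophily: float = 0.9
    outer_max: int = 20
    prior_tol: float = 1e-3
    epochs: int = 100
    learning_rate: float = 0.01
    hidden: int = 16
    heads: int = 4
    # cross-validation and aggregation
    repeats: int = 10
    folds: int = 5
    aggregator: str = "dibra"
    prune_keep_fraction: float = 0.5
    # evaluation
    ns: tuple[int, ...] = (200, 300)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ns" in data:
            data["ns"] = tuple(data["ns"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["ns"] = list(data["ns"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def select_positives(
    deg_table: pd.DataFrame,
    network: GeneNetwork,
    ko_gene: str,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    k_deg: int = 50,
    k_np: int = 50,
    deg_rank_offset: int = 0,
    relax_deg_filter: bool = False,
    restart_prob: float = 0.5,
) -> tuple[PositiveGeneSet, dict[str, float], tuple[str, ...]]:
    """DEG filtering + propagation → labeled positive set.

    ``deg_rank_offset`` skips that many top DEGs before taking ``k_deg``
    (secondary-top selection); ``relax_deg_filter`` ranks the unfiltered
    DEG table by adjusted p-value instead of applying the strict cutoffs.
    Returns (positives, propagation scores, DEG positives used).
    """
    if relax_deg_filter:
        ordered = deg_table.copy()
        ordered["_abs"] = ordered["log2FC"].abs()
        ordered = ordered.sort_values(
            ["padj", "_abs", "gene"], ascending=[True, False, True]
        ).drop(columns="_abs")
    else:
        ordered = filter_degs(deg_table, lfc_threshold, padj_threshold)
    ranked_genes = [g for g in ordered["gene"] if g != ko_gene and g in network]
    deg_top = top_k(ranked_genes[deg_rank_offset:], k=k_deg)
    positives, np_scores = build_positive_set(
        deg_top, network, ko_gene, k_np=k_np, restart_prob=restart_prob
    )
    return positives, np_scores, deg_top


def _rwr_cv_rankings(
    network: GeneNetwork,
    fold_plan,
    ko_gene: str,
    restart_prob: float,
) -> list[RankedGeneList]:
    """RWR baseline under the same CV protocol: one ranking per fold subset."""
    rankings = []
    for subset in fold_plan.subsets:
        seeds = ([ko_gene] if ko_gene in network else []) + list(subset)
        scores = rwr(network, seeds, restart_prob=restart_prob)
        rankings.append(rwr_rank(scores))
    return rankings


# ---------------------------------------------------------------------------
# Synthetic benchmark (in memory)
# ---------------------------------------------------------------------------

def run_synthetic_benchmark(
    preset: str = "default",
    seed: int = 0,
    repeats: int = 2,
    folds: int = 5,
    ns: Sequence[int] = (200, 300),
    aggregator: str = "dibra",
    include_rwr_baseline: bool = True,
    **pu_params,
) -> dict:
    """Full pipeline on a generated benchmark; returns results and diagnostics.

    Keys of the returned dict: ``instance``, ``positives``, ``aggregate``
    (pipeline AggregatedRanking), ``evaluation`` (partial-AUC table),
    ``auc`` (method → {n: AUC_n}), ``random_expectation`` ({n: E[AUC_n]}),
    ``rescue`` (held-out sub-threshold truth gene diagnostics).
    """
    inst = synthetic.make_benchmark(preset, seed)
    p = inst.params
    deg_table = wilcoxon_deg(inst.expression, inst.design)
    positives, np_scores, deg_top = select_positives(
        deg_table,
        inst.network,
        inst.ko_gene,
        k_deg=p["k_deg"],
        k_np=p["k_np"],
        deg_rank_offset=p.get("deg_rank_offset", 0),
        relax_deg_filter=p.get("relax_deg_filter", False),
    )
    features, names = default_features(inst.network, np_scores, deg_table)
    pu_instance = PUInstance.from_positive_set(
        inst.network, positives, features, names
    )
    fold_plan = make_folds(
        positives, repeats=repeats, folds=folds, seed=derive_fold_seed(seed, 0, 10_000)
    )
    aggregate, fold_rankings = run_cv_aggregate(
        pu_instance, fold_plan, aggregator=aggregator, master_seed=seed, **pu_params
    )

    input_positives = positives.as_set() | {inst.ko_gene}
    rankings = {"pugrank": aggregate.full}
    if include_rwr_baseline:
        rwr_lists = _rwr_cv_rankings(inst.network, fold_plan, inst.ko_gene, 0.5)
        rwr_agg = aggregate_rankings(rwr_lists, method=aggregator)
        rankings["rwr"] = rwr_agg.full

    evaluation = evaluate_methods(rankings, inst.truth, input_positives, ns=ns)
    auc = {
        row["method"]: {n: row[f"AUC{n}"] for n in ns}
        for _, row in evaluation.iterrows()
    }
    cleaned = exclude_input_positives(aggregate.full, input_positives)
    n_negatives = len([g for g in cleaned.genes if g not in inst.truth])
    coverage = len(inst.truth & set(cleaned.genes)) / len(inst.truth)
    expectation = {
        n: random_auc_expectation(n, n_negatives, truth_coverage=coverage)
        for n in ns
    }

    held_out_sub = sorted(inst.subthreshold_truth - input_positives)
    rescue = _rescue_diagnostics(cleaned, held_out_sub, inst.truth)
    return {
        "instance": inst,
        "deg_table": deg_table,
        "positives": positives,
        "deg_top": deg_top,
        "np_scores": np_scores,
        "fold_plan": fold_plan,
        "fold_rankings": fold_rankings,
        "aggregate": aggregate,
        "rankings": rankings,
        "evaluation": evaluation,
        "auc": auc,
        "random_expectation": expectation,
        "rescue": rescue,
    }


def _rescue_diagnostics(
    cleaned: RankedGeneList, held_out_sub: Sequence[str], truth
) -> dict:
    """Rank percentiles of held-out sub-threshold truth genes vs background.

    Genes pruned out of the aggregate are imputed at the bottom
    (percentile 1.0), which only works against the rescue claim.
    """
    total = len(cleaned) + 1
    truth = set(truth)
    in_pct = [
        (cleaned.rank_of(g) if g in cleaned else total) / total for g in held_out_sub
    ]
    out_pct = [
        (r + 1) / total for r, g in enumerate(cleaned.genes) if g not in truth
    ]
    return {
        "held_out_subthreshold": list(held_out_sub),
        "group_percentiles": in_pct,
        "background_percentiles": out_pct,
    }


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline per config, writing results to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: list[dict] = []
    current = {"name": "inputs"}

    def stage(name):
        current["name"] = name
        t0 = time.time()

        def done(**extra):
            log.append({"stage": name, "seconds": round(time.time() - t0, 3), **extra})

        return done

    try:
        done = stage("inputs")
        if config.preset is not None:
            inst = synthetic.make_benchmark(config.preset, config.seed)
            network, ko_gene, truth = inst.network, inst.ko_gene, set(inst.truth)
            deg_table = wilcoxon_deg(inst.expression, inst.design)
            network_io.write_edge_list(network, outdir / "network.tsv")
            network_io.write_gene_list(truth, outdir / "truth.txt")
            (outdir / "ko_gene.txt").write_text(ko_gene + "\n")
            network_io.write_deg_table(deg_table, outdir / "deg_table.tsv")
            params = inst.params
            k_deg, k_np = params["k_deg"], params["k_np"]
            deg_rank_offset = params.get("deg_rank_offset", 0)
            relax = params.get("relax_deg_filter", False)
        else:
            if not (config.network and config.ko_gene):
                raise ValueError("config needs a preset or network + ko_gene paths")
            network = network_io.load_edge_list(
                config.network, min_confidence=config.min_confidence
            )
            ko_gene = config.ko_gene
            truth = (
                network_io.load_gene_list(config.truth) if config.truth else set()
            )
            if config.deg_table:
                deg_table = network_io.load_deg_table(config.deg_table)
            elif config.expression and config.design:
                expr = pd.read_csv(config.expression, sep="\t", index_col=0)
                design_df = pd.read_csv(config.design, sep="\t")
                design = pd.Series(
                    design_df["condition"].values, index=design_df["sample"]
                )
                deg_table = wilcoxon_deg(expr, design)
            else:
                raise ValueError("config needs deg_table or expression + design")
            k_deg, k_np = config.k_deg, config.k_np
            deg_rank_offset = config.deg_rank_offset
            relax = config.relax_deg_filter
        done(genes=network.n_genes, edges=network.n_edges)

        done = stage("select_positives")
        positives, np_scores, deg_top = select_positives(
            deg_table,
            network,
            ko_gene,
            lfc_threshold=config.lfc_threshold,
            padj_threshold=config.padj_threshold,
            k_deg=k_deg,
            k_np=k_np,
            deg_rank_offset=deg_rank_offset,
            relax_deg_filter=relax,
            restart_prob=config.restart_prob,
        )
        network_io.write_gene_list(positives.genes, outdir / "positives.txt")
        with open(outdir / "positives_provenance.tsv", "w") as fh:
            fh.write("gene\tprovenance\n")
            for g in positives.genes:
                fh.write(f"{g}\t{positives.provenance[g]}\n")
        done(n_positives=len(positives))

        done = stage("pu_cv")
        features, names = default_features(network, np_scores, deg_table)
        pu_instance = PUInstance.from_positive_set(network, positives, features, names)
        fold_plan = make_folds(
            positives,
            repeats=config.repeats,
            folds=config.folds,
            seed=derive_fold_seed(config.seed, 0, 10_000),
        )
        aggregate, fold_rankings = run_cv_aggregate(
            pu_instance,
            fold_plan,
            aggregator=config.aggregator,
            master_seed=config.seed,
            aggregator_params=(
                {"prune_keep_fraction": config.prune_keep_fraction}
                if config.aggregator == "dibra"
                else None
            ),
            h=config.homophily,
            outer_max=config.outer_max,
            prior_tol=config.prior_tol,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            hidden=config.hidden,
            heads=config.heads,
        )
        folds_dir = outdir / "fold_rankings"
        folds_dir.mkdir(exist_ok=True)
        for i, ranking in enumerate(fold_rankings):
            r, f = divmod(i, fold_plan.folds)
            network_io.write_ranking(ranking, folds_dir / f"repeat{r}_fold{f}.tsv")
        network_io.write_ranking(aggregate.ranking, outdir / "aggregate.tsv")
        done(n_runs=len(fold_rankings))

        done = stage("evaluate")
        input_positives = positives.as_set() | {ko_gene}
        if truth:
            evaluation = evaluate_methods(
                {"pugrank": aggregate.full}, truth, input_positives, ns=config.ns
            )
            evaluation.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
            done(**{f"AUC{n}": float(evaluation.iloc[0][f"AUC{n}"]) for n in config.ns})
        else:
            done(skipped="no truth list provided")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {current['name']!r}: {exc}"
        ) from exc
    finally:
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
    return outdir
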