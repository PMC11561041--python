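"""Selection of labeled positive genes from DEG analysis and network propagation.

The positive set that seeds PU learning is the union of (a) the top-k
differentially expressed genes under strict cutoffs (|log2FC| > 1,
padj < .05, ranked by ascending adjusted p-value) and (b) the top-k genes
by random-walk-with-restart propagation seeded with the KO gene plus those
DEGs.  Strict cutoffs keep false positives out of the labeled set; the
false negatives they create are what the PU stage later rescues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositiveGeneSet:
    """Labeled positives R with per-gene provenance in {DEG, NP, BOTH}.

    The KO gene itself is a seed, never a positive.
    """

    genes: tuple[str, ...]
    provenance: dict[str, str]
    ko_gene: str

    def __post_init__(self) -> None:
        if self.ko_gene in self.genes:
            raise ValueError("KO gene cannot be a positive")
        if set(self.genes) != set(self.provenance):
            raise ValueError("provenance keys must match genes")
        bad = {t for t in self.provenance.values()} - {"DEG", "NP", "BOTH"}
        if bad:
            raise ValueError(f"unknown provenance tags: {bad}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)

    def restrict_to(self, universe: Iterable[str]) -> "PositiveGeneSet":
        universe = set(universe)
        kept = tuple(g for g in self.genes if g in universe)
        dropped = len(self.genes) - len(kept)
        if dropped:
            logger.warning("dropped %d positives outside the universe", dropped)
        return PositiveGeneSet(
            genes=kept,
            provenance={g: self.provenance[g] for g in kept},
            ko_gene=self.ko_gene,
        )

    def subset(self, keep: Iterable[str]) -> "PositiveGeneSet":
        keep = set(keep)
        kept = tuple(g for g in self.genes if g in keep)
        return PositiveGeneSet(
            genes=kept,
            provenance={g: self.provenance[g] for g in kept},
            ko_gene=self.ko_gene,
        )


# ---------------------------------------------------------------------------
# DEG filtering
# ---------------------------------------------------------------------------

def filter_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Strict DEG filter: |log2FC| > lfc_threshold AND padj < padj_threshold.

    Result is sorted by ascending adjusted p-value; padj ties are broken by
    descending |log2FC| (prefer stronger effects), then by gene id, so the
    order is deterministic.
    """
    mask = (table["log2FC"].abs() > lfc_threshold) & (table["padj"] < padj_threshold)
    kept = table.loc[mask].copy()
    kept["_abs_lfc"] = kept["log2FC"].abs()
    kept = kept.sort_values(
        ["padj", "_abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return kept.reset_index(drop=True)


def top_k(
    ordered: Sequence[str] | pd.DataFrame | Mapping[str, float],
    k: int = 50,
    exclude: Iterable[str] = (),
) -> tuple[str, ...]:
    """First ``k`` genes of an ordered input, skipping ``exclude``.

    Accepts an already-sorted DEG table (uses its ``gene`` column), a score
    mapping (sorted descending, ties by gene id), or any ordered sequence.
    Returns fewer than ``k`` genes if the input is exhausted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if isinstance(ordered, pd.DataFrame):
        genes: Sequence[str] = list(ordered["gene"])
    elif isinstance(ordered, Mapping):
        genes = [g for g, _ in sorted(ordered.items(), key=lambda kv: (-kv[1], kv[0]))]
    else:
        genes = list(ordered)
    exclude = set(exclude)
    out: list[str] = []
    for g in genes:
        if g in exclude:
            continue
        out.append(g)
        if len(out) == k:
            break
    return tuple(out)


# ---------------------------------------------------------------------------
# Random walk with restart
# ---------------------------------------------------------------------------

def rwr(
    network: GeneNetwork,
    seeds: Iterable[str],
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    weighted: bool = True,
) -> dict[str, float]:
    """Random walk with restart over the confidence-weighted network.

    Iterates ``p <- r*p0 + (1-r)*W p`` to a fixed point, where ``p0`` is
    uniform over the retained seeds and ``W`` is the column-normalized
    (by weighted degree) adjacency, i.e. ``W[i, j]`` is the probability of
    stepping from gene j to gene i.  The result is a probability vector
    over all network genes.

    Seeds absent from the network are dropped with a warning; if none
    remain, this is an error.
    """
    if not (0.0 < restart_prob <= 1.0):
        raise ValueError("restart_prob must be in (0, 1]")
    idx = network.gene_index
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in idx]
    if len(present) < len(seeds):
        logger.warning(
            "dropped %d seed(s) absent from the network", len(seeds) - len(present)
        )
    if not present:
        raise ValueError("no seed gene is present in the network")

    n = network.n_genes
    adj = network.adjacency().astype(float)
    if not weighted:
        adj = (adj > 0).astype(float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0  # isolated genes hold their mass
    w = adj.multiply(1.0 / col_sums).tocsr()  # column-stochastic: j -> i

    p0 = np.zeros(n)
    p0[[idx[s] for s in present]] = 1.0 / len(present)
    p = p0.copy()
    r = restart_prob
    for _ in range(max_iter):
        p_next = r * p0 + (1.0 - r) * (w @ p)
        if np.abs(p_next - p).sum() < tol:
            p = p_next
            break
        p = p_next
    else:
        residual = float(np.abs(r * p0 + (1.0 - r) * (w @ p) - p).sum())
        raise RuntimeError(
            f"RWR did not converge in {max_iter} iterations (L1 residual {residual:.3e})"
        )
    p = np.maximum(p, 0.0)
    p /= p.sum()
    return {g: float(p[i]) for g, i in idx.items()}


# ---------------------------------------------------------------------------
# Positive-set assembly
# ---------------------------------------------------------------------------

def build_positive_set(
    deg_top: Sequence[str],
    network: GeneNetwork,
    ko_gene: str,
    k_np: int = 50,
    restart_prob: float = 0.5,
    rwr_tol: float = 1e-10,
    weighted: bool = True,
) -> tuple[PositiveGeneSet, dict[str, float]]:
    """Union of DEG positives and propagation positives, with provenance.

    ``deg_top`` is the ordered top-k DEG selection (already restricted to
    network genes; absentees are dropped with a warning).  The propagation
    seeds are the KO gene plus ``deg_top``; the propagation positives are
    the ``k_np`` best-scoring non-seed genes.  Returns the positive set and
    the propagation scores (reused downstream as classifier features).
    """
    deg_top = [g for g in dict.fromkeys(deg_top) if g != ko_gene]
    in_net = [g for g in deg_top if g in network]
    if len(in_net) < len(deg_top):
        logger.warning(
            "dropped %d DEG positives absent from the network",
            len(deg_top) - len(in_net),
        )
    seeds = [ko_gene] + in_net if ko_gene in network else list(in_net)
    np_scores = rwr(
        network, seeds, restart_prob=restart_prob, tol=rwr_tol, weighted=weighted
    )
    np_top = top_k(np_scores, k=k_np, exclude=set(seeds) | {ko_gene})
    provenance: dict[str, str] = {g: "DEG" for g in in_net}
    for g in np_top:
        provenance[g] = "BOTH" if g in provenance else "NP"
    genes = tuple(in_net) + tuple(g for g in np_top if g not in set(in_net))
    return (
        PositiveGeneSet(genes=genes, provenance=provenance, ko_gene=ko_gene),
        np_scores,
    )


# ---------------------------------------------------------------------------
# Minimal Wilcoxon DEG routine (for synthetic fixtures)
# ---------------------------------------------------------------------------

def wilcoxon_deg(
    expression: pd.DataFrame,
    design: pd.Series | Mapping[str, str],
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DEG test between WT and KO samples.

    ``expression`` is genes × samples (non-negative); ``design`` maps sample
    name to condition in {WT, KO}.  log2FC = log2((mean_KO + c) / (mean_WT + c))
    with pseudo-count ``c``; adjusted p-values are Benjamini–Hochberg.

    This is a minimal stand-in so synthetic fixtures can exercise the full
    path; it does not attempt to replicate scRNA/bulk DEG pipelines.
    """
    design = pd.Series(dict(design) if not isinstance(design, pd.Series) else design)
    wt_samples = design.index[design == "WT"]
    ko_samples = design.index[design == "KO"]
    if len(wt_samples) < 2 or len(ko_samples) < 2:
        raise ValueError("need at least 2 samples per condition")
    wt = expression.loc[:, wt_samples].to_numpy(float)
    ko = expression.loc[:, ko_samples].to_numpy(float)
    if (wt < 0).any() or (ko < 0).any():
        raise ValueError("expression values must be non-negative")

    res = stats.ranksums(ko, wt, axis=1)
    pvals = np.asarray(res.pvalue, float)
    c = pseudo_count
    log2fc = np.log2((ko.mean(axis=1) + c) / (wt.mean(axis=1) + c))
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "gene": expression.index.astype(str),
            "log2FC": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    )
    return out.reset_index(drop=True)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
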