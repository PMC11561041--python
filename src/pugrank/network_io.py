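"""Readers/writers for gene networks, gene lists, DEG tables and rankings.

The central container is :class:`GeneNetwork`, an undirected weighted graph
of genes (the pairwise Markov network the PU-learning stage operates on).
Edge confidences are kept on a [0, 1] scale; STRING-style 0–1000 integer
scores are rescaled automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected weighted gene network.

    Parameters
    ----------
    genes
        Sorted tuple of gene identifiers (opaque strings).
    edges
        Mapping from unordered gene pair (stored as a sorted 2-tuple) to a
        confidence in [0, 1].  No self-loops; every endpoint is in ``genes``.
    """

    genes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(hash=False)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for (a, b), c in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)} not stored in sorted order")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge endpoint not in gene set: {(a, b)}")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"confidence {c} outside [0, 1] for edge {(a, b)}")

    # -- basic queries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_index

    @property
    def gene_index(self) -> dict[str, int]:
        """Gene → integer index (cached)."""
        idx = self.__dict__.get("_gene_index")
        if idx is None:
            idx = {g: i for i, g in enumerate(self.genes)}
            self.__dict__["_gene_index"] = idx
        return idx

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric confidence-weighted adjacency matrix (CSR, cached)."""
        adj = self.__dict__.get("_adjacency")
        if adj is None:
            idx = self.gene_index
            n = self.n_genes
            if self.n_edges:
                rows, cols, vals = [], [], []
                for (a, b), c in self.edges.items():
                    ia, ib = idx[a], idx[b]
                    rows += [ia, ib]
                    cols += [ib, ia]
                    vals += [c, c]
                adj = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
            else:
                adj = sparse.csr_matrix((n, n))
            self.__dict__["_adjacency"] = adj
        return adj

    def degrees(self) -> np.ndarray:
        """Unweighted degree per gene, aligned with ``genes``."""
        adj = self.adjacency()
        return np.asarray((adj > 0).sum(axis=1)).ravel()

    def neighbors(self, gene: str) -> list[str]:
        adj = self.adjacency()
        i = self.gene_index[gene]
        return [self.genes[j] for j in adj.indices[adj.indptr[i]:adj.indptr[i + 1]]]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b), c in self.edges.items():
            g.add_edge(a, b, confidence=c)
        return g

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], drop_isolated: bool = True
    ) -> "GeneNetwork":
        """Build a network from (gene1, gene2, confidence) triples.

        Self-loops are dropped; duplicate pairs (in either order) keep the
        maximum confidence; genes are the union of edge endpoints.
        """
        edge_map: dict[tuple[str, str], float] = {}
        for a, b, c in edges:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            prev = edge_map.get(key)
            if prev is None or c > prev:
                edge_map[key] = float(c)
        genes = sorted({g for pair in edge_map for g in pair})
        return cls(genes=tuple(genes), edges=edge_map)


@dataclass(frozen=True)
class RankedGeneList:
    """A strict total order over genes with scores; rank 1 is best.

    Scores are non-increasing with rank; score ties are broken by ascending
    gene identifier so the order is deterministic.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")
        for i in range(1, len(self.scores)):
            if self.scores[i] > self.scores[i - 1] + 1e-12:
                raise ValueError("scores must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.genes)

    def rank_of(self, gene: str) -> int:
        """1-based rank; raises KeyError for absent genes."""
        ranks = self.__dict__.get("_ranks")
        if ranks is None:
            ranks = {g: i + 1 for i, g in enumerate(self.genes)}
            self.__dict__["_ranks"] = ranks
        return ranks[gene]

    def __contains__(self, gene: str) -> bool:
        try:
            self.rank_of(gene)
            return True
        except KeyError:
            return False

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedGeneList":
        """Sort descending by score, ties broken by ascending gene id."""
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            genes=tuple(g for g, _ in items),
            scores=tuple(float(s) for _, s in items),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "gene": list(self.genes),
                "score": list(self.scores),
            }
        )


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def load_edge_list(path: str | Path, min_confidence: float = 0.7) -> GeneNetwork:
    """Load a STRING-style edge list and apply strict confidence filtering.

    The file is whitespace- or tab-delimited with 2 or 3 columns
    (gene1, gene2[, confidence]); a missing third column means confidence 1.
    Confidences given on the 0–1000 integer scale (any value > 1 in the
    file) are divided by 1000.  Edges with confidence ``<= min_confidence``
    are removed (strict "greater than" filter), self-loops dropped,
    duplicates resolved by maximum confidence, and genes left isolated
    after filtering are discarded so every retained gene participates in
    message passing.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    raw: list[tuple[str, str, float]] = []
    max_seen = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if lineno == 1 and len(parts) >= 2 and _looks_like_header(parts):
                continue
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    c = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: confidence {parts[2]!r} is not a number"
                    ) from exc
                if c < 0:
                    raise EdgeListParseError(f"line {lineno}: negative confidence {c}")
            else:
                c = 1.0
            max_seen = max(max_seen, c)
            raw.append((a, b, c))
    if max_seen > 1.0:  # 0–1000 STRING integer scale
        raw = [(a, b, c / 1000.0) for a, b, c in raw]
    raw = [(a, b, c) for a, b, c in raw if c > min_confidence]
    network = GeneNetwork.from_edges(raw)
    if network.n_genes == 0:
        raise ValueError(
            f"network is empty after filtering at confidence > {min_confidence}"
        )
    return network


def _looks_like_header(parts: Sequence[str]) -> bool:
    if len(parts) == 3:
        try:
            float(parts[2])
            return False
        except ValueError:
            return True
    lowered = {p.lower() for p in parts}
    return bool(lowered & {"gene1", "gene2", "protein1", "protein2", "source", "target"})


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write a 3-column TSV (gene1, gene2, confidence) that round-trips."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tcombined_score\n")
        for (a, b), c in sorted(network.edges.items()):
            fh.write(f"{a}\t{b}\t{c:.6g}\n")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def load_gene_list(path: str | Path) -> set[str]:
    """One identifier per line; '#' comments allowed; whitespace trimmed."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    if not genes:
        raise ValueError(f"gene list {path} contains no genes")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

DEG_COLUMNS = ("gene", "log2FC", "pvalue", "padj")


def load_deg_table(path: str | Path) -> pd.DataFrame:
    """TSV with header gene, log2FC, pvalue, padj; identifiers must be unique."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    table = table.loc[:, list(DEG_COLUMNS)].copy()
    table["gene"] = table["gene"].astype(str)
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in DEG table: {dupes[:5]}")
    return table


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(DEG_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

def write_ranking(ranking: RankedGeneList, path: str | Path) -> None:
    """TSV with columns rank, gene, score; round-trips via read_ranking."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\n")
        for i, (g, s) in enumerate(zip(ranking.genes, ranking.scores), start=1):
            fh.write(f"{i}\t{g}\t{s!r}\n")


def read_ranking(path: str | Path) -> RankedGeneList:
    genes: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["rank", "gene", "score"]:
            raise ValueError(f"unexpected ranking header: {header}")
        for line in fh:
            rank_s, gene, score_s = line.rstrip("\n").split("\t")
            genes.append(gene)
            scores.append(float(score_s))
    return RankedGeneList(genes=tuple(genes), scores=tuple(scores))


def ranking_from_frame(frame: pd.DataFrame) -> RankedGeneList:
    frame = frame.sort_values("rank")
    return RankedGeneList(
        genes=tuple(frame["gene"].astype(str)),
        scores=tuple(frame["score"].astype(float)),
    )
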