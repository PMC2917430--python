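"""Neighbor ranking of compendium genes by Pearson distance to a reference gene.

The Pearson distance between two expression profiles is ``1 - r`` with ``r``
their Pearson correlation, so it lives in [0, 2] and a low score means close
similarity of expression pattern.  :func:`rank_neighbors` scores every
non-reference gene of a (pre-filtered) compendium against the reference
profile and sorts ascending — the classical gene-neighbors operation.
Correlation is computed on raw filtered intensities by default, with a
``log2`` switch as the documented alternative.  Genes with constant profiles
have no defined correlation; they are excluded from the ranking and reported,
ties are broken lexicographically by gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .expression_io import ExpressionMatrix

__all__ = [
    "NeighborEntry",
    "NeighborRanking",
    "pearson_distance",
    "rank_neighbors",
    "select_top_k",
]


class NeighborEntry(NamedTuple):
    gene_id: str
    distance: float
    rank: int


@dataclass
class NeighborRanking:
    """All non-reference genes ordered by ascending Pearson distance."""

    reference_gene: str
    entries: list[NeighborEntry]
    excluded_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries):
            if e.rank != i + 1:
                raise ValueError("ranks must be 1..n with no gaps")
            if i and e.distance < self.entries[i - 1].distance:
                raise ValueError("distances must be non-decreasing with rank")
            if e.gene_id == self.reference_gene:
                raise ValueError("reference gene must not appear among entries")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def positions_of(self, gene_ids: Iterable[str]) -> list[int]:
        """Sorted 1-based ranks of the given genes; absent ids are ignored."""
        wanted = set(gene_ids)
        return sorted(e.rank for e in self.entries if e.gene_id in wanted)

    def to_rows(self) -> list[tuple[int, str, float]]:
        return [(e.rank, e.gene_id, e.distance) for e in self.entries]


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson distance ``1 - r`` between two profiles; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("profiles need >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant profile: Pearson correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def rank_neighbors(
    matrix: ExpressionMatrix,
    reference_gene: str,
    log2: bool = False,
) -> NeighborRanking:
    """Rank every other gene of the matrix by Pearson distance to the reference.

    Ties are broken by lexicographic gene id; constant-profile genes are
    excluded with a warning and listed in ``excluded_constant``.
    """
    if reference_gene not in matrix.gene_ids:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    vals = np.log2(np.maximum(matrix.values, 1e-12)) if log2 else matrix.values
    ref_i = matrix.gene_ids.index(reference_gene)
    ref = vals[ref_i]
    ref_c = ref - ref.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    if ref_norm == 0:
        raise ValueError(f"reference gene {reference_gene!r} has a constant profile")

    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    excluded = [
        matrix.gene_ids[i] for i in range(matrix.n_genes) if norms[i] == 0 and i != ref_i
    ]
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant-profile gene(s) excluded from the ranking"
        )
    scored: list[tuple[float, str]] = []
    for i in range(matrix.n_genes):
        if i == ref_i or norms[i] == 0:
            continue
        r = float(centered[i] @ ref_c / (norms[i] * ref_norm))
        scored.append((1.0 - r, matrix.gene_ids[i]))
    scored.sort(key=lambda t: (t[0], t[1]))
    entries = [NeighborEntry(g, d, rank + 1) for rank, (d, g) in enumerate(scored)]
    return NeighborRanking(
        reference_gene=reference_gene, entries=entries, excluded_constant=excluded
    )


def select_top_k(
    ranking: NeighborRanking,
    query: Iterable[str],
    k: int,
) -> list[tuple[str, float]]:
    """The ``k`` query genes closest to the reference, ascending by distance.

    ``query`` may be any iterable of gene ids (e.g. a signature's
    ``gene_ids``).  Raises when ``k`` exceeds the number of query genes
    present in the ranking, naming both counts.
    """
    ids = set(getattr(query, "gene_ids", query))
    hits = [(e.gene_id, e.distance) for e in ranking.entries if e.gene_id in ids]
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(hits):
        raise ValueError(
            f"k = {k} exceeds the {len(hits)} query genes present in the ranking"
        )
    return hits[:k]


def write_ranking_tsv(ranking: NeighborRanking, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# reference={ranking.reference_gene}\n")
        fh.write("rank\tgene_id\tdistance\n")
        for rank, gene, dist in ranking.to_rows():
            fh.write(f"{rank}\t{gene}\t{dist:.10g}\n")


def read_ranking_tsv(path) -> NeighborRanking:
    reference = None
    entries: list[NeighborEntry] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# reference="):
                reference = line.split("=", 1)[1]
                continue
            if line.startswith("rank"):
                continue
            rank_s, gene, dist_s = line.split("\t")
            entries.append(NeighborEntry(gene, float(dist_s), int(rank_s)))
    if reference is None:
        raise ValueError(f"{path}: missing '# reference=' header")
    return NeighborRanking(reference_gene=reference, entries=entries)
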