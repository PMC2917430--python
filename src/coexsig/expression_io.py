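"""Expression-matrix containers, GCT/CLS I/O, filtering rules and gene-id mapping.

The pipeline's universal currency is a genes x samples intensity matrix on the
positive "relative units" scale produced by array preprocessing.  This module
provides:

* :class:`ExpressionMatrix` / :class:`ClassLabels` — validated containers;
* GCT v1.2 and CLS readers/writers (the GenePattern-ecosystem formats);
* :func:`variation_filter` — the informative-gene rule for the two-condition
  cell-line experiment (log2 interquartile range > 0.5 and at least one sample
  above 100 relative units);
* :func:`compendium_filter` — the compendium rules (drop genes that are too
  low/too high in a majority of arrays, or nearly flat across all arrays);
* :func:`map_gene_ids` — case-insensitive symbol mapping of a signature onto a
  target matrix, with collapse policies for multi-probe symbols.

Both filters preserve input gene order and report every removal with the rule
that triggered it; ``n_in == n_kept + len(removed)`` always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClassLabels",
    "FilterReport",
    "GeneIdMapping",
    "GctParseError",
    "ClsParseError",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "variation_filter",
    "compendium_filter",
    "map_gene_ids",
    "write_filter_report",
]


class GctParseError(ValueError):
    """Malformed GCT file; the message names the offending line."""


class ClsParseError(ValueError):
    """Malformed CLS file."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples intensity matrix with unique, ordered identifiers.

    Parameters
    ----------
    gene_ids
        Row identifiers (gene symbols or probe accessions), unique.
    sample_ids
        Column identifiers, unique.
    values
        Float array of shape ``(len(gene_ids), len(sample_ids))``; all entries
        must be finite.
    descriptions
        Optional per-gene free-text annotations (the GCT ``Description``
        column); defaults to ``"na"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    descriptions: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.descriptions is None:
            self.descriptions = ["na"] * len(self.gene_ids)
        elif len(self.descriptions) != len(self.gene_ids):
            raise ValueError("descriptions length does not match gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, descriptions: list[str] | None = None) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            descriptions=descriptions,
        )

    def row(self, gene_id: str) -> np.ndarray:
        """Return one gene's profile as a 1-D array."""
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or integer index array, order-preserving."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            descriptions=[self.descriptions[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ClassLabels:
    """One categorical label per sample, ordered like the paired matrix."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)

    def mask(self, label: str) -> np.ndarray:
        return np.array([l == label for l in self.labels], dtype=bool)

    def check_paired(self, matrix: ExpressionMatrix) -> None:
        if self.sample_ids != matrix.sample_ids:
            raise ValueError("class labels are not aligned with matrix samples")


@dataclass
class FilterReport:
    """Bookkeeping for a filtering pass: every input gene is kept or tagged."""

    n_in: int
    n_kept: int
    removed: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + len(self.removed):
            raise ValueError("filter report does not conserve gene counts")

    def removed_ids(self) -> list[str]:
        return [g for g, _ in self.removed]


# ---------------------------------------------------------------------------
# GCT v1.2
# ---------------------------------------------------------------------------


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.2 file.

    The format is: a ``#1.2`` version line; a ``<n_genes>\\t<n_samples>``
    dimension line; a header row ``Name\\tDescription\\t<sample ids...>``; then
    one row per gene.  Any structural violation raises :class:`GctParseError`
    naming the offending line (1-based).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise GctParseError(f"{path}: line 1: expected version line '#1.2'")
    if len(lines) < 3:
        raise GctParseError(f"{path}: truncated file (fewer than 3 lines)")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise GctParseError(
            f"{path}: line 2: expected '<n_genes>\\t<n_samples>', got {lines[1]!r}"
        ) from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise GctParseError(f"{path}: line 3: header must start with 'Name\\tDescription'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise GctParseError(
            f"{path}: line 3: header lists {len(sample_ids)} samples, "
            f"line 2 declares {n_samples}"
        )
    body = [l for l in lines[3:] if l.strip() != ""]
    if len(body) != n_genes:
        raise GctParseError(
            f"{path}: file contains {len(body)} data rows, line 2 declares {n_genes}"
        )
    gene_ids: list[str] = []
    descriptions: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    seen: set[str] = set()
    for i, line in enumerate(body):
        lineno = i + 4
        fields = line.split("\t")
        if len(fields) != n_samples + 2:
            raise GctParseError(
                f"{path}: line {lineno}: expected {n_samples + 2} columns, got {len(fields)}"
            )
        name = fields[0]
        if name in seen:
            raise GctParseError(f"{path}: line {lineno}: duplicate gene id {name!r}")
        seen.add(name)
        gene_ids.append(name)
        descriptions.append(fields[1])
        try:
            values[i] = [float(x) for x in fields[2:]]
        except ValueError as exc:
            raise GctParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(gene_ids, sample_ids, values, descriptions)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a GCT v1.2 file at full float precision (lossless round-trip)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, desc, row in zip(matrix.gene_ids, matrix.descriptions, matrix.values):
            fh.write(g + "\t" + desc + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# CLS
# ---------------------------------------------------------------------------


def read_cls(path, sample_ids: list[str] | None = None) -> ClassLabels:
    """Read a space-delimited categorical CLS file.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``# <class names...>``;
    line 3: per-sample tokens, either class names or 0-based indices into the
    line-2 name list.  If ``sample_ids`` is omitted, synthetic ids ``S1..Sn``
    are assigned.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [l.strip() for l in fh.read().splitlines() if l.strip()]
    if len(lines) < 3:
        raise ClsParseError(f"{path}: expected 3 non-empty lines")
    head = lines[0].split()
    try:
        n, k = int(head[0]), int(head[1])
    except (ValueError, IndexError):
        raise ClsParseError(f"{path}: line 1: expected '<n> <k> 1'") from None
    if not lines[1].startswith("#"):
        raise ClsParseError(f"{path}: line 2: expected '# <class names>'")
    names = lines[1][1:].split()
    if len(names) != k:
        raise ClsParseError(f"{path}: line 2 lists {len(names)} classes, line 1 declares {k}")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise ClsParseError(f"{path}: line 3 has {len(tokens)} labels, line 1 declares {n}")
    if all(t.isdigit() for t in tokens) and set(names) != set(tokens):
        try:
            labels = [names[int(t)] for t in tokens]
        except IndexError:
            raise ClsParseError(f"{path}: line 3: class index out of range") from None
    else:
        unknown = sorted(set(tokens) - set(names))
        if unknown:
            raise ClsParseError(f"{path}: line 3: unknown class labels {unknown}")
        labels = tokens
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    return ClassLabels(sample_ids=sample_ids, labels=labels)


def write_cls(labels: ClassLabels, path) -> None:
    classes = labels.classes
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(labels.labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels.labels) + "\n")


# ---------------------------------------------------------------------------
# Filtering rules
# ---------------------------------------------------------------------------


def variation_filter(
    matrix: ExpressionMatrix,
    iqr_min: float = 0.5,
    intensity_min: float = 100.0,
    log_scale: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Informative-gene filter for the two-condition experiment.

    A gene is kept iff (a) at least one sample exceeds ``intensity_min`` raw
    units, and (b) the interquartile range of its log2 intensities (values
    floored at 1 before the log) exceeds ``iqr_min``.  The IQR is evaluated on
    the log2 scale by default — on raw relative units a threshold of 0.5 would
    be vacuous — with ``log_scale=False`` as the documented alternative.
    Quantiles use linear interpolation (NumPy's default, R type 7).
    """
    if matrix.n_genes == 0:
        raise ValueError("empty matrix")
    vals = matrix.values
    max_ok = vals.max(axis=1) > intensity_min
    scale = np.log2(np.maximum(vals, 1.0)) if log_scale else vals
    q25, q75 = np.percentile(scale, [25, 75], axis=1)
    iqr_ok = (q75 - q25) > iqr_min
    keep = max_ok & iqr_ok
    removed = []
    for i in np.flatnonzero(~keep):
        rule = "intensity" if not max_ok[i] else "iqr"
        removed.append((matrix.gene_ids[i], rule))
    report = FilterReport(n_in=matrix.n_genes, n_kept=int(keep.sum()), removed=removed)
    return matrix.subset_genes(keep), report


def compendium_filter(
    matrix: ExpressionMatrix,
    low: float = 50.0,
    high: float = 15000.0,
    majority: float = 0.5,
    fold_min: float = 2.0,
    diff_min: float = 50.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Compendium preprocessing filter.

    Removes a gene when a strict majority of arrays sit below ``low`` or above
    ``high`` relative units, and removes survivors whose dynamic range across
    all arrays is flat: max/max(min, 1) below ``fold_min`` or max - min below
    ``diff_min``.  Removals are tagged ``low``/``high``/``fold``/``diff`` in
    rule-check order.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty matrix")
    vals = matrix.values
    frac_low = (vals < low).mean(axis=1)
    frac_high = (vals > high).mean(axis=1)
    vmax = vals.max(axis=1)
    vmin = vals.min(axis=1)
    fold = vmax / np.maximum(vmin, 1.0)
    keep = np.ones(matrix.n_genes, dtype=bool)
    removed: list[tuple[str, str]] = []
    for i in range(matrix.n_genes):
        if frac_low[i] > majority:
            rule = "low"
        elif frac_high[i] > majority:
            rule = "high"
        elif fold[i] < fold_min:
            rule = "fold"
        elif (vmax[i] - vmin[i]) < diff_min:
            rule = "diff"
        else:
            continue
        keep[i] = False
        removed.append((matrix.gene_ids[i], rule))
    report = FilterReport(n_in=matrix.n_genes, n_kept=int(keep.sum()), removed=removed)
    return matrix.subset_genes(keep), report


def write_filter_report(report: FilterReport, path) -> None:
    """Write removals as a TSV ``gene_id\\trule`` with a count header comment."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# n_in={report.n_in}\tn_kept={report.n_kept}\tn_removed={len(report.removed)}\n")
        fh.write("gene_id\trule\n")
        for gene, rule in report.removed:
            fh.write(f"{gene}\t{rule}\n")


# ---------------------------------------------------------------------------
# Gene-identifier mapping
# ---------------------------------------------------------------------------


@dataclass
class GeneIdMapping:
    """Result of mapping signature identifiers onto a target matrix."""

    mapping: dict[str, str]  # source id -> target row id, source order preserved
    dropped: list[str]  # source ids with no match in the target

    @property
    def target_ids(self) -> list[str]:
        return list(self.mapping.values())


def map_gene_ids(
    source_ids,
    target_matrix: ExpressionMatrix,
    collapse: str = "max_mean",
    target_symbols: dict[str, str] | None = None,
) -> GeneIdMapping:
    """Map source gene symbols onto target matrix rows.

    Matching is exact but case-insensitive on symbols.  By default each target
    row's own identifier is its symbol; pass ``target_symbols`` (row id ->
    symbol) for probe-level tables where several probes share one symbol.
    When several target rows carry the same symbol the ``collapse`` policy
    decides: ``max_mean`` keeps the row with the greatest mean intensity,
    ``first`` keeps the first row in matrix order, ``error`` raises.

    Source ids absent from the target are dropped and reported; an empty
    intersection yields an empty mapping with a warning, never an exception.
    """
    if collapse not in ("max_mean", "first", "error"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    source_ids = [str(s) for s in source_ids]
    sym_of = (
        {rid: str(target_symbols.get(rid, rid)) for rid in target_matrix.gene_ids}
        if target_symbols is not None
        else {rid: rid for rid in target_matrix.gene_ids}
    )
    by_symbol: dict[str, list[int]] = {}
    for i, rid in enumerate(target_matrix.gene_ids):
        by_symbol.setdefault(sym_of[rid].lower(), []).append(i)

    row_means = target_matrix.values.mean(axis=1) if target_matrix.n_genes else np.empty(0)
    mapping: dict[str, str] = {}
    dropped: list[str] = []
    for src in source_ids:
        rows = by_symbol.get(src.lower())
        if not rows:
            dropped.append(src)
            continue
        if len(rows) == 1 or collapse == "first":
            chosen = rows[0]
        elif collapse == "max_mean":
            chosen = max(rows, key=lambda i: (row_means[i], -i))
        else:
            raise ValueError(
                f"symbol {src!r} matches {len(rows)} target rows and collapse='error'"
            )
        mapping[src] = target_matrix.gene_ids[chosen]
    if source_ids and not mapping:
        warnings.warn("no source gene ids could be mapped onto the target matrix")
    return GeneIdMapping(mapping=mapping, dropped=dropped)
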