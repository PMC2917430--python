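"""Synthetic surrogate data with planted structure and ground truth.

The downstream analysis assumes two datasets it cannot ship: a two-condition
cell-line GeneChip experiment (a control line versus a knockdown of the
reference gene, triplicate arrays) and a pan-cancer expression compendium
(190 specimens of 14 tumor types).  The generators here emulate the
*statistical shape* of those inputs at desk scale:

* positive, heavy-right-tailed intensities on the array "relative units"
  scale (log2-normal background, saturation at a configurable ceiling);
* a planted set of >= 2-fold differential genes in the two-group experiment;
* a planted coexpression module with a controlled Pearson correlation to a
  designated reference gene in the compendium;
* genes deliberately constructed to violate each filtering rule.

Every generator takes an explicit integer seed and drives a single named
pseudo-random algorithm (NumPy PCG64), so identical configs give identical
matrices across runs.  Each generator also emits a :class:`PlantedTruth`
record naming exactly which genes carry which planted effect, for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ClassLabels, ExpressionMatrix

__all__ = [
    "InvalidConfigError",
    "TwoGroupSimConfig",
    "CompendiumSimConfig",
    "PlantedTruth",
    "simulate_two_group_experiment",
    "embed_correlated_module",
    "simulate_tumor_compendium",
    "simulate_linked_study",
    "write_truth_tsv",
]


class InvalidConfigError(ValueError):
    """A simulation config violates its invariants."""


def _rng(seed: int) -> np.random.Generator:
    # PCG64 is the fixed algorithm; all determinism contracts rest on it.
    return np.random.Generator(np.random.PCG64(int(seed)))


# ---------------------------------------------------------------------------
# Configs and truth record
# ---------------------------------------------------------------------------


@dataclass
class TwoGroupSimConfig:
    """Two-condition experiment: ``n_per_group`` replicate arrays per class.

    Background genes get a gene-level log2 mean drawn from
    ``N(baseline_log2_mean, baseline_log2_sd)`` plus i.i.d. replicate noise of
    sd ``noise_log2_sd``; planted genes additionally shift the group-1 mean by
    ``+/- log2(fold)`` with the fold drawn log-uniformly from ``fold_range``.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    n_de_up: int = 0
    n_de_down: int = 0
    fold_range: tuple[float, float] = (2.0, 8.0)
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.35
    seed: int = 0
    group_labels: tuple[str, str] = ("control", "knockdown")

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise InvalidConfigError("n_genes and n_per_group must be positive")
        if self.n_de_up < 0 or self.n_de_down < 0:
            raise InvalidConfigError("planted gene counts must be non-negative")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise InvalidConfigError("more planted genes than genes")
        if self.baseline_log2_sd <= 0 or self.noise_log2_sd <= 0:
            raise InvalidConfigError("standard deviations must be positive")
        lo, hi = self.fold_range
        if lo < 1 or hi < lo:
            raise InvalidConfigError("fold_range must satisfy 1 <= low <= high")
        if self.group_labels[0] == self.group_labels[1]:
            raise InvalidConfigError("group labels must differ")


@dataclass
class CompendiumSimConfig:
    """Multi-tumor compendium with one reference gene and a planted module.

    ``rho`` is the target Pearson correlation between each module gene and the
    reference profile; violator counts plant genes that fail, respectively,
    the majority-low, majority-high and flatness compendium rules.
    ``intensity_floor``/``intensity_ceiling`` anchor the relative-units scale
    to the filter bounds (50 and 15,000); background values saturate at the
    ceiling.
    """

    n_genes: int = 2000
    n_samples: int = 190
    n_types: int = 14
    module_size: int = 20
    rho: float = 0.8
    n_low_violators: int = 10
    n_high_violators: int = 10
    n_flat_violators: int = 10
    intensity_floor: float = 50.0
    intensity_ceiling: float = 15000.0
    reference_id: str = "REF"
    type_effect_log2_sd: float = 0.0  # optional per-tumor-type mean shift
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples < 3 or self.n_types <= 0:
            raise InvalidConfigError("counts must be positive (n_samples >= 3)")
        n_special = (
            1 + self.module_size + self.n_low_violators + self.n_high_violators + self.n_flat_violators
        )
        if min(self.module_size, self.n_low_violators, self.n_high_violators, self.n_flat_violators) < 0:
            raise InvalidConfigError("module/violator counts must be non-negative")
        if n_special > self.n_genes:
            raise InvalidConfigError("module + violators + reference exceed n_genes")
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidConfigError("rho must lie in [0, 1]")
        if not 0 < self.intensity_floor < self.intensity_ceiling:
            raise InvalidConfigError("need 0 < intensity_floor < intensity_ceiling")
        if self.type_effect_log2_sd < 0:
            raise InvalidConfigError("type_effect_log2_sd must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated matrix."""

    de_genes: list[tuple[str, str, float]] = field(default_factory=list)  # (id, "up"/"down", fold)
    module_genes: list[str] = field(default_factory=list)
    reference_gene: str | None = None
    violator_genes: list[tuple[str, str]] = field(default_factory=list)  # (id, rule)

    def check_consistent(self, matrix: ExpressionMatrix) -> None:
        ids = set(matrix.gene_ids)
        listed = [g for g, _, _ in self.de_genes] + self.module_genes + [g for g, _ in self.violator_genes]
        if self.reference_gene is not None:
            listed.append(self.reference_gene)
        if len(set(listed)) != len(listed):
            raise ValueError("duplicate gene ids in truth record")
        missing = [g for g in listed if g not in ids]
        if missing:
            raise ValueError(f"truth lists ids absent from matrix: {missing[:5]}")


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    """Persist ground truth as ``gene_id\\trole\\tparam`` rows."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\trole\tparam\n")
        if truth.reference_gene is not None:
            fh.write(f"{truth.reference_gene}\treference\t.\n")
        for g, direction, fold in truth.de_genes:
            fh.write(f"{g}\tde_{direction}\t{fold:.6g}\n")
        for g in truth.module_genes:
            fh.write(f"{g}\tmodule\t.\n")
        for g, rule in truth.violator_genes:
            fh.write(f"{g}\tviolator\t{rule}\n")


# ---------------------------------------------------------------------------
# Two-group experiment
# ---------------------------------------------------------------------------


def simulate_two_group_experiment(
    config: TwoGroupSimConfig,
) -> tuple[ExpressionMatrix, ClassLabels, PlantedTruth]:
    """Simulate a two-condition replicate-array experiment.

    Returns the intensity matrix (genes x ``2 * n_per_group`` arrays), the
    class labels (group 1 first), and the planted truth.  Group 1 is the
    reference condition: "up" genes are planted higher there, "down" genes
    higher in group 2.
    """
    config.validate()
    rng = _rng(config.seed)
    n, m = config.n_genes, config.n_per_group
    gene_ids = [f"G{i:05d}" for i in range(n)]

    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    log2m = base[:, None] + rng.normal(0.0, config.noise_log2_sd, size=(n, 2 * m))

    n_de = config.n_de_up + config.n_de_down
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.empty(0, dtype=int)
    lo, hi = config.fold_range
    folds = 2.0 ** rng.uniform(math.log2(lo), math.log2(max(hi, lo)), size=n_de) if n_de else np.empty(0)
    de_genes: list[tuple[str, str, float]] = []
    for j, (i, fold) in enumerate(zip(de_idx, folds)):
        shift = math.log2(fold)
        if j < config.n_de_up:
            log2m[i, :m] += shift
            de_genes.append((gene_ids[i], "up", float(fold)))
        else:
            log2m[i, :m] -= shift
            de_genes.append((gene_ids[i], "down", float(fold)))

    values = np.exp2(log2m)
    g1, g2 = config.group_labels
    sample_ids = [f"{g1}_{j + 1}" for j in range(m)] + [f"{g2}_{j + 1}" for j in range(m)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    labels = ClassLabels(sample_ids=sample_ids, labels=[g1] * m + [g2] * m)
    truth = PlantedTruth(de_genes=de_genes)
    truth.check_consistent(matrix)
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Coexpression module embedding
# ---------------------------------------------------------------------------


def embed_correlated_module(
    reference_profile: np.ndarray,
    rho: float,
    n_genes: int,
    noise_seed: int,
    intensity_floor: float = 50.0,
    intensity_ceiling: float = 15000.0,
) -> np.ndarray:
    """Build gene profiles with expected Pearson correlation ``rho`` to a reference.

    On the standardized scale each row is ``rho * z_ref + sqrt(1 - rho^2) * eps``
    with independent standard-normal noise, then affinely mapped (positive
    slope, so the sample correlation is untouched) into the positive intensity
    range: each row's minimum is pinned at ``2 * intensity_floor`` and its
    maximum at a log-uniform value in ``[8 * floor, ceiling / 2]``, so every
    module gene clears the majority-low/high and flatness compendium rules by
    construction.
    """
    if not 0.0 <= rho <= 1.0:
        raise InvalidConfigError("rho must lie in [0, 1]")
    ref = np.asarray(reference_profile, dtype=float)
    if ref.ndim != 1 or ref.size < 3:
        raise InvalidConfigError("reference profile needs >= 3 samples")
    sd = ref.std()
    if sd == 0:
        raise ValueError("reference profile is constant; correlation undefined")
    if n_genes < 0:
        raise InvalidConfigError("n_genes must be non-negative")
    rng = _rng(noise_seed)
    z_ref = (ref - ref.mean()) / sd
    eps = rng.standard_normal(size=(n_genes, ref.size))
    g = rho * z_ref[None, :] + math.sqrt(1.0 - rho * rho) * eps

    lo = 2.0 * intensity_floor
    hi = np.exp2(
        rng.uniform(np.log2(8.0 * intensity_floor), np.log2(intensity_ceiling / 2.0), size=n_genes)
    )
    gmin = g.min(axis=1, keepdims=True)
    span = g.max(axis=1, keepdims=True) - gmin
    span = np.where(span == 0, 1.0, span)  # degenerate constant row; harmless
    return lo + (g - gmin) * (hi[:, None] - lo) / span


# ---------------------------------------------------------------------------
# Tumor compendium
# ---------------------------------------------------------------------------


def simulate_tumor_compendium(
    config: CompendiumSimConfig,
) -> tuple[ExpressionMatrix, ClassLabels, PlantedTruth]:
    """Simulate a multi-tumor expression compendium with a planted module.

    One designated reference gene gets a broad log2-normal profile; module
    genes are embedded with target correlation ``config.rho`` to it; violator
    genes are constructed to fail the majority-low, majority-high and flatness
    compendium rules; the remaining background genes are independent of the
    reference, drawn inside the filter-surviving intensity band and saturated
    at ``intensity_ceiling``.  Samples carry cyclic tumor-type labels
    ``T01..T{n_types}`` (decorative unless ``type_effect_log2_sd > 0``).
    """
    config.validate()
    rng = _rng(config.seed)
    n, ns = config.n_genes, config.n_samples
    floor, ceil = config.intensity_floor, config.intensity_ceiling

    # reference profile: broad dynamic range, well inside the filter bounds
    ref_center = math.log2(floor * 20.0)  # 1000 for the default floor of 50
    ref = np.exp2(rng.normal(ref_center, 1.2, size=ns))
    ref = np.clip(ref, floor * 1.5, ceil * 0.9)

    values = np.empty((n, ns), dtype=float)
    roles = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n - 1) + 1  # row 0 is the reference
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor : cursor + count]
        cursor += count
        return idx

    module_idx = take(config.module_size)
    low_idx = take(config.n_low_violators)
    high_idx = take(config.n_high_violators)
    flat_idx = take(config.n_flat_violators)

    values[0] = ref
    roles[0] = "reference"

    module_seed = int(rng.integers(0, 2**31 - 1))
    if config.module_size:
        values[module_idx] = embed_correlated_module(
            ref, config.rho, config.module_size, module_seed, floor, ceil
        )
        roles[module_idx] = "module"

    if config.n_low_violators:
        values[low_idx] = rng.uniform(floor * 0.1, floor * 0.9, size=(config.n_low_violators, ns))
        roles[low_idx] = "low"
    if config.n_high_violators:
        values[high_idx] = rng.uniform(ceil * 1.1, ceil * 1.6, size=(config.n_high_violators, ns))
        roles[high_idx] = "high"
    if config.n_flat_violators:
        flat_mu = rng.uniform(floor * 4.0, floor * 10.0, size=config.n_flat_violators)
        values[flat_idx] = flat_mu[:, None] + rng.uniform(
            0.0, floor * 0.6, size=(config.n_flat_violators, ns)
        )
        roles[flat_idx] = "flat"

    bg_idx = np.array([i for i in range(n) if roles[i] == "background"], dtype=int)
    if bg_idx.size:
        bg_mu = rng.uniform(math.log2(floor * 4.0), math.log2(ceil / 4.0), size=bg_idx.size)
        bg_sd = rng.uniform(0.5, 1.0, size=bg_idx.size)
        bg = bg_mu[:, None] + bg_sd[:, None] * rng.standard_normal(size=(bg_idx.size, ns))
        type_ids = np.arange(ns) % config.n_types
        if config.type_effect_log2_sd > 0:
            shifts = rng.normal(0.0, config.type_effect_log2_sd, size=(bg_idx.size, config.n_types))
            bg += shifts[:, type_ids]
        values[bg_idx] = np.minimum(np.exp2(bg), ceil)  # saturation

    gene_ids = [config.reference_id] + [f"C{i:05d}" for i in range(1, n)]
    sample_ids = [f"TUM{j + 1:03d}" for j in range(ns)]
    labels = ClassLabels(
        sample_ids=sample_ids,
        labels=[f"T{(j % config.n_types) + 1:02d}" for j in range(ns)],
    )
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = PlantedTruth(
        module_genes=[gene_ids[i] for i in module_idx],
        reference_gene=config.reference_id,
        violator_genes=[(gene_ids[i], "low") for i in low_idx]
        + [(gene_ids[i], "high") for i in high_idx]
        + [(gene_ids[i], "flat") for i in flat_idx],
    )
    truth.check_consistent(matrix)
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Linked study (two-group experiment + compendium sharing gene ids)
# ---------------------------------------------------------------------------


def simulate_linked_study(
    two_group: TwoGroupSimConfig,
    compendium: CompendiumSimConfig,
) -> tuple[
    tuple[ExpressionMatrix, ClassLabels, PlantedTruth],
    tuple[ExpressionMatrix, ClassLabels, PlantedTruth],
]:
    """Simulate both inputs of the full pipeline on a shared gene namespace.

    The compendium's planted module genes are given the identifiers of the
    two-group experiment's up-planted genes (and the compendium reference id
    replaces one additional cell-line gene), so a signature derived from the
    cell-line experiment maps onto the compendium exactly as a real symbol
    intersection would.  ``two_group.n_de_up`` must be at least
    ``compendium.module_size``.
    """
    if two_group.n_de_up < compendium.module_size:
        raise InvalidConfigError("need n_de_up >= module_size to link the planted truths")
    cell = simulate_two_group_experiment(two_group)
    comp_matrix, comp_labels, comp_truth = simulate_tumor_compendium(compendium)

    cell_matrix, cell_labels, cell_truth = cell
    up_ids = [g for g, d, _ in cell_truth.de_genes if d == "up"]
    rename = dict(zip(up_ids, comp_truth.module_genes))  # first module_size up genes
    # give the compendium reference an expression row in the cell-line matrix too
    taken = set(rename) | set(rename.values())
    spare = next(
        g
        for g in cell_matrix.gene_ids
        if g not in taken and g not in {x for x, _, _ in cell_truth.de_genes}
    )
    rename[spare] = comp_truth.reference_gene

    new_ids = [rename.get(g, g) for g in cell_matrix.gene_ids]
    cell_matrix = ExpressionMatrix(
        new_ids, cell_matrix.sample_ids, cell_matrix.values, cell_matrix.descriptions
    )
    cell_truth = PlantedTruth(
        de_genes=[(rename.get(g, g), d, f) for g, d, f in cell_truth.de_genes]
    )
    cell_truth.check_consistent(cell_matrix)
    return (cell_matrix, cell_labels, cell_truth), (comp_matrix, comp_labels, comp_truth)
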