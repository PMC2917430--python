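"""Moderated two-group differential expression and signature selection.

The two-condition experiment is analyzed limma-style: per gene, an ordinary
pooled-variance two-sample comparison of log2 intensities, with the per-gene
variance shrunk toward an empirical-Bayes prior before forming the
t-statistic.  With prior degrees of freedom ``d0`` and prior variance
``s0^2``, the posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),      d = n1 + n2 - 2,

and the moderated t is ``t = delta / (s_tilde * sqrt(1/n1 + 1/n2))`` with
``delta`` the difference of group mean log2 intensities, referred to a
t-distribution with ``d0 + d`` degrees of freedom.  The prior is estimated by
moment matching on the log sample variances under a scaled-inverse-chi-squared
model (digamma/trigamma relations); when the observed spread of log variances
is at or below its theoretical minimum the moment estimate diverges and a
finite cap is substituted.

Fold changes follow the array-era signed convention: the ratio ``r`` of
raw-scale group means is reported as ``r`` when ``r >= 1`` and ``-1/r``
otherwise, so a gene 4-fold higher in the knockdown reads -4.  Multiple
testing uses Benjamini-Hochberg FDR.  A small 2^-ddCt utility covers qPCR
validation arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ClassLabels, ExpressionMatrix

__all__ = [
    "DegenerateModelError",
    "InsufficientReplicationError",
    "ModeratedVarianceModel",
    "SignatureQuery",
    "estimate_prior",
    "fit_moderated_t",
    "bh_adjust",
    "signed_fold_change",
    "select_coexpressed_signature",
    "ddct_relative_expression",
    "DE_TABLE_COLUMNS",
]

DE_TABLE_COLUMNS = [
    "gene_id",
    "mean_ref",
    "mean_other",
    "log2fc",
    "signed_fc",
    "s2",
    "t_mod",
    "p_raw",
    "p_adj",
]


class DegenerateModelError(ValueError):
    """The variance model cannot be formed (e.g. no positive variances)."""


class InsufficientReplicationError(ValueError):
    """A class has fewer than 2 samples."""


@dataclass
class ModeratedVarianceModel:
    """Empirical-Bayes variance prior: d0 prior df, s0_sq prior variance.

    ``capped`` records that the moment estimate of ``d0`` diverged (observed
    spread of log variances at or below its theoretical minimum) and the
    finite ceiling ``d0_cap`` was substituted.
    """

    d0: float
    s0_sq: float
    d: float
    d0_cap: float | None = None
    capped: bool = False

    def __post_init__(self) -> None:
        if self.d0 < 0 or not math.isfinite(self.d0):
            raise ValueError("d0 must be finite and >= 0 (use d0_cap for divergent fits)")
        if self.s0_sq < 0:
            raise ValueError("s0_sq must be >= 0")


@dataclass
class SignatureQuery:
    """Genes up in the reference condition passing both selection thresholds."""

    gene_ids: list[str]
    direction: str = "up"
    p_adj_max: float = 0.05
    fold_min: float = 2.0
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Prior estimation (moment matching on log variances)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    # trigamma(x) ~ 1/x + 1/(2x^2); these bounds bracket the root well
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_prior(
    sample_variances: np.ndarray,
    d: float,
    d0_cap: float | None = None,
) -> ModeratedVarianceModel:
    """Moment-matching fit of the scaled-inverse-chi-squared variance prior.

    Under the model ``s^2 | sigma^2 ~ sigma^2 chi^2_d / d`` with
    ``1/sigma^2 ~ chi^2_{d0}/(d0 s0^2)``, the log sample variances satisfy
    ``E[log s^2] = log s0^2 + psi(d/2) - log(d/2) + psi(d0/2)... `` with the
    standard digamma/trigamma moment relations; ``d0`` solves
    ``trigamma(d0/2) = var(e) - trigamma(d/2)`` with
    ``e = log s^2 - psi(d/2) + log(d/2)``.  If the right-hand side is not
    positive the estimate diverges and ``d0`` is set to ``d0_cap``
    (default ``10 * d``) with ``capped=True``.

    Requires at least 10 strictly positive variances.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if d <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise DegenerateModelError("all sample variances are zero")
    if pos.size < 10:
        raise DegenerateModelError(
            f"need >= 10 positive sample variances to fit the prior, got {pos.size}"
        )
    cap = 10.0 * d if d0_cap is None else float(d0_cap)
    z = np.log(pos)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        capped = False
        if d0 > cap:
            d0, capped = cap, True
    else:
        # spread of log variances below its sampling minimum: effectively a
        # common variance; substitute the cap and the plain mean variance
        d0 = cap
        s0_sq = float(pos.mean())
        capped = True
    return ModeratedVarianceModel(d0=d0, s0_sq=s0_sq, d=float(d), d0_cap=cap, capped=capped)


# ---------------------------------------------------------------------------
# Moderated t fit
# ---------------------------------------------------------------------------


def fit_moderated_t(
    matrix: ExpressionMatrix,
    classes: ClassLabels,
    reference_class: str | None = None,
    model: ModeratedVarianceModel | None = None,
    d0_cap: float | None = None,
) -> pd.DataFrame:
    """Fit the moderated two-group comparison for every gene.

    ``reference_class`` names the class treated as group 1 (defaults to the
    first label in order of appearance); positive statistics mean higher in
    the reference class.  When ``model`` is None the variance prior is
    estimated from the data via :func:`estimate_prior`.

    Returns a DataFrame with columns :data:`DE_TABLE_COLUMNS`: raw-scale group
    means; ``log2fc``, the difference of group mean log2 intensities (the
    log-scale effect the t-statistic tests, so their signs always agree); the
    raw-scale signed fold change; the pooled log2-scale sample variance
    ``s2``; the moderated t and its two-sided p-value (t distribution with
    ``d0 + d`` df); and BH-adjusted p-values.
    """
    classes.check_paired(matrix)
    labels = classes.classes
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    if reference_class is None:
        reference_class = labels[0]
    elif reference_class not in labels:
        raise ValueError(f"reference class {reference_class!r} not among {labels}")
    other_class = labels[1] if labels[0] == reference_class else labels[0]
    m1 = classes.mask(reference_class)
    m2 = classes.mask(other_class)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicationError(
            f"each class needs >= 2 samples (got {reference_class}:{n1}, {other_class}:{n2})"
        )
    if np.any(matrix.values <= 0):
        raise ValueError("intensities must be strictly positive (log2 is taken internally)")

    log2v = np.log2(matrix.values)
    x1, x2 = log2v[:, m1], log2v[:, m2]
    delta = x1.mean(axis=1) - x2.mean(axis=1)
    d = float(n1 + n2 - 2)
    s2 = (((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / d

    if model is None:
        model = estimate_prior(s2, d, d0_cap=d0_cap)
    elif model.d0 == 0 and np.all(s2 == 0):
        raise DegenerateModelError("all per-gene variances are zero and d0 = 0")

    s2_post = (model.d0 * model.s0_sq + d * s2) / (model.d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        t_mod = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t_mod)
    df_total = model.d0 + d
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_raw = np.clip(p_raw, 0.0, 1.0)

    mean_ref = matrix.values[:, m1].mean(axis=1)
    mean_other = matrix.values[:, m2].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_ref": mean_ref,
            "mean_other": mean_other,
            "log2fc": delta,
            "signed_fc": _signed_fold_change_vec(mean_ref, mean_other),
            "s2": s2,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        }
    )
    table.attrs["model"] = model
    table.attrs["reference_class"] = reference_class
    table.attrs["other_class"] = other_class
    return table


# ---------------------------------------------------------------------------
# BH-FDR, fold changes, signature selection, ddCt
# ---------------------------------------------------------------------------


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_ref: float, mean_other: float) -> float:
    """Array-era signed fold change of two positive raw-scale means.

    Returns ``r = mean_ref / mean_other`` when ``r >= 1``, else ``-1/r``;
    so equal means give 1.0 and the sign flips under argument exchange.
    """
    if mean_ref <= 0 or mean_other <= 0:
        raise ValueError("group means must be strictly positive")
    r = mean_ref / mean_other
    return r if r >= 1.0 else -1.0 / r


def _signed_fold_change_vec(mean_ref: np.ndarray, mean_other: np.ndarray) -> np.ndarray:
    r = mean_ref / mean_other
    return np.where(r >= 1.0, r, -1.0 / r)


def select_coexpressed_signature(
    de: pd.DataFrame,
    p_adj_max: float = 0.05,
    fold_min: float = 2.0,
    exclude: tuple[str, ...] | list[str] = (),
) -> SignatureQuery:
    """Select the up-in-reference signature from a differential table.

    Keeps genes with ``p_adj < p_adj_max`` and ``signed_fc >= fold_min`` (the
    up direction on the signed-fold scale).  ``exclude`` removes listed genes
    — typically the reference gene itself, whose self-coexpression would be
    circular.  An empty selection returns an empty query with a warning.
    """
    missing = {"gene_id", "signed_fc", "p_adj"} - set(de.columns)
    if missing:
        raise ValueError(f"differential table lacks columns {sorted(missing)}")
    excluded = [g for g in exclude if g in set(de["gene_id"])]
    keep = (de["p_adj"] < p_adj_max) & (de["signed_fc"] >= fold_min)
    ids = [g for g in de.loc[keep, "gene_id"] if g not in set(exclude)]
    if not ids:
        warnings.warn("signature selection returned no genes")
    return SignatureQuery(
        gene_ids=ids, p_adj_max=p_adj_max, fold_min=fold_min, excluded=excluded
    )


def ddct_relative_expression(
    ct_target_trt: float,
    ct_ref_trt: float,
    ct_target_ctl: float,
    ct_ref_ctl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``ddCt = (Ct_target,treated - Ct_reference,treated) -
    (Ct_target,control - Ct_reference,control)``; returns ``2 ** -ddCt``.
    """
    for ct in (ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_trt - ct_ref_trt) - (ct_target_ctl - ct_ref_ctl)
    return 2.0 ** (-ddct)


def write_de_table(de: pd.DataFrame, path) -> None:
    """Write the differential table as TSV with the documented column set."""
    de.loc[:, DE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
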