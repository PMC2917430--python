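"""Moderated t, prior estimation, BH-FDR, fold conventions, ddCt."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

import coexsig as cs
from coexsig.differential_expression import (
    DegenerateModelError,
    InsufficientReplicationError,
)


def _matrix_from_log2(log2x):
    log2x = np.asarray(log2x, dtype=float)
    n, m = log2x.shape
    return cs.ExpressionMatrix(
        [f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)], 2.0**log2x
    )


def _two_class(n_per_group):
    ids = [f"s{j}" for j in range(2 * n_per_group)]
    return cs.ClassLabels(ids, ["A"] * n_per_group + ["B"] * n_per_group)


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def test_identical_groups_give_zero_statistic():
    rng = np.random.Generator(np.random.PCG64(0))
    half = rng.normal(8, 1, (20, 3))
    matrix = _matrix_from_log2(np.hstack([half, half]))
    table = cs.fit_moderated_t(matrix, _two_class(3), "A")
    assert np.allclose(table["t_mod"], 0.0)
    assert np.allclose(table["p_raw"], 1.0)
    assert np.allclose(table["log2fc"], 0.0)


def test_zero_prior_df_reduces_to_ordinary_pooled_t():
    """With d0 = 0 the moderated t is the textbook pooled-variance t."""
    rng = np.random.Generator(np.random.PCG64(7))
    log2x = rng.normal(8, 1, (50, 6))
    matrix = _matrix_from_log2(log2x)
    model = cs.ModeratedVarianceModel(d0=0.0, s0_sq=0.0, d=4.0)
    table = cs.fit_moderated_t(matrix, _two_class(3), "A", model=model)
    # independent oracle: explicit pooled-variance formula per gene
    for i in range(50):
        x1, x2 = log2x[i, :3], log2x[i, 3:]
        sp2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / 4.0
        t_ref = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (2.0 / 3.0))
        assert table["t_mod"].iloc[i] == pytest.approx(t_ref, abs=1e-10)
    t_scipy, _ = stats.ttest_ind(log2x[:, :3].T, log2x[:, 3:].T)
    assert np.allclose(table["t_mod"], t_scipy, atol=1e-10)


def test_hand_worked_fixed_prior_case():
    """Fixed d0=4, s0^2=0.1, constant replicates (1,1,1) vs (2,2,2)."""
    matrix = _matrix_from_log2(np.array([[1.0, 1, 1, 2, 2, 2]]))
    model = cs.ModeratedVarianceModel(d0=4.0, s0_sq=0.1, d=4.0)
    table = cs.fit_moderated_t(matrix, _two_class(3), "A", model=model)
    # s2 = 0, posterior variance (4*0.1)/8 = 0.05, t = -1/sqrt(0.05 * 2/3)
    assert table["s2"].iloc[0] == 0.0
    assert table["t_mod"].iloc[0] == pytest.approx(-5.477225575, abs=1e-6)
    p_expected = 2 * stats.t.sf(5.477225575, df=8)
    assert table["p_raw"].iloc[0] == pytest.approx(p_expected, rel=1e-6)


def test_moderated_t_shrinks_toward_prior_limit():
    """As d0 grows, t approaches delta / (s0 * sqrt(1/n1 + 1/n2))."""
    rng = np.random.Generator(np.random.PCG64(1))
    log2x = rng.normal(5, 2, (30, 6))
    matrix = _matrix_from_log2(log2x)
    s0_sq = 0.3
    model = cs.ModeratedVarianceModel(d0=1e12, s0_sq=s0_sq, d=4.0)
    table = cs.fit_moderated_t(matrix, _two_class(3), "A", model=model)
    delta = log2x[:, :3].mean(axis=1) - log2x[:, 3:].mean(axis=1)
    limit = delta / np.sqrt(s0_sq * (2.0 / 3.0))
    assert np.allclose(table["t_mod"], limit, rtol=1e-6)


def test_sign_of_t_matches_fold_direction():
    rng = np.random.Generator(np.random.PCG64(5))
    log2x = rng.normal(8, 1, (100, 6))
    log2x[:50, :3] += 2.0
    matrix = _matrix_from_log2(log2x)
    table = cs.fit_moderated_t(matrix, _two_class(3), "A")
    ok = table["s2"] > 0
    assert np.all(np.sign(table.loc[ok, "t_mod"]) == np.sign(table.loc[ok, "log2fc"]))


def test_insufficient_replication_rejected():
    matrix = _matrix_from_log2(np.ones((5, 3)))
    classes = cs.ClassLabels(matrix.sample_ids, ["A", "A", "B"])
    with pytest.raises(InsufficientReplicationError):
        cs.fit_moderated_t(matrix, classes, "A")


def test_degenerate_all_zero_variance_with_zero_prior():
    matrix = _matrix_from_log2(np.tile([[1.0, 1, 1, 2, 2, 2]], (12, 1)))
    model = cs.ModeratedVarianceModel(d0=0.0, s0_sq=0.0, d=4.0)
    with pytest.raises(DegenerateModelError):
        cs.fit_moderated_t(matrix, _two_class(3), "A", model=model)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path):
    """Full-pipeline cross-check against the reference empirical-Bayes fit in R."""
    rng = np.random.Generator(np.random.PCG64(42))
    n, m = 200, 3
    sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, n)
    log2x = rng.normal(8, 1, (n, 1)) + np.sqrt(sigma2)[:, None] * rng.standard_normal((n, 2 * m))
    matrix = _matrix_from_log2(log2x)
    table = cs.fit_moderated_t(matrix, _two_class(m), "A")
    model = table.attrs["model"]

    xfile = str(tmp_path / "limma_x.tsv")
    tfile = str(tmp_path / "limma_t.tsv")
    np.savetxt(xfile, log2x, delimiter="\t")
    rcode = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{xfile}", sep="\\t"))
        design <- cbind(Intercept = 1, AvsB = c(1, 1, 1, 0, 0, 0))
        fit <- eBayes(lmFit(x, design))
        out <- cbind(fit$df.prior, fit$s2.prior, fit$t[, "AvsB"], fit$p.value[, "AvsB"])
        write.table(out, "{tfile}", col.names = FALSE, row.names = FALSE)
        """
    )
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True, timeout=120)
    ref = np.loadtxt(tfile)
    assert model.d0 == pytest.approx(ref[0, 0], rel=1e-5)
    assert model.s0_sq == pytest.approx(ref[0, 1], rel=1e-5)
    assert np.allclose(table["t_mod"], ref[:, 2], atol=1e-8)
    assert np.allclose(table["p_raw"], ref[:, 3], atol=1e-8)


# ---------------------------------------------------------------------------
# Prior estimation
# ---------------------------------------------------------------------------


def test_prior_equal_variances_hits_the_cap():
    s2 = np.full(50, 0.2)
    model = cs.estimate_prior(s2, d=4.0)
    assert model.capped
    assert model.d0 == 40.0  # default cap 10 * d
    assert model.s0_sq == pytest.approx(0.2)


def test_prior_recovery_from_scaled_inv_chi2():
    """Moment matching recovers (d0, s0^2) from data simulated at d0=4, s0^2=0.05."""
    d0_true, s0_true, d = 4.0, 0.05, 4.0
    d0_hats, s0_hats = [], []
    for seed in range(20):
        rng = np.random.Generator(np.random.PCG64(seed))
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(int(d), 5000) / d
        model = cs.estimate_prior(s2, d)
        d0_hats.append(model.d0)
        s0_hats.append(model.s0_sq)
    assert 2.5 <= np.median(d0_hats) <= 6.5
    assert np.median(s0_hats) == pytest.approx(s0_true, rel=0.25)


def test_prior_needs_ten_positive_variances():
    with pytest.raises(DegenerateModelError):
        cs.estimate_prior(np.array([0.1] * 9), d=4.0)
    with pytest.raises(DegenerateModelError):
        cs.estimate_prior(np.zeros(100), d=4.0)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def _bh_oracle(p):
    """Brute-force step-up: q_i = min_{j >= i in sorted order} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.minimum(q, 1.0)


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.42], [0.42]),
    ],
)
def test_bh_hand_worked(p, expected):
    assert np.allclose(cs.bh_adjust(np.array(p)), expected)


def test_bh_agrees_with_brute_force_over_permutations():
    base = [0.001, 0.02, 0.02, 0.3, 0.77, 1.0]
    for perm in itertools.permutations(base):
        p = np.array(perm)
        assert np.allclose(cs.bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_preserves_order_and_never_decreases():
    rng = np.random.Generator(np.random.PCG64(9))
    p = rng.uniform(size=200)
    q = cs.bh_adjust(p)
    assert np.all(q >= p)
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cs.bh_adjust(np.array([0.5, 1.5]))
    with pytest.raises(ValueError):
        cs.bh_adjust(np.array([-0.1]))


# ---------------------------------------------------------------------------
# Signed fold change & signature selection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a, b, expected", [(4, 1, 4.0), (1, 4, -4.0), (3, 2, 1.5), (5, 5, 1.0)])
def test_signed_fold_change_examples(a, b, expected):
    assert cs.signed_fold_change(a, b) == pytest.approx(expected)


def test_signed_fold_change_antisymmetry():
    rng = np.random.Generator(np.random.PCG64(3))
    for _ in range(100):
        a, b = rng.uniform(0.1, 100, 2)
        if a == b:
            continue
        assert cs.signed_fold_change(a, b) == pytest.approx(-cs.signed_fold_change(b, a))


def test_signed_fold_change_rejects_nonpositive():
    with pytest.raises(ValueError):
        cs.signed_fold_change(0.0, 1.0)


def test_signature_selection_applies_both_thresholds():
    import pandas as pd

    de = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "signed_fc": [4.0, -4.0, 1.5, 4.0, 2.1],
            "p_adj": [0.01, 0.01, 0.01, 0.2, 0.04],
        }
    )
    query = cs.select_coexpressed_signature(de)
    assert query.gene_ids == ["g1", "g5"]


def test_signature_selection_empty_warns():
    import pandas as pd

    de = pd.DataFrame({"gene_id": ["g1"], "signed_fc": [4.0], "p_adj": [1.0]})
    with pytest.warns(UserWarning, match="no genes"):
        query = cs.select_coexpressed_signature(de)
    assert query.gene_ids == []


def test_signature_selection_vacuous_thresholds_take_all_up():
    import pandas as pd

    de = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "signed_fc": [1.2, -3.0, 8.0],
            "p_adj": [0.9, 0.9, 0.9],
        }
    )
    query = cs.select_coexpressed_signature(de, p_adj_max=1.0 + 1e-12, fold_min=1.0)
    assert query.gene_ids == ["g1", "g3"]


def test_signature_selection_excludes_reference():
    import pandas as pd

    de = pd.DataFrame(
        {"gene_id": ["REF", "g2"], "signed_fc": [5.0, 4.0], "p_adj": [0.001, 0.001]}
    )
    query = cs.select_coexpressed_signature(de, exclude=("REF",))
    assert query.gene_ids == ["g2"]
    assert query.excluded == ["REF"]


def test_de_recovery_on_planted_two_group_data():
    """>= 90% of up-planted 4-fold genes selected, realized FDR <= 10% (median of 10 seeds)."""
    recoveries, fdrs = [], []
    for seed in range(10):
        cfg = cs.TwoGroupSimConfig(
            n_genes=2000, n_per_group=3, n_de_up=100, n_de_down=100,
            fold_range=(4.0, 4.0), noise_log2_sd=0.35, seed=seed,
        )
        matrix, labels, truth = cs.simulate_two_group_experiment(cfg)
        table = cs.fit_moderated_t(matrix, labels, "control")
        query = cs.select_coexpressed_signature(table)
        selected = set(query.gene_ids)
        up = {g for g, direction, _ in truth.de_genes if direction == "up"}
        recoveries.append(len(selected & up) / len(up))
        fdrs.append(len(selected - up) / max(len(selected), 1))
    assert np.median(recoveries) >= 0.90
    assert np.median(fdrs) <= 0.10


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cts, expected",
    [
        ((20.0, 20.0, 20.0, 20.0), 1.0),
        ((25.0, 20.0, 24.0, 20.0), 0.5),
        ((24.0, 20.0, 26.0, 20.0), 4.0),
    ],
)
def test_ddct_arithmetic(cts, expected):
    assert cs.ddct_relative_expression(*cts) == pytest.approx(expected)


def test_ddct_rejects_nonfinite():
    with pytest.raises(ValueError):
        cs.ddct_relative_expression(np.nan, 20.0, 20.0, 20.0)
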