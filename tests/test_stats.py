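"""Statistics layer: exact rank tests, CIs, logistic ORs, normalisation, SAM."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ngi.stats import (ExpressionMatrix, logistic_or_pcr, mann_whitney,
                       normalize_expression, paired_mean_difference_ci,
                       paired_wilcoxon, rank_group_test, sam_til_association,
                       spearman)

from oracles import (oracle_mannwhitney_p, oracle_spearman_p,
                     oracle_wilcoxon_p)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_spearman_exact_p_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    res = spearman(x, y)
    assert res.exact
    assert res.p_value == oracle_spearman_p(x, y)


def test_spearman_constant_input_flagged():
    res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.p_value is None and res.flag == "constant input"


def test_spearman_invariant_to_monotone_transform():
    rng = np.random.default_rng(4)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r1 = spearman(x, y)
    r2 = spearman(np.exp(x), y ** 3)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def test_wilcoxon_degenerate_all_zero():
    res = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
    assert res.p_value is None and res.flag == "all differences zero"


def test_wilcoxon_six_positive_differences_one_sided():
    res = paired_wilcoxon(np.zeros(6), np.arange(1.0, 7.0), alternative="greater")
    assert res.exact
    assert res.p_value == pytest.approx(1 / 64)


def test_wilcoxon_symmetric_in_arguments():
    rng = np.random.default_rng(1)
    x = rng.normal(size=10)
    y = x + rng.normal(size=10)
    assert paired_wilcoxon(x, y).p_value == pytest.approx(
        paired_wilcoxon(y, x).p_value)


@pytest.mark.parametrize("seed", [3, 7, 11])
def test_wilcoxon_exact_p_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    diff = np.round(rng.normal(size=9), 1)
    diff = diff[diff != 0]
    res = paired_wilcoxon(np.zeros(len(diff)), diff)
    assert res.exact
    assert res.p_value == oracle_wilcoxon_p(diff)


def test_wilcoxon_large_n_close_to_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = x + rng.normal(0.4, 1.0, size=40)
    res = paired_wilcoxon(x, y)
    ref = sps.wilcoxon(y, x, correction=True, mode="approx")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Mann–Whitney / Kruskal–Wallis


def test_mannwhitney_identical_groups_null():
    res = rank_group_test([[1, 2, 3], [1, 2, 3]])
    assert res.p_value >= 0.99


def test_mannwhitney_separated_groups_exact():
    res = rank_group_test([[1, 2, 3], [10, 11, 12]])
    assert res.exact
    assert res.p_value == pytest.approx(2 / 20)


@pytest.mark.parametrize("seed", [2, 9])
def test_mannwhitney_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    g1 = np.round(rng.normal(size=5), 1)
    g2 = np.round(rng.normal(0.5, 1, size=6), 1)
    res = mann_whitney(g1, g2)
    assert res.exact
    assert res.p_value == oracle_mannwhitney_p(g1, g2)


def test_two_group_kruskal_equals_mannwhitney_approximation():
    rng = np.random.default_rng(8)
    a = rng.normal(size=30)
    b = rng.normal(0.6, 1, size=25)
    kw = sps.kruskal(a, b)
    mw = mann_whitney(a, b, exact_max_total=0)
    assert mw.p_value == pytest.approx(kw.pvalue, abs=1e-6)


def test_three_groups_use_kruskal():
    res = rank_group_test([[1, 2], [2, 3], [3, 4]])
    assert res.method == "kruskal_wallis"


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_group_test([[1, 2], []])


# ---------------------------------------------------------------------------
# paired mean difference


def test_paired_ci_identity():
    r = paired_mean_difference_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.mean_difference == 0.0
    assert r.ci_low <= 0.0 <= r.ci_high


def test_paired_ci_closed_form():
    d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r = paired_mean_difference_ci(np.zeros(5), d)
    half = sps.t.ppf(0.975, 4) * d.std(ddof=1) / math.sqrt(5)
    assert r.mean_difference == pytest.approx(3.0)
    assert r.ci_high - r.mean_difference == pytest.approx(half)
    assert r.ci_high - r.mean_difference == pytest.approx(
        2.776 * 1.5811 / math.sqrt(5), abs=2e-3)


def test_wider_level_never_narrows_ci():
    rng = np.random.default_rng(6)
    x = rng.normal(size=12)
    y = x + rng.normal(size=12)
    r95 = paired_mean_difference_ci(x, y, level=0.95)
    r99 = paired_mean_difference_ci(x, y, level=0.99)
    assert (r99.ci_high - r99.ci_low) >= (r95.ci_high - r95.ci_low)


# ---------------------------------------------------------------------------
# logistic odds ratio


def test_binary_predictor_matches_cross_product_ratio():
    y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
    x = np.array([1] * 100 + [0] * 100)
    res = logistic_or_pcr(y, x)
    assert res.converged
    assert res.or_per_unit == pytest.approx((30 * 90) / (70 * 10), abs=1e-6)


def test_or_unit_scaling_identity():
    rng = np.random.default_rng(2)
    x = rng.normal(50, 10, 300)
    y = (rng.uniform(size=300) < 1 / (1 + np.exp(-(x - 50) / 10))).astype(int)
    r1 = logistic_or_pcr(y, x, unit_scale=1.0)
    r10 = logistic_or_pcr(y, x, unit_scale=10.0)
    assert r10.or_per_unit == pytest.approx(r1.or_per_unit ** 10, rel=1e-9)


def test_null_predictor_ci_covers_one():
    rng = np.random.default_rng(13)
    covered = 0
    reps = 100
    for _ in range(reps):
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 0.3).astype(int)
        res = logistic_or_pcr(y, x)
        if res.converged and res.ci_low <= 1.0 <= res.ci_high:
            covered += 1
    assert covered >= 0.90 * reps


def test_single_class_outcome_rejected():
    with pytest.raises(ValueError):
        logistic_or_pcr([1, 1, 1], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# expression normalisation


def _toy_counts():
    return pd.DataFrame(
        {"s1": [100, 200, 50, 400, 80, 10], "s2": [50, 100, 25, 200, 40, 5]},
        index=["ACTB", "MRPL19", "PSMC4", "RPLP0", "SF3A1", "GENE1"],
    )


def test_normalisation_equalises_housekeeping_means():
    hk = ["ACTB", "MRPL19", "PSMC4", "RPLP0", "SF3A1"]
    norm = normalize_expression(_toy_counts(), hk)
    means = norm.values.loc[hk].mean(axis=0)
    assert means.std() < 1e-12


def test_already_normalised_matrix_is_fixed_point():
    hk = ["ACTB", "GENE1"]
    raw = pd.DataFrame({"s1": [100, 10], "s2": [100, 20]},
                       index=["ACTB", "GENE1"])
    raw.loc["GENE1"] = [100, 100]  # equal housekeeping log-means
    norm = normalize_expression(raw, hk)
    assert np.allclose(norm.offsets.to_numpy(), 0.0)
    assert np.allclose(norm.values.to_numpy(), np.log2(raw.to_numpy() + 1.0))


def test_zero_count_maps_to_zero_before_offset():
    raw = pd.DataFrame({"s1": [0, 100]}, index=["GENE0", "ACTB"])
    norm = normalize_expression(raw, ["ACTB"])
    assert norm.values.loc["GENE0", "s1"] == pytest.approx(0.0 + norm.offsets["s1"])


def test_known_offset_shift():
    hk = ["ACTB"]
    raw = pd.DataFrame({"s1": [16], "s2": [33]}, index=["ACTB"])
    # log2(17) vs log2(34): s1 sits exactly 1 below s2; grand mean splits it
    norm = normalize_expression(raw, hk)
    assert norm.offsets["s1"] - norm.offsets["s2"] == pytest.approx(1.0)


def test_missing_housekeeping_rejected():
    with pytest.raises(ValueError, match="missing"):
        normalize_expression(_toy_counts().drop(index="ACTB"),
                             ["ACTB", "MRPL19"])


# ---------------------------------------------------------------------------
# quantitative SAM


def test_sam_refuses_too_few_permutations():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 20)))
    with pytest.raises(ValueError):
        sam_til_association(X, np.arange(20.0), n_permutations=10)


def test_sam_constant_gene_never_significant():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(8, 1, (50, 40)),
                     index=[f"G{i}" for i in range(50)])
    X.loc["G0"] = 5.0  # constant gene
    res = sam_til_association(X, rng.uniform(0, 50, 40), n_permutations=100,
                              seed=0)
    row = res.table.set_index("gene").loc["G0"]
    assert not row["significant"]
    assert np.isfinite(row["d"])


def test_sam_q_monotone_in_abs_d():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(8, 1, (120, 40)),
                     index=[f"G{i}" for i in range(120)])
    res = sam_til_association(X, rng.uniform(0, 50, 40), n_permutations=100,
                              seed=1)
    t = res.table.assign(absd=lambda d: d["d"].abs()).sort_values(
        "absd", ascending=False)
    assert (np.diff(t["q"].to_numpy()) >= -1e-12).all()


def test_sam_detects_planted_gene():
    rng = np.random.default_rng(6)
    stils = rng.uniform(0, 60, 60)
    z = (stils - stils.mean()) / stils.std()
    X = rng.normal(8, 1, (300, 60))
    X[0] = 8 + 0.9 * z + math.sqrt(1 - 0.81) * rng.normal(size=60)
    Xd = pd.DataFrame(X, index=[f"G{i}" for i in range(300)])
    res = sam_til_association(Xd, stils, n_permutations=200, seed=2)
    assert "G0" in res.significant_genes
    assert res.table["significant"].sum() <= 6  # controls false calls
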