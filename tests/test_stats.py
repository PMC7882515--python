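"""Cohort inference: omnibus tests, gate, post-hoc, FDR, partial
correlation, and ROC — each against hand arithmetic or an independent
oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dkiasl.stats import (bh_fdr, chi_squared_counts, combined_auc,
                          kruskal_wallis, normality_gate, one_way_anova,
                          pairwise_posthoc, partial_pearson,
                          regionwise_group_analysis, roc_auc)
from dkiasl.synth import CohortConfig, make_cohort


# ---------------------------------------------------------------------------
# chi-squared


def chi2_loop_oracle(table):
    """Explicit expected-count double loop."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = row[i] * col[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def test_chi_squared_flat_table():
    chi2, p = chi_squared_counts([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == 1.0


def test_chi_squared_identical_proportions():
    chi2, _ = chi_squared_counts([[10, 20], [20, 40]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_chi_squared_sex_counts_against_loop():
    """Three-group M/F counts (13/20, 12/15, 12/19) vs the loop oracle."""
    table = [[13, 12, 12], [20, 15, 19]]
    chi2, p = chi_squared_counts(table)
    assert chi2 == pytest.approx(chi2_loop_oracle(table), rel=1e-12)
    assert 0 < p < 1


def test_chi_squared_rejects_empty_margin():
    with pytest.raises(ValueError):
        chi_squared_counts([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# ANOVA / Kruskal-Wallis


def test_anova_hand_example():
    """{1,2,3},{2,3,4},{3,4,5}: SSB = 6, SSW = 6 -> F = (6/2)/(6/6) = 3."""
    f, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
    assert f == pytest.approx(3.0, rel=1e-12)
    assert p == pytest.approx(sps.f.sf(3.0, 2, 6), rel=1e-12)


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 15)
    f, _ = one_way_anova([a, b])
    t, _ = sps.ttest_ind(a, b)
    assert f == pytest.approx(t**2, rel=1e-10)


def test_anova_null_p_uniform():
    """Under exchangeable groups the ANOVA p-value is uniform."""
    rng = np.random.default_rng(17)
    ps = [one_way_anova([rng.normal(size=15) for _ in range(3)])[1]
          for _ in range(2000)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_anova_separated_group():
    rng = np.random.default_rng(2)
    groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
    _, p = one_way_anova(groups)
    assert p < 1e-6


def test_kruskal_hand_rank_formula():
    """No ties: H = 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1) by hand."""
    groups = [[1, 2], [3, 4], [5, 6]]
    h, _ = kruskal_wallis(groups)
    # ranks 1..6; group mean ranks 1.5, 3.5, 5.5
    expected = 12.0 / (6 * 7) * (2 * 1.5**2 + 2 * 3.5**2 + 2 * 5.5**2) - 3 * 7
    assert h == pytest.approx(expected, rel=1e-12)


def test_kruskal_invariant_to_monotone_transform(rng):
    groups = [rng.normal(size=10), rng.normal(1, 1, 12), rng.normal(2, 1, 9)]
    h1, _ = kruskal_wallis(groups)
    h2, _ = kruskal_wallis([np.exp(g) for g in groups])
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_kruskal_rejects_constant_data():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 1], [1, 1], [1, 1]])


def test_normality_gate_routes():
    rng = np.random.default_rng(31)
    gaussians = [rng.normal(size=30) for _ in range(3)]
    assert normality_gate(gaussians) == "anova"
    skewed = [rng.normal(size=30), rng.normal(size=30),
              np.exp(rng.normal(0, 1.5, 30))]
    assert normality_gate(skewed) == "kruskal_wallis"
    with pytest.warns(UserWarning):
        assert normality_gate([[1.0, 2.0], gaussians[0], gaussians[1]]) \
            == "kruskal_wallis"


def test_posthoc_null_keeps_pairs_nonsignificant():
    """Identical-mean groups: every pair above 0.05 in >= 90% of reps."""
    rng = np.random.default_rng(7)
    ok = 0
    reps = 200
    for _ in range(reps):
        groups = [rng.normal(size=20) for _ in range(3)]
        pw = pairwise_posthoc(groups, "anova")
        ok += all(p > 0.05 for p in pw.values())
    assert ok / reps >= 0.90


def test_posthoc_isolates_shifted_group():
    rng = np.random.default_rng(9)
    hits = 0
    reps = 100
    for _ in range(reps):
        groups = [rng.normal(0, 1, 25), rng.normal(0, 1, 25),
                  rng.normal(2.0, 1, 25)]
        pw = pairwise_posthoc(groups, "anova", ("a", "b", "c"))
        hits += (pw[("a", "c")] < 0.05 and pw[("b", "c")] < 0.05
                 and pw[("a", "b")] > 0.05)
    assert hits / reps >= 0.80
    # same shape on the rank branch
    pw = pairwise_posthoc([rng.normal(0, 1, 25), rng.normal(0, 1, 25),
                           rng.normal(3.0, 1, 25)], "kruskal_wallis",
                          ("a", "b", "c"))
    assert pw[("a", "c")] < 0.05 and pw[("b", "c")] < 0.05


def test_posthoc_degenerate_equal_data():
    pw = pairwise_posthoc([[1, 1], [1, 1], [1, 1]], "anova")
    assert all(p == 1.0 for p in pw.values())


# ---------------------------------------------------------------------------
# BH-FDR


def bh_stepup_oracle(p, q):
    """Literal step-up definition, O(m^2) adjusted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj_sorted = np.array([min(min(m * sorted_p[j] / (j + 1)
                                   for j in range(i, m)), 1.0)
                           for i in range(m)])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, reject


def test_bh_hand_examples():
    adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert rej.all()  # p(4) = 0.04 <= 4/4 * 0.05
    adj, rej = bh_fdr([0.001, 0.8], q=0.05)
    assert rej.tolist() == [True, False]
    assert adj[0] == pytest.approx(0.002)


def test_bh_matches_stepup_oracle(rng):
    for _ in range(200):
        m = rng.integers(1, 25)
        p = rng.random(m)
        adj, rej = bh_fdr(p, q=0.05)
        adj_o, rej_o = bh_stepup_oracle(p, 0.05)
        assert np.allclose(adj, adj_o, atol=1e-12)
        assert np.array_equal(rej, rej_o)


def test_bh_monotone_and_consistent(rng):
    p = np.sort(rng.random(30))
    adj, rej = bh_fdr(p, q=0.05)
    assert np.all(np.diff(adj) >= -1e-15)
    assert np.array_equal(rej, adj <= 0.05)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# region families


def test_single_region_family_fdr_equals_raw():
    tab, _ = make_cohort(CohortConfig(seed=0))
    res = regionwise_group_analysis(tab, "MK", "left", regions=("Hip (h)",))
    assert res["p_fdr"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])


def test_configured_effect_detected_others_controlled():
    """A single configured strong deficit is flagged; null regions mostly not."""
    effects = {("SCDplus", "MK", "left", "Hip (h)"): -1.5,
               ("aMCI", "MK", "left", "Hip (h)"): -1.5}
    detected, false_flags = 0, 0
    reps = 30
    for seed in range(reps):
        tab, _ = make_cohort(CohortConfig(seed=seed, effects_sd=effects))
        res = regionwise_group_analysis(tab, "MK", "left", posthoc=False)
        detected += bool(res.loc[res.region == "Hip (h)", "reject_fdr"].iloc[0])
        false_flags += int(res.loc[res.region != "Hip (h)", "reject_fdr"].sum())
    assert detected / reps >= 0.95
    assert false_flags / (reps * 11) < 0.05


def test_missing_region_column_raises():
    tab, _ = make_cohort(CohortConfig(seed=0))
    tab = tab.drop(columns=["MK__left__PCC"])
    with pytest.raises(ValueError, match="PCC"):
        regionwise_group_analysis(tab, "MK", "left")


# ---------------------------------------------------------------------------
# partial correlation


def residualize_oracle(v, covs):
    z = np.column_stack([np.ones(len(v)), covs])
    return v - z @ np.linalg.solve(z.T @ z, z.T @ v)


def test_partial_pearson_identity_case(rng):
    x = rng.normal(size=50)
    covs = rng.normal(size=(50, 2))
    r, p = partial_pearson(x, x.copy(), covs)
    assert r == pytest.approx(1.0)


def test_partial_pearson_removes_confounder():
    rng = np.random.default_rng(3)
    z = rng.normal(size=500)
    x = 2 * z + rng.normal(size=500)
    y = -3 * z + rng.normal(size=500)
    r_plain, _ = partial_pearson(x, y)
    r_adj, _ = partial_pearson(x, y, z)
    assert abs(r_plain) > 0.5  # confounded
    assert abs(r_adj) < 0.1


def test_partial_pearson_matches_residualization_oracle(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    covs = rng.normal(size=(40, 3))
    r, p = partial_pearson(x, y, covs)
    rx, ry = residualize_oracle(x, covs), residualize_oracle(y, covs)
    r_oracle = np.corrcoef(rx, ry)[0, 1]
    assert r == pytest.approx(r_oracle, abs=1e-10)
    # df = n - 2 - k t-test
    t = r_oracle * np.sqrt((40 - 2 - 3) / (1 - r_oracle**2))
    assert p == pytest.approx(2 * sps.t.sf(abs(t), 35), rel=1e-10)


def test_partial_pearson_no_covariates_is_plain_pearson(rng):
    x, y = rng.normal(size=30), rng.normal(size=30)
    r, _ = partial_pearson(x, y)
    assert r == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)


def test_partial_pearson_collinear_covariates(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    z = rng.normal(size=20)
    with pytest.raises(ValueError, match="collinear"):
        partial_pearson(x, y, np.column_stack([z, 2 * z]))


# ---------------------------------------------------------------------------
# ROC / AUC


def pair_counting_auc(scores, labels, positive):
    """Concordant-pair oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    res = roc_auc([1, 2, 3, 10, 11, 12], list("nnnppp"), "p")
    assert res.auc == 1.0 and res.ci_high == 1.0


def test_roc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    res = roc_auc(scores, labels, 1)
    assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_roc_monotone_transform_invariance(rng):
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    a1 = roc_auc(scores, labels, 1).auc
    a2 = roc_auc(np.exp(3 * scores), labels, 1).auc
    assert a1 == a2


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], ["a", "a", "a"], "a")


def test_roc_exhaustive_small_n_with_ties(rng):
    """Every label split x tie-rich score vector at n <= 6 vs the pair oracle."""
    from itertools import product

    for n in (3, 4, 5):
        for scores in product(range(3), repeat=n):
            scores = np.array(scores, dtype=float)
            for bits in range(1, 2**n - 1):
                labels = np.array([(bits >> i) & 1 for i in range(n)])
                res = roc_auc(scores, labels, 1)
                assert res.auc == pytest.approx(
                    pair_counting_auc(scores, labels, 1), abs=1e-12)


def test_combined_single_feature_equals_plain_auc(rng):
    x = rng.normal(size=60)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    x[30:] += 1.0
    combined = combined_auc(pd.DataFrame({"f": x}), labels, "b")
    single = roc_auc(x, labels, "b")
    assert combined.auc == pytest.approx(single.auc, abs=1e-12)
    assert not combined.ridge_fallback


def test_combined_auc_ridge_fallback_on_separation():
    x = np.concatenate([np.zeros(10), np.ones(10)])
    labels = np.array(["a"] * 10 + ["b"] * 10)
    res = combined_auc(pd.DataFrame({"f": x}), labels, "b")
    assert res.ridge_fallback
    assert res.auc == 1.0


def test_combined_auc_noise_feature_stability():
    """Appending a pure-noise column barely moves the combined AUC."""
    rng = np.random.default_rng(13)
    n = 2000
    labels = np.array(["a"] * n + ["b"] * n)
    x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
    base = combined_auc(pd.DataFrame({"f": x}), labels, "b").auc
    noisy = combined_auc(pd.DataFrame({"f": x, "junk": rng.normal(size=2 * n)}),
                         labels, "b").auc
    assert abs(base - noisy) < 0.03


def test_delong_ci_contains_auc(rng):
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, 80)
    labels[:2] = [0, 1]
    res = roc_auc(scores, labels, 1)
    assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
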