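"""Three-group cohort statistics for ROI imaging metrics.

Covers the study's inference stage: chi-squared for sex counts, one-way
ANOVA with a Shapiro-Wilk normality gate falling back to Kruskal-Wallis,
Tukey-Kramer / Dunn post-hoc contrasts, Benjamini-Hochberg FDR over the
12-region family of a (metric, hemisphere) pair, covariate-adjusted
Pearson correlation, and single / logistic-combined ROC analysis with
DeLong confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .roi import REGION_NAMES

__all__ = [
    "GROUPS", "chi_squared_counts", "one_way_anova", "kruskal_wallis",
    "normality_gate", "pairwise_posthoc", "bh_fdr",
    "regionwise_group_analysis", "partial_pearson",
    "roc_auc", "combined_auc", "ROCResult", "metric_column",
]

GROUPS = ("EC", "SCDplus", "aMCI")


def metric_column(metric: str, hemisphere: str, region: str) -> str:
    """Wide cohort-table column name for one (metric, hemisphere, region)."""
    return f"{metric}__{hemisphere}__{region}"


# ---------------------------------------------------------------------------
# omnibus tests


def chi_squared_counts(contingency) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty row or column")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _check_groups(values_by_group: list[np.ndarray], min_n: int = 2) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < min_n:
            raise ValueError(f"every group needs >= {min_n} values")
    return groups


def one_way_anova(values_by_group) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: F = MS_between / MS_within."""
    groups = _check_groups(values_by_group)
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise ValueError("degenerate data: zero within- and between-group variance")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def kruskal_wallis(values_by_group) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction, chi-squared reference."""
    groups = _check_groups(values_by_group)
    if len(np.unique(np.concatenate(groups))) == 1:
        raise ValueError("all values identical: ranks are degenerate")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def normality_gate(values_by_group, alpha: float = 0.05) -> str:
    """Route to "anova" or "kruskal_wallis" via per-group Shapiro-Wilk tests.

    Any group failing normality at ``alpha``, or any group too small to
    test (n < 3), routes to the rank test (the latter with a warning).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in values_by_group]
    for g in groups:
        if g.size < 3:
            warnings.warn("group with n < 3: defaulting to kruskal_wallis")
            return "kruskal_wallis"
    for g in groups:
        if np.var(g) == 0:
            return "kruskal_wallis"
        if sps.shapiro(g).pvalue < alpha:
            return "kruskal_wallis"
    return "anova"


def pairwise_posthoc(values_by_group, test_used: str,
                     group_names=GROUPS) -> dict[tuple[str, str], float]:
    """Pairwise contrasts following the omnibus test.

    ANOVA branch: Tukey-Kramer HSD.  Kruskal-Wallis branch: Dunn's rank
    test with tie correction, BH-adjusted over the pairs.  Degenerate
    all-equal data yields p = 1 for every pair.
    """
    groups = _check_groups(values_by_group)
    names = list(group_names)
    if len(groups) != len(names):
        raise ValueError("group_names must match the number of groups")
    pairs = list(combinations(range(len(groups)), 2))
    if len(np.unique(np.concatenate(groups))) == 1:
        return {(names[i], names[j]): 1.0 for i, j in pairs}
    if test_used == "anova":
        res = sps.tukey_hsd(*groups)
        return {(names[i], names[j]): float(res.pvalue[i, j]) for i, j in pairs}
    if test_used == "kruskal_wallis":
        raw = _dunn_pvalues(groups, pairs)
        adj = bh_fdr(raw)[0]
        return {(names[i], names[j]): float(p) for (i, j), p in zip(pairs, adj)}
    raise ValueError(f"unknown omnibus test: {test_used}")


def _dunn_pvalues(groups: list[np.ndarray], pairs) -> np.ndarray:
    """Dunn's z statistics on midranks with the standard tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    rank_groups = np.split(ranks, np.cumsum([g.size for g in groups])[:-1])
    mean_ranks = [rg.mean() for rg in rank_groups]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    ps = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        ps.append(2.0 * sps.norm.sf(abs(z)))
    return np.asarray(ps)


# ---------------------------------------------------------------------------
# multiplicity


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns (adjusted p-values, reject flags at level q).  Adjusted
    p_(i) = min_{j >= i} m * p_(j) / j capped at 1; rejections are exactly
    {adjusted p <= q}.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# region-family analysis


@dataclass
class GroupComparisonResult:
    region: str
    hemisphere: str
    metric: str
    test_used: str
    statistic: float
    p_raw: float
    p_fdr: float = np.nan
    pairwise_p: dict = field(default_factory=dict)
    pairwise_p_fdr: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)


def regionwise_group_analysis(cohort: pd.DataFrame, metric: str,
                              hemisphere: str, q: float = 0.05,
                              regions=REGION_NAMES,
                              alpha_normality: float = 0.05,
                              posthoc: bool = True) -> pd.DataFrame:
    """Three-group comparison of every region of one (metric, hemisphere).

    Per region: Shapiro-Wilk gate -> ANOVA or Kruskal-Wallis -> pairwise
    post-hoc.  BH-FDR is applied across the regions as one family, to the
    omnibus p-values and, separately, to each pairwise contrast's p-values
    (both adjusted columns are reported alongside the raw ones).
    ``posthoc=False`` skips the pairwise contrasts (omnibus-only sweeps,
    e.g. large simulation studies).
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table needs a 'group' column")
    results: list[GroupComparisonResult] = []
    for region in regions:
        col = metric_column(metric, hemisphere, region)
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col}")
        by_group = [cohort.loc[cohort["group"] == g, col].to_numpy()
                    for g in GROUPS]
        test = normality_gate(by_group, alpha=alpha_normality)
        if test == "anova":
            stat, p = one_way_anova(by_group)
        else:
            stat, p = kruskal_wallis(by_group)
        pw = pairwise_posthoc(by_group, test) if posthoc else {}
        results.append(GroupComparisonResult(
            region=region, hemisphere=hemisphere, metric=metric,
            test_used=test, statistic=stat, p_raw=p, pairwise_p=pw,
            group_means={g: float(np.mean(v)) for g, v in zip(GROUPS, by_group)},
        ))
    p_adj, reject = bh_fdr([r.p_raw for r in results], q=q)
    pairs = list(combinations(GROUPS, 2)) if posthoc else []
    pw_adj = {pair: bh_fdr([r.pairwise_p[pair] for r in results], q=q)[0]
              for pair in pairs}
    rows = []
    for i, r in enumerate(results):
        row = {
            "region": r.region, "hemisphere": r.hemisphere, "metric": r.metric,
            "test_used": r.test_used, "statistic": r.statistic,
            "p_raw": r.p_raw, "p_fdr": float(p_adj[i]),
            "reject_fdr": bool(reject[i]),
        }
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        for pair in pairs:
            tag = f"{pair[0]}_vs_{pair[1]}"
            row[f"p_{tag}"] = r.pairwise_p[pair]
            row[f"p_fdr_{tag}"] = float(pw_adj[pair][i])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate-adjusted correlation


def partial_pearson(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualized on an intercept plus the covariate
    columns by least squares; the correlation of the residuals is tested
    with df = n - 2 - k (k covariates).  With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        z = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        z = np.column_stack([np.ones(n), cov])
    k = z.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(z, y, rcond=None)
    rx = x - z @ beta_x
    ry = y - z @ beta_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("zero residual variance")
    r = float(np.sum(rx * ry) / denom)
    df = n - 2 - k
    r_c = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    positive_class: object
    features: list
    weights: dict | None = None
    ridge_fallback: bool = False


def _midrank_auc(scores: np.ndarray, is_pos: np.ndarray) -> float:
    ranks = sps.rankdata(scores)  # midranks: ties get half credit
    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_ci(scores: np.ndarray, is_pos: np.ndarray,
               auc: float, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the Mann-Whitney AUC via placement values."""
    pos = scores[is_pos]
    neg = scores[~is_pos]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa (midranks)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    half = zcrit * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_auc(scores, labels, positive_class) -> ROCResult:
    """AUC by the Mann-Whitney statistic (ties half credit), DeLong 95% CI.

    ``positive_class`` must be named explicitly; the AUC is never flipped.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    is_pos = labels == positive_class
    if is_pos.all() or not is_pos.any():
        raise ValueError("both classes must be present")
    auc = _midrank_auc(scores, is_pos)
    lo, hi = _delong_ci(scores, is_pos, auc)
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi,
                     positive_class=positive_class, features=["score"])


def combined_auc(feature_table: pd.DataFrame, labels, positive_class,
                 max_iter: int = 200) -> ROCResult:
    """Logistic-regression combined score over several features, then ROC.

    Features are standardized (zero mean, unit SD); the logistic model is
    fitted by unpenalized maximum likelihood; its fitted probabilities are
    the combined score.  On separation or non-convergence the fit falls
    back to a lightly ridge-penalized logistic regression (penalty 1e-4)
    and the result is flagged.
    """
    import statsmodels.api as sm

    feats = pd.DataFrame(feature_table)
    if feats.shape[1] < 1:
        raise ValueError("need at least one feature column")
    labels = np.asarray(labels).ravel()
    y = (labels == positive_class).astype(float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    x = feats.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    xs = (x - x.mean(axis=0)) / sd
    design = sm.add_constant(xs, has_constant="add")

    ridge_used = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=max_iter)
            if fit.mle_retvals.get("converged", False) and \
                    np.all(np.isfinite(fit.params)) and \
                    np.max(np.abs(fit.params)) < 1e3:
                params = np.asarray(fit.params)
        except Exception:
            params = None
    if params is None:
        from sklearn.linear_model import LogisticRegression

        ridge_used = True
        clf = LogisticRegression(C=1.0 / 1e-4, max_iter=5000)
        clf.fit(xs, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])

    logits = design @ params
    scores = 1.0 / (1.0 + np.exp(-logits))
    is_pos = y.astype(bool)
    auc = _midrank_auc(scores, is_pos)
    lo, hi = _delong_ci(scores, is_pos, auc)
    names = list(feats.columns)
    weights = {"intercept": float(params[0])}
    weights.update({name: float(w) for name, w in zip(names, params[1:])})
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi,
                     positive_class=positive_class, features=names,
                     weights=weights, ridge_fallback=ridge_used)
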