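"""Evaluation battery for scored cohorts.

ROC/AUC against simulation ground-truth labels, operating points with
Wilson intervals, risk-band stratification summaries, factor correlation
structure (Fisher-z intervals, VIF) and the sport comparison (one-way
ANOVA with eta^2 / omega^2, Kruskal-Wallis with epsilon^2, Tukey HSD and
Bonferroni pairwise tests, plus distributional diagnostics).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.proportion import proportion_confint

from .scoring import RISK_CATEGORIES, classify_risk_array

__all__ = [
    "RocResult",
    "OperatingPoint",
    "SportComparison",
    "roc_analysis",
    "operating_point",
    "risk_stratification_summary",
    "factor_correlation_analysis",
    "sport_comparison",
]

FACTOR_COLUMNS = ("E_pct", "dI_ms", "phi", "e_env", "C_pct", "S_hours", "T")


def _check_two_classes(labels: np.ndarray) -> tuple:
    labels = np.asarray(labels).astype(int)
    pos = int((labels == 1).sum())
    neg = int((labels == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("labels must contain both classes")
    return pos, neg


def auc_mannwhitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected Mann-Whitney concordance probability."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    ci_method: str = "stratified-bootstrap"
    n_pos: int = 0
    n_neg: int = 0


def _delong_ci(scores, labels, alpha=0.05):
    """DeLong (1988) covariance-based AUC confidence interval.

    Uses the placement-value formulation: V10_i = mean over negatives of
    the concordance indicator for positive i, V01_j likewise for
    negatives; var(AUC) = S10/n_pos + S01/n_neg.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    order = np.argsort(np.concatenate([pos, neg]))
    # midranks via rankdata (average method) on pooled and per-class scores
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def roc_analysis(scores, labels, *, n_boot: int = 2000, seed: int = 0,
                 method: str = "bootstrap") -> RocResult:
    """ROC curve and AUC with a confidence interval.

    The AUC is the Mann-Whitney concordance probability.  The default CI is
    a seeded stratified bootstrap (resampling positives and negatives
    separately, percentile interval); ``method='delong'`` switches to the
    DeLong asymptotic interval.  Single-class label vectors are rejected.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = _check_two_classes(labels)
    auc = auc_mannwhitney(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)

    if method == "delong":
        _, lo, hi = _delong_ci(scores, labels)
    elif method == "bootstrap" and n_boot > 0:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=n_pos, replace=True)
            ni = rng.choice(neg_idx, size=n_neg, replace=True)
            s = np.concatenate([scores[pi], scores[ni]])
            y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
            boots[b] = auc_mannwhitney(s, y)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = math.nan
    return RocResult(auc=auc, ci_low=float(lo), ci_high=float(hi),
                     fpr=fpr, tpr=tpr, thresholds=thr,
                     ci_method=method, n_pos=n_pos, n_neg=n_neg)


@dataclass
class OperatingPoint:
    """2x2-table metrics (percent) at a cutoff; positive iff score >= cutoff."""

    cutoff: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float
    sensitivity_ci: tuple = (math.nan, math.nan)
    specificity_ci: tuple = (math.nan, math.nan)
    ppv_ci: tuple = (math.nan, math.nan)
    npv_ci: tuple = (math.nan, math.nan)


def _rate_with_ci(num: int, den: int) -> tuple:
    """Percentage and Wilson 95% CI; not-available (NaN) on an empty cell."""
    if den == 0:
        return math.nan, (math.nan, math.nan)
    lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
    return 100.0 * num / den, (100.0 * lo, 100.0 * hi)


def operating_point(scores, labels, cutoff: float) -> OperatingPoint:
    """Sensitivity / specificity / PPV / NPV at ``cutoff`` with Wilson CIs.

    Undefined cells (no positives, no negatives, no predicted
    positives/negatives) yield NaN, never 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens, sens_ci = _rate_with_ci(tp, tp + fn)
    spec, spec_ci = _rate_with_ci(tn, tn + fp)
    ppv, ppv_ci = _rate_with_ci(tp, tp + fp)
    npv, npv_ci = _rate_with_ci(tn, tn + fn)
    return OperatingPoint(cutoff=cutoff, tp=tp, fn=fn, tn=tn, fp=fp,
                          sensitivity_pct=sens, specificity_pct=spec,
                          ppv_pct=ppv, npv_pct=npv,
                          sensitivity_ci=sens_ci, specificity_ci=spec_ci,
                          ppv_ci=ppv_ci, npv_ci=npv_ci)


def risk_stratification_summary(scores, score_cap: float = 2.0) -> dict:
    """Band proportions (percent) and distribution descriptives of scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty dataset")
    cats = classify_risk_array(scores, score_cap)
    n = scores.size
    proportions = {c: 100.0 * np.sum(cats == c) / n for c in RISK_CATEGORIES}
    q1, med, q3 = np.percentile(scores, [25, 50, 75])
    return {
        "n": int(n),
        "proportions_pct": proportions,
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if n > 1 else 0.0,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "min": float(scores.min()),
        "max": float(scores.max()),
        "skewness": float(stats.skew(scores)) if n > 2 else math.nan,
        "kurtosis": float(stats.kurtosis(scores)) if n > 3 else math.nan,
    }


def _pearson_with_ci(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson r with Fisher-z 95% CI; NaN triple on a constant column."""
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan, math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if n < 4 or abs(r) >= 1.0:
        return r, math.nan, math.nan
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.975)
    return r, math.tanh(z - zc * se), math.tanh(z + zc * se)


def factor_correlation_analysis(frame: pd.DataFrame,
                                score_col: str = "wase_score") -> dict:
    """Pairwise Pearson structure among factors and versus the score.

    Returns the correlation matrix with Fisher-z 95% intervals and the
    variance inflation factor of each factor from the cross-factor linear
    regressions.  Constant columns are reported not-available.
    """
    cols = [c for c in FACTOR_COLUMNS if c in frame.columns]
    if score_col in frame.columns:
        cols = cols + [score_col]
    if len(frame) < 3:
        raise ValueError("need at least 3 rows")
    if len(cols) < 2:
        raise ValueError("no factor columns present")
    data = frame[cols].to_numpy(dtype=float)

    k = len(cols)
    r_mat = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    ci_low = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    ci_high = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    for i, j in itertools.combinations(range(k), 2):
        r, lo, hi = _pearson_with_ci(data[:, i], data[:, j])
        r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
        ci_low.iloc[i, j] = ci_low.iloc[j, i] = lo
        ci_high.iloc[i, j] = ci_high.iloc[j, i] = hi

    factor_cols = [c for c in cols if c != score_col]
    vif = {}
    X = frame[factor_cols].to_numpy(dtype=float)
    keep = [i for i, c in enumerate(factor_cols) if np.std(X[:, i]) > 0]
    Xc = sm.add_constant(X[:, keep]) if keep else None
    for i, c in enumerate(factor_cols):
        if i not in keep or len(keep) < 2:
            vif[c] = math.nan
        else:
            vif[c] = float(variance_inflation_factor(Xc, keep.index(i) + 1))
    return {"r": r_mat, "ci_low": ci_low, "ci_high": ci_high, "vif": vif}


@dataclass
class SportComparison:
    f_stat: float
    df: tuple
    p_value: float
    eta2: float
    eta2_ci: tuple
    omega2: float
    kruskal_h: float
    kruskal_p: float
    epsilon2: float
    group_means: dict
    tukey: pd.DataFrame
    bonferroni: pd.DataFrame
    diagnostics: dict
    n_units: int = 0
    aggregation: str = "athlete-block"


def _eta2_ci(f_obs: float, df1: int, df2: int, conf: float = 0.95) -> tuple:
    """Noncentral-F inversion CI for eta^2 (pivot on the noncentrality)."""
    from scipy.optimize import brentq

    n_total = df1 + df2 + 1
    alpha = 1.0 - conf

    def coverage(nc):
        return stats.ncf.cdf(f_obs, df1, df2, nc)

    # upper noncentrality: coverage = alpha/2; lower: coverage = 1 - alpha/2
    hi_nc = 0.0
    if coverage(0.0) > alpha / 2:
        upper = 10.0
        while coverage(upper) > alpha / 2 and upper < 1e6:
            upper *= 2
        if coverage(upper) <= alpha / 2:
            hi_nc = brentq(lambda nc: coverage(nc) - alpha / 2, 0.0, upper)
    lo_nc = 0.0
    if coverage(0.0) > 1 - alpha / 2:
        upper = 10.0
        while coverage(upper) > 1 - alpha / 2 and upper < 1e6:
            upper *= 2
        lo_nc = brentq(lambda nc: coverage(nc) - (1 - alpha / 2), 0.0, upper)
    to_eta2 = lambda nc: nc / (nc + n_total)
    return (to_eta2(lo_nc), to_eta2(hi_nc))


def aggregate_athlete_blocks(frame: pd.DataFrame, block_s: float = 600.0,
                             score_col: str = "wase_score") -> pd.DataFrame:
    """Per-athlete per-time-block mean scores (the ANOVA analysis units).

    With the default 60-minute session and 10-minute blocks this yields
    six units per athlete, i.e. 360 units for the default cohort.
    """
    df = frame.copy()
    df["_block"] = (df["timestamp_ms"] / 1000.0 // block_s).astype(int)
    out = (df.groupby(["athlete_id", "sport", "_block"], observed=True)[score_col]
             .mean().reset_index())
    return out.rename(columns={score_col: "score", "_block": "block"})


def sport_comparison(dataset, aggregation: str = "athlete-block",
                     block_s: float = 600.0) -> SportComparison:
    """One-way comparison of scores across sports.

    ``aggregation='athlete-block'`` (default) averages each athlete's score
    within consecutive time blocks and treats those means as the analysis
    units; ``'athlete'`` uses one mean per athlete; ``'none'`` uses raw
    rows.  Reports the ANOVA F, eta^2 (with noncentral-F CI), omega^2,
    Kruskal-Wallis H with epsilon^2, Tukey HSD and Bonferroni-adjusted
    pairwise t-tests (6 comparisons), and Shapiro-Wilk / Levene /
    Breusch-Pagan diagnostics computed on the aggregated units.
    """
    frame = dataset.frame if hasattr(dataset, "frame") else dataset
    if aggregation == "athlete-block":
        units = aggregate_athlete_blocks(frame, block_s=block_s)
    elif aggregation == "athlete":
        units = aggregate_athlete_blocks(frame, block_s=math.inf)
    elif aggregation == "none":
        units = frame.rename(columns={"wase_score": "score"})[["sport", "score"]]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    groups = {s: g["score"].to_numpy(dtype=float)
              for s, g in units.groupby("sport", observed=True)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 sports with >=2 aggregated units each")

    values = [v for v in groups.values()]
    all_scores = np.concatenate(values)
    n_total = all_scores.size
    k = len(values)
    grand = all_scores.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_total = float(((all_scores - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    df1, df2 = k - 1, n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f_stat, p = (0.0, 1.0) if ms_between == 0 else (math.inf, 0.0)
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df1, df2))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    omega2 = ((ss_between - df1 * ms_within) / (ss_total + ms_within)
              if (ss_total + ms_within) > 0 else 0.0)
    omega2 = max(0.0, omega2)
    try:
        eta2_ci = _eta2_ci(f_stat, df1, df2) if math.isfinite(f_stat) else (0.0, 1.0)
    except Exception:
        eta2_ci = (math.nan, math.nan)

    if all(np.ptp(v) == 0 for v in values) and np.ptp(all_scores) == 0:
        kr_h, kr_p = 0.0, 1.0
    else:
        kr_h, kr_p = stats.kruskal(*values)
    epsilon2 = (kr_h - k + 1) / (n_total - k) if n_total > k else math.nan

    tukey_res = pairwise_tukeyhsd(units["score"].to_numpy(),
                                  units["sport"].to_numpy(), alpha=0.05)
    tukey = pd.DataFrame(tukey_res.summary().data[1:],
                         columns=tukey_res.summary().data[0])

    pairs = []
    n_pairs = k * (k - 1) // 2
    for a, b in itertools.combinations(sorted(groups), 2):
        t, pu = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        pairs.append({"group1": a, "group2": b,
                      "mean_diff": float(groups[a].mean() - groups[b].mean()),
                      "t": float(t), "p_unadjusted": float(pu),
                      "p_bonferroni": float(min(1.0, pu * n_pairs))})
    bonf = pd.DataFrame(pairs)

    resid = np.concatenate([v - v.mean() for v in values])
    diagnostics = {}
    try:
        w, wp = stats.shapiro(resid) if 3 <= len(resid) <= 5000 else (math.nan, math.nan)
    except Exception:
        w, wp = math.nan, math.nan
    diagnostics["shapiro_w"], diagnostics["shapiro_p"] = float(w), float(wp)
    lev_f, lev_p = stats.levene(*values, center="mean")
    diagnostics["levene_f"], diagnostics["levene_p"] = float(lev_f), float(lev_p)
    dummies = pd.get_dummies(units["sport"], drop_first=True, dtype=float)
    X = sm.add_constant(dummies.to_numpy())
    try:
        bp_lm, bp_lm_p, _, _ = het_breuschpagan(
            units["score"].to_numpy() - X @ np.linalg.lstsq(
                X, units["score"].to_numpy(), rcond=None)[0], X)
    except Exception:
        bp_lm, bp_lm_p = math.nan, math.nan
    diagnostics["breusch_pagan_chi2"] = float(bp_lm)
    diagnostics["breusch_pagan_p"] = float(bp_lm_p)
    diagnostics["skewness"] = float(stats.skew(units["score"]))
    diagnostics["kurtosis"] = float(stats.kurtosis(units["score"]))

    return SportComparison(
        f_stat=float(f_stat), df=(df1, df2), p_value=p,
        eta2=float(eta2), eta2_ci=eta2_ci, omega2=float(omega2),
        kruskal_h=float(kr_h), kruskal_p=float(kr_p), epsilon2=float(epsilon2),
        group_means={s: float(v.mean()) for s, v in groups.items()},
        tukey=tukey, bonferroni=bonf, diagnostics=diagnostics,
        n_units=int(n_total), aggregation=aggregation)
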