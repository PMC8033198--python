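"""Diagnostic-performance statistics: ROC/AUC, Youden operating point,
confusion metrics with CIs, DeLong and Wilcoxon comparisons, agreement
statistics, decision-curve analysis, subgroups, and baseline-table tests.

Positive class convention: the malignant label is 1 and a test is "positive"
when the model output is at or above the operating threshold.  Proportion CIs
are Clopper-Pearson exact; AUC and likelihood-ratio CIs use a stratified
nonparametric percentile bootstrap (B = 2000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "ROCResult",
    "DiagnosticsRow",
    "DCAResult",
    "roc_auc",
    "youden_threshold",
    "confusion_metrics",
    "diagnostics_from_scores",
    "proportion_ci",
    "bootstrap_ci",
    "delong_test",
    "wilcoxon_signed_rank",
    "weighted_kappa",
    "icc_2_1",
    "net_benefit_curve",
    "subgroup_indices",
    "baseline_table",
]


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_binary(labels: np.ndarray) -> Tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Full ROC curve; AUC equals the Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_binary(labels)

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    sens = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]

    ranks = rankdata(scores)
    auc = float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=1.0 - fpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_threshold(roc: ROCResult) -> Tuple[float, float, float]:
    """Threshold maximizing sens + spec - 1; ties resolved toward higher
    specificity (i.e., the more conservative operating point)."""
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.flatnonzero(j == j.max())
    k = best[np.argmax(roc.specificities[best])]
    return float(roc.thresholds[k]), float(roc.sensitivities[k]), float(roc.specificities[k])


# ---------------------------------------------------------------------------
# Confusion-matrix metrics


@dataclass
class DiagnosticsRow:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    auc: Optional[float] = None
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    flags: Dict[str, str] = field(default_factory=dict)

    def as_percent_row(self) -> Dict[str, float]:
        """Point estimates on the reporting scale: percentages and LRs to one
        decimal, AUC to two."""
        row = {
            "sensitivity_pct": round(self.sensitivity * 100, 1),
            "specificity_pct": round(self.specificity * 100, 1),
            "ppv_pct": round(self.ppv * 100, 1),
            "npv_pct": round(self.npv * 100, 1),
            "plr": round(self.plr, 1),
            "nlr": round(self.nlr, 1),
        }
        if self.auc is not None:
            row["auc"] = round(self.auc, 2)
        return row


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticsRow:
    """Point estimates from confusion counts; undefined metrics are flagged."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    flags: Dict[str, str] = {}

    def ratio(num, den, name):
        if den == 0:
            flags[name] = "undefined (zero denominator)"
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    plr = ratio(sens, 1 - spec, "plr") if not np.isnan(sens) and not np.isnan(spec) else float("nan")
    nlr = ratio(1 - sens, spec, "nlr") if not np.isnan(sens) and not np.isnan(spec) else float("nan")
    return DiagnosticsRow(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, plr=plr, nlr=nlr, flags=flags
    )


def proportion_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Clopper-Pearson exact CI for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Stratified nonparametric percentile bootstrap CI of a score metric."""
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        idx = np.r_[rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
        vals[b] = metric_fn(scores[idx], labels[idx])
    alpha = 1 - level
    return float(np.percentile(vals, 100 * alpha / 2)), float(np.percentile(vals, 100 * (1 - alpha / 2)))


def diagnostics_from_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: Optional[float] = None,
    ci: bool = True,
    B: int = 2000,
    seed: int = 0,
) -> DiagnosticsRow:
    """Full diagnostics row at the Youden-optimal (or given) threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    roc = roc_auc(scores, labels)
    if threshold is None:
        threshold, _, _ = youden_threshold(roc)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    row = confusion_metrics(tp, fp, tn, fn)
    row.auc = roc.auc
    row.flags["threshold"] = repr(float(threshold))
    if ci:
        row.ci["sensitivity"] = proportion_ci(tp, tp + fn)
        row.ci["specificity"] = proportion_ci(tn, tn + fp)
        if tp + fp > 0:
            row.ci["ppv"] = proportion_ci(tp, tp + fp)
        if tn + fn > 0:
            row.ci["npv"] = proportion_ci(tn, tn + fn)
        row.ci["auc"] = bootstrap_ci(lambda s, y: roc_auc(s, y).auc, scores, labels, B=B, seed=seed)
    return row


# ---------------------------------------------------------------------------
# Paired comparisons


def _placements(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement values via midranks (ties count 1/2)
    all_ranks = rankdata(np.r_[pos, neg])
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> Dict[str, float]:
    """Paired DeLong comparison of two correlated AUCs on the same patients."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("paired scores must align with labels")
    _check_binary(labels)
    v10a, v01a, auc_a = _placements(a, labels)
    v10b, v01b, auc_b = _placements(b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    out = {"auc_a": auc_a, "auc_b": auc_b, "var_a": cov[0, 0], "var_b": cov[1, 1]}
    if var_diff <= 0:
        out.update({"z": 0.0, "p": 1.0, "degenerate": True})
        return out
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    out.update({"z": float(z), "p": float(2 * stats.norm.sf(abs(z))), "degenerate": False})
    return out


def delong_auc_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01, _ = _placements(scores, labels)
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def wilcoxon_signed_rank(
    paired_values_a: Sequence[float], paired_values_b: Sequence[float]
) -> Dict[str, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Uses the exact null distribution when <= 25 nonzero differences (and no
    ties among them), the tie-corrected normal approximation otherwise.
    Zero differences are dropped; all-zero input returns p = 1 with a flag.
    """
    a = np.asarray(paired_values_a, dtype=float)
    b = np.asarray(paired_values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return {"W": 0.0, "p": 1.0, "n": 0, "degenerate": True}
    if nz.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    mode = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", mode=mode, correction=False)
    return {"W": float(res.statistic), "p": float(res.pvalue), "n": int(nz.size), "degenerate": False}


# ---------------------------------------------------------------------------
# Agreement


def weighted_kappa(
    ratings_a: Sequence[int],
    ratings_b: Sequence[int],
    weights: str = "linear",
    categories: Optional[Sequence[int]] = None,
) -> float:
    """Weighted kappa: 1 - sum(w*O) / sum(w*E), disagreement weights
    ``|i-j|/(K-1)`` (linear, default) or ``(|i-j|/(K-1))^2`` (quadratic)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("ratings must be paired")
    cats = np.asarray(categories if categories is not None else np.union1d(a, b))
    k = cats.size
    if k < 2:
        raise ValueError("kappa undefined: fewer than 2 categories in use")
    index = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    obs /= obs.sum()
    pa = obs.sum(axis=1)
    pb = obs.sum(axis=0)
    exp = np.outer(pa, pb)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(ii - jj) / (k - 1)
    if weights == "quadratic":
        w = w**2
    elif weights != "linear":
        raise ValueError("weights must be 'linear' or 'quadratic'")
    denom = (w * exp).sum()
    if denom == 0:
        raise ValueError("kappa undefined: no expected disagreement")
    return float(1.0 - (w * obs).sum() / denom)


def icc_2_1(measurements: np.ndarray) -> Dict[str, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is subjects x raters.  Computed from the two-way ANOVA
    mean squares; zero between-subject variance is flagged.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 5:
        raise ValueError("need a subjects x raters matrix with >= 5 subjects, >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0
    # msr <= mse means no detectable between-subject variance
    return {"icc": float(icc), "msr": msr, "msc": msc, "mse": mse, "degenerate": bool(msr <= mse)}


# ---------------------------------------------------------------------------
# Decision curve analysis


@dataclass
class DCAResult:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray


def net_benefit_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Optional[np.ndarray] = None,
) -> DCAResult:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt), calling positive when
    prob >= pt; includes treat-all and treat-none reference curves."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    prevalence = labels.mean()
    odds = thresholds / (1 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        nb_model[i] = tp / n - fp / n * odds[i]
    nb_all = prevalence - (1 - prevalence) * odds
    return DCAResult(
        thresholds=thresholds,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=np.zeros_like(thresholds),
    )


# ---------------------------------------------------------------------------
# Subgroups and baseline table


def subgroup_indices(cohort, afp_band: str = "<20") -> np.ndarray:
    """Indices of the normal-AFP malignant patients plus all benign patients."""
    keep = []
    for i, p in enumerate(cohort.patients):
        if p.label == 0 or p.covariates.get("afp_band") == afp_band:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    labels = cohort.labels()[idx]
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("subgroup must contain both classes")
    return idx


def _is_numericish(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series)


def baseline_table(cohort, normality_alpha: float = 0.05) -> pd.DataFrame:
    """Per-covariate group comparison.

    Continuous covariates: Welch t when both groups pass a Shapiro normality
    check, Mann-Whitney otherwise.  Categorical: Pearson chi-squared unless an
    expected cell falls below 5, in which case Fisher's exact test (2x2; wider
    tables fall back to chi-squared with a flag).
    """
    frame = cohort.covariate_frame()
    y = frame.pop("label").to_numpy()
    rows = []
    for col in frame.columns:
        series = frame[col]
        g0 = series[y == 0]
        g1 = series[y == 1]
        flag = ""
        if _is_numericish(series) and series.nunique() > 6:
            if len(g0) >= 3 and len(g1) >= 3:
                normal = (
                    stats.shapiro(g0).pvalue > normality_alpha
                    and stats.shapiro(g1).pvalue > normality_alpha
                )
            else:
                normal = False
            if normal:
                test = "welch_t"
                stat, p = stats.ttest_ind(g0, g1, equal_var=False)
            else:
                test = "mann_whitney"
                stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        else:
            tab = pd.crosstab(series, y)
            if tab.shape[0] < 2:
                rows.append({"covariate": col, "test": "none", "statistic": np.nan, "p": np.nan, "flag": "constant covariate"})
                continue
            chi2, p_chi, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
            if (expected < 5).any():
                if tab.shape == (2, 2):
                    test = "fisher"
                    stat, p = stats.fisher_exact(tab.to_numpy())
                else:
                    test = "chi2"
                    stat, p = chi2, p_chi
                    flag = "expected cell < 5; Fisher unavailable for r x c"
            else:
                test = "chi2"
                stat, p = chi2, p_chi
        rows.append({"covariate": col, "test": test, "statistic": float(stat), "p": float(p), "flag": flag})
    return pd.DataFrame(rows).set_index("covariate")
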