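"""Feature selection: correlation filter, univariate-AUC filter,
z-normalization, and L1-penalized logistic regression with the 1-SE rule.

Stage order is fixed — correlation filter, then AUC filter, then
z-normalization, then LASSO — and each stage keeps a subset of the previous
stage's columns.  All statistics are estimated on training data only; the
fitted normalization is applied unchanged to any other split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    kept_after_corr: List[str]
    kept_after_auc: List[str]
    lasso_selected: List[str]
    lambda_path: List[float]
    chosen_lambda: float
    normalization_params: Dict[str, Tuple[float, float]]
    cv_mean_deviance: List[float] = field(default_factory=list)
    cv_se_deviance: List[float] = field(default_factory=list)
    empty_selection: bool = False

    def __post_init__(self) -> None:
        if not set(self.lasso_selected) <= set(self.kept_after_auc) <= set(self.kept_after_corr):
            raise ValueError("selection stages must be nested subsets")
        if self.lambda_path and self.chosen_lambda not in self.lambda_path:
            raise ValueError("chosen_lambda must come from the lambda path")

    def to_dict(self) -> dict:
        return {
            "kept_after_corr": self.kept_after_corr,
            "kept_after_auc": self.kept_after_auc,
            "lasso_selected": self.lasso_selected,
            "lambda_path": self.lambda_path,
            "chosen_lambda": self.chosen_lambda,
            "normalization_params": {k: list(v) for k, v in self.normalization_params.items()},
            "cv_mean_deviance": self.cv_mean_deviance,
            "cv_se_deviance": self.cv_se_deviance,
            "empty_selection": self.empty_selection,
        }


def univariate_auc(x: Sequence[float], y: Sequence[int]) -> float:
    """Direction-folded Mann-Whitney AUC, ties counted half; in [0.5, 1]."""
    return max(_raw_auc(x, y), 1.0 - _raw_auc(x, y))


def _raw_auc(x: Sequence[float], y: Sequence[int]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _univariate_aucs(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Vectorized folded AUC for every column."""
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = np.apply_along_axis(rankdata, 0, X.to_numpy(dtype=float))
    raw = (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)
    return pd.Series(np.maximum(raw, 1 - raw), index=X.columns)


def correlation_filter(
    X: pd.DataFrame, threshold: float = 0.95, ranking: Optional[pd.Series] = None
) -> List[str]:
    """Greedy redundancy filter.

    Features are visited in descending ``ranking`` order (column order breaks
    ties deterministically) and dropped when their absolute Pearson
    correlation with any already-kept feature exceeds ``threshold``.
    Zero-variance features are dropped first since their correlation is
    undefined.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if X.shape[0] < 2:
        raise ValueError("at least 2 rows are required")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("dropping %d zero-variance features before correlation filter", degenerate.sum())
    cols = np.flatnonzero(~degenerate)
    if cols.size == 0:
        return []
    if ranking is not None:
        order = np.argsort(-ranking.iloc[cols].to_numpy(), kind="stable")
    else:
        order = np.arange(cols.size)
    z = (arr[:, cols] - arr[:, cols].mean(axis=0)) / sd[cols]
    n = arr.shape[0]

    kept: List[int] = []
    for idx in order:
        if not kept:
            kept.append(idx)
            continue
        r = np.abs(z[:, kept].T @ z[:, idx]) / n
        if r.max() <= threshold:
            kept.append(idx)
    kept_names = [X.columns[cols[i]] for i in sorted(kept)]
    return kept_names


def auc_filter(X: pd.DataFrame, y: Sequence[int], min_auc: float = 0.6) -> List[str]:
    """Keep features whose folded univariate AUC is >= ``min_auc`` (inclusive)."""
    aucs = _univariate_aucs(X, np.asarray(y))
    kept = [c for c in X.columns if aucs[c] >= min_auc]
    logger.info("AUC filter removed %d of %d features", X.shape[1] - len(kept), X.shape[1])
    return kept


def zscore(
    X_train: pd.DataFrame, X_apply: Optional[pd.DataFrame] = None
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame], Dict[str, Tuple[float, float]]]:
    """Normalize by the training mean and population SD of each column.

    Zero-SD training columns are dropped (with a warning) from both outputs.
    """
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} zero-variance columns in z-normalization")
    cols = X_train.columns[~bad]
    params = {c: (float(mean[c]), float(sd[c])) for c in cols}
    Xt = (X_train[cols] - mean[cols]) / sd[cols]
    Xa = None
    if X_apply is not None:
        Xa = (X_apply[cols] - mean[cols]) / sd[cols]
    return Xt, Xa, params


def apply_zscore(X: pd.DataFrame, params: Dict[str, Tuple[float, float]]) -> pd.DataFrame:
    cols = list(params)
    mean = pd.Series({c: params[c][0] for c in cols})
    sd = pd.Series({c: params[c][1] for c in cols})
    return (X[cols] - mean) / sd


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int, ratio: float = 1e-4) -> np.ndarray:
    n = X.shape[0]
    p0 = y.mean()
    lmax = np.abs(X.T @ (y - p0)).max() / n
    lmax = max(lmax, 1e-8)
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * sum(logloss) + |w|_1; glmnet-style lambda maps to
    # C = 1 / (n * lambda)
    n = X.shape[0]
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=100, tol=1e-4,
        random_state=0,
    )
    with warnings.catch_warnings():
        # at the weakly penalized end of the path on near-separable or pure
        # noise data liblinear may stop at max_iter; the CV deviance there is
        # far from the optimum anyway, so the path choice is unaffected
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _deviance(model: LogisticRegression, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)[:, 1]
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(
    X: pd.DataFrame,
    y: Sequence[int],
    n_folds: int = 10,
    n_repeats: int = 50,
    rule: str = "1se",
    seed: int = 0,
    n_lambda: int = 100,
) -> Tuple[List[str], dict]:
    """Cross-validated L1 logistic path selection.

    The CV criterion is the mean held-out binomial deviance over all
    ``n_folds * n_repeats`` folds; the SE is the standard error of those
    per-fold means.  Under the 1-SE rule the chosen lambda is the largest one
    whose mean deviance is within one SE of the minimum; ``rule='min'`` picks
    the minimizer itself.  Returns (selected names, diagnostics dict).
    """
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=int)
    if set(np.unique(ya)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    minority = int(min((ya == 0).sum(), (ya == 1).sum()))
    if n_folds > minority:
        logger.warning("reducing LASSO CV folds from %d to %d (minority class size)", n_folds, minority)
        n_folds = minority
    if n_folds < 2:
        raise ValueError("need at least 2 patients per class for cross-validation")
    lambdas = _lambda_path(Xa, ya, n_lambda)
    fold_devs = []  # one row of per-lambda deviances per (repeat, fold)
    rng = np.random.SeedSequence(seed)
    for rep_ss in rng.spawn(n_repeats):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for tr, te in skf.split(Xa, ya):
            devs = np.empty(lambdas.size)
            for k, lam in enumerate(lambdas):
                model = _fit_l1(Xa[tr], ya[tr], lam)
                devs[k] = _deviance(model, Xa[te], ya[te])
            fold_devs.append(devs)
    fold_devs = np.asarray(fold_devs)
    mean_dev = fold_devs.mean(axis=0)
    se_dev = fold_devs.std(axis=0, ddof=1) / np.sqrt(fold_devs.shape[0])

    k_min = int(np.argmin(mean_dev))
    if rule == "min":
        k_chosen = k_min
    else:
        limit = mean_dev[k_min] + se_dev[k_min]
        # lambdas are descending, so the first index within the limit is the
        # largest qualifying lambda
        k_chosen = int(np.flatnonzero(mean_dev <= limit)[0])
    chosen = float(lambdas[k_chosen])

    final = _fit_l1(Xa, ya, chosen)
    nonzero = np.flatnonzero(np.abs(final.coef_[0]) > 0)
    selected = [X.columns[i] for i in nonzero]
    info = {
        "lambda_path": [float(v) for v in lambdas],
        "chosen_lambda": chosen,
        "cv_mean_deviance": [float(v) for v in mean_dev],
        "cv_se_deviance": [float(v) for v in se_dev],
        "n_selected": len(selected),
        "empty_selection": len(selected) == 0,
    }
    if not selected:
        logger.warning("LASSO selected no features at lambda=%.4g", chosen)
    else:
        logger.info("LASSO selected %d features at lambda=%.4g", len(selected), chosen)
    return selected, info


def epv_check(n_events: int, n_covariates: int) -> bool:
    """Events-per-variable rule: warn when events < 10 x covariates."""
    if n_covariates > 0 and n_events < 10 * n_covariates:
        warnings.warn(
            f"events-per-variable rule violated: {n_events} events for "
            f"{n_covariates} covariates (rule requires >= {10 * n_covariates})"
        )
        return False
    return True


def select_features(
    X_train: pd.DataFrame,
    y_train: Sequence[int],
    corr_threshold: float = 0.95,
    min_auc: float = 0.6,
    n_folds: int = 10,
    n_repeats: int = 50,
    rule: str = "1se",
    seed: int = 0,
    n_lambda: int = 100,
) -> SelectionResult:
    """The full chain: correlation filter -> AUC filter -> z-score -> LASSO."""
    y = np.asarray(y_train, dtype=int)
    aucs = _univariate_aucs(X_train, y)
    kept_corr = correlation_filter(X_train, threshold=corr_threshold, ranking=aucs)
    kept_auc = auc_filter(X_train[kept_corr], y, min_auc=min_auc)
    if not kept_auc:
        return SelectionResult(
            kept_after_corr=kept_corr,
            kept_after_auc=[],
            lasso_selected=[],
            lambda_path=[],
            chosen_lambda=float("nan"),
            normalization_params={},
            empty_selection=True,
        )
    Xn, _, params = zscore(X_train[kept_auc])
    selected, info = lasso_select(
        Xn, y, n_folds=n_folds, n_repeats=n_repeats, rule=rule, seed=seed, n_lambda=n_lambda
    )
    epv_check(int((y == 1).sum()), len(selected))
    return SelectionResult(
        kept_after_corr=kept_corr,
        kept_after_auc=kept_auc,
        lasso_selected=selected,
        lambda_path=info["lambda_path"],
        chosen_lambda=info["chosen_lambda"],
        normalization_params=params,
        cv_mean_deviance=info["cv_mean_deviance"],
        cv_se_deviance=info["cv_se_deviance"],
        empty_selection=info["empty_selection"],
    )
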