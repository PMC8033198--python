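"""RBF-SVM models over three predictor sets (texture features, reader score,
both) with the repeated 80/20 hold-out scheme.

Kernel convention: ``k(u, v) = exp(-sigma * ||u - v||^2)`` — the kernlab
parameterization — so ``sigma`` maps directly onto scikit-learn's ``gamma``.
The alternative ``exp(-||u-v||^2 / (2*sigma^2))`` is available via
``sigma_convention='bandwidth'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from ceusomics.cohort import Cohort
from ceusomics.selection import SelectionResult, apply_zscore, select_features
from ceusomics.evaluation import roc_auc

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("ultrasomics", "reader_score", "combined")


@dataclass
class ModelSpec:
    predictor_set: str = "ultrasomics"
    C: float = 1.0
    sigma: float = 0.012
    sigma_convention: str = "kernlab"  # or 'bandwidth'
    probability_calibration: bool = True

    def __post_init__(self) -> None:
        if self.predictor_set not in PREDICTOR_SETS:
            raise ValueError(f"predictor_set must be one of {PREDICTOR_SETS}")
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")
        if self.sigma_convention not in ("kernlab", "bandwidth"):
            raise ValueError("sigma_convention must be 'kernlab' or 'bandwidth'")

    @property
    def gamma(self) -> float:
        if self.sigma_convention == "kernlab":
            return self.sigma
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class FittedModel:
    spec: ModelSpec
    svm: SVC
    feature_names: List[str]
    selection: Optional[SelectionResult] = None

    def _design(self, X: Optional[pd.DataFrame], reader: Optional[np.ndarray]) -> np.ndarray:
        blocks = []
        if self.spec.predictor_set in ("ultrasomics", "combined"):
            if self.selection is None or X is None:
                raise ValueError("feature matrix required for this predictor set")
            Xn = apply_zscore(X, self.selection.normalization_params)
            blocks.append(Xn[self.selection.lasso_selected].to_numpy(dtype=float))
        if self.spec.predictor_set in ("reader_score", "combined"):
            if reader is None:
                raise ValueError("reader scores required for this predictor set")
            blocks.append(np.asarray(reader, dtype=float)[:, None])
        return np.hstack(blocks)

    def decision_scores(self, X: Optional[pd.DataFrame], reader: Optional[np.ndarray]) -> np.ndarray:
        return self.svm.decision_function(self._design(X, reader))

    def probabilities(self, X: Optional[pd.DataFrame], reader: Optional[np.ndarray]) -> np.ndarray:
        if not self.spec.probability_calibration:
            raise ValueError("model was fitted without probability calibration")
        return self.svm.predict_proba(self._design(X, reader))[:, 1]


def train_svm(
    design: np.ndarray, y: Sequence[int], spec: ModelSpec, seed: int = 0
) -> SVC:
    """Fit the RBF SVM on an already-assembled design matrix."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    svm = SVC(
        C=spec.C,
        kernel="rbf",
        gamma=spec.gamma,
        probability=spec.probability_calibration,
        random_state=seed,
    )
    svm.fit(np.asarray(design, dtype=float), y)
    return svm


def split_cohort(
    cohort: Cohort, train_fraction: float = 0.8, stratified: bool = True, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index split, stratified by class."""
    y = cohort.labels()
    if min((y == 0).sum(), (y == 1).sum()) < 5:
        raise ValueError("both classes must have at least 5 patients to split")
    idx = np.arange(len(cohort))
    tr, va = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=y if stratified else None,
        random_state=seed,
        shuffle=True,
    )
    return np.sort(tr), np.sort(va)


def crossvalidate(
    design: np.ndarray, y: Sequence[int], spec: ModelSpec, n_folds: int = 10, seed: int = 0
) -> Dict[str, object]:
    """Stratified k-fold CV; returns pooled out-of-fold AUC and per-fold AUCs."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_folds > min((y == 0).sum(), (y == 1).sum()):
        raise ValueError("n_folds exceeds the minority class count")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    fold_aucs = []
    for tr, te in skf.split(design, y):
        svm = SVC(C=spec.C, kernel="rbf", gamma=spec.gamma, random_state=seed)
        svm.fit(design[tr], y[tr])
        scores = svm.decision_function(design[te])
        pooled[te] = scores
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_auc(scores, y[te]).auc)
    return {
        "pooled_auc": roc_auc(pooled, y).auc,
        "fold_aucs": fold_aucs,
        "oof_scores": pooled,
    }


@dataclass
class RepeatResult:
    seed: int
    train_idx: np.ndarray
    validation_idx: np.ndarray
    train_auc: float
    validation_auc: float
    cv_pooled_auc: float
    model: FittedModel
    validation_scores: np.ndarray
    validation_probs: Optional[np.ndarray]
    selection_empty: bool = False


@dataclass
class ModelReport:
    spec: ModelSpec
    per_repeat: List[RepeatResult]
    best_repeat_index: int = field(init=False)
    mean_validation_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = [r.validation_auc for r in self.per_repeat]
        self.best_repeat_index = int(np.argmax(aucs))  # ties -> lowest index
        self.mean_validation_auc = float(np.mean(aucs))

    @property
    def best(self) -> RepeatResult:
        return self.per_repeat[self.best_repeat_index]

    def selected_features(self) -> List[str]:
        best = self.best
        if best.model.selection is None:
            return []
        return list(best.model.selection.lasso_selected)

    def to_dict(self) -> dict:
        return {
            "predictor_set": self.spec.predictor_set,
            "C": self.spec.C,
            "sigma": self.spec.sigma,
            "best_repeat_index": self.best_repeat_index,
            "mean_validation_auc": self.mean_validation_auc,
            "selected_features": self.selected_features(),
            "per_repeat": [
                {
                    "seed": r.seed,
                    "train_auc": r.train_auc,
                    "validation_auc": r.validation_auc,
                    "cv_pooled_auc": r.cv_pooled_auc,
                    "n_train": int(len(r.train_idx)),
                    "n_validation": int(len(r.validation_idx)),
                    "selection_empty": r.selection_empty,
                }
                for r in self.per_repeat
            ],
        }


def _fit_one(
    cohort: Cohort,
    spec: ModelSpec,
    train_idx: np.ndarray,
    selection: Optional[SelectionResult],
    seed: int,
) -> FittedModel:
    y_tr = cohort.labels()[train_idx]
    reader = cohort.reader_scores()
    X = cohort.features
    model = FittedModel(
        spec=spec,
        svm=None,  # type: ignore[arg-type]
        feature_names=[] if selection is None else list(selection.lasso_selected),
        selection=selection,
    )
    X_tr = None if X is None else X.iloc[train_idx]
    design = model._design(X_tr, reader[train_idx])
    model.svm = train_svm(design, y_tr, spec, seed=seed)
    return model


def run_experiment(
    cohort: Cohort,
    spec: ModelSpec,
    n_repeats: int = 10,
    master_seed: int = 0,
    train_fraction: float = 0.8,
    n_folds: int = 10,
    selection_kwargs: Optional[dict] = None,
) -> ModelReport:
    """Repeated hold-out: split -> selection (train only) -> fit -> validate."""
    return run_models(
        cohort,
        [spec],
        n_repeats=n_repeats,
        master_seed=master_seed,
        train_fraction=train_fraction,
        n_folds=n_folds,
        selection_kwargs=selection_kwargs,
    )[spec.predictor_set]


def run_models(
    cohort: Cohort,
    specs: Sequence[ModelSpec],
    n_repeats: int = 10,
    master_seed: int = 0,
    train_fraction: float = 0.8,
    n_folds: int = 10,
    selection_kwargs: Optional[dict] = None,
) -> Dict[str, ModelReport]:
    """Run several predictor sets on shared splits (and shared per-split
    feature selection, which depends only on the training features/labels)."""
    selection_kwargs = dict(selection_kwargs or {})
    y = cohort.labels()
    reader = cohort.reader_scores()
    needs_features = any(s.predictor_set in ("ultrasomics", "combined") for s in specs)
    if needs_features and cohort.features is None:
        raise ValueError("cohort has no extracted features; run extraction first")

    results: Dict[str, List[RepeatResult]] = {s.predictor_set: [] for s in specs}
    ss = np.random.SeedSequence(master_seed)
    for rep, child in enumerate(ss.spawn(n_repeats)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        tr, va = split_cohort(cohort, train_fraction=train_fraction, seed=rep_seed)
        selection = None
        if needs_features:
            X_tr = cohort.features.iloc[tr]
            selection = select_features(X_tr, y[tr], seed=rep_seed, **selection_kwargs)
            if selection.empty_selection or not selection.lasso_selected:
                logger.warning("repeat %d: empty LASSO selection; feature models fall back", rep)
        for spec in specs:
            use_sel = selection if spec.predictor_set != "reader_score" else None
            eff_spec = spec
            sel_empty = False
            if spec.predictor_set in ("ultrasomics", "combined") and (
                selection is None or not selection.lasso_selected
            ):
                # fall back to the reader-score model, flagged
                eff_spec = ModelSpec(
                    predictor_set="reader_score",
                    C=spec.C,
                    sigma=spec.sigma,
                    sigma_convention=spec.sigma_convention,
                    probability_calibration=spec.probability_calibration,
                )
                use_sel = None
                sel_empty = True
            model = _fit_one(cohort, eff_spec, tr, use_sel, seed=rep_seed)
            X_all = cohort.features
            X_tr_f = None if X_all is None else X_all.iloc[tr]
            X_va_f = None if X_all is None else X_all.iloc[va]
            tr_scores = model.decision_scores(X_tr_f, reader[tr])
            va_scores = model.decision_scores(X_va_f, reader[va])
            va_probs = (
                model.probabilities(X_va_f, reader[va]) if spec.probability_calibration else None
            )
            # CV is a robustness diagnostic; clamp folds for tiny cohorts
            eff_folds = min(n_folds, int(min((y[tr] == 0).sum(), (y[tr] == 1).sum())))
            if eff_folds >= 2:
                cv = crossvalidate(
                    model._design(X_tr_f, reader[tr]), y[tr], eff_spec, n_folds=eff_folds, seed=rep_seed
                )
            else:
                cv = {"pooled_auc": float("nan")}
            results[spec.predictor_set].append(
                RepeatResult(
                    seed=rep_seed,
                    train_idx=tr,
                    validation_idx=va,
                    train_auc=roc_auc(tr_scores, y[tr]).auc,
                    validation_auc=roc_auc(va_scores, y[va]).auc,
                    cv_pooled_auc=cv["pooled_auc"],
                    model=model,
                    validation_scores=va_scores,
                    validation_probs=va_probs,
                    selection_empty=sel_empty,
                )
            )
    return {s.predictor_set: ModelReport(spec=s, per_repeat=results[s.predictor_set]) for s in specs}
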