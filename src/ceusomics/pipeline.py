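"""End-to-end orchestration: simulate -> extract -> select -> train ->
evaluate -> report, reproducible from a single master seed.

Every numeric artifact written by :func:`run` is regenerable from the
persisted intermediates alone (``features.csv`` + ``clinical.csv`` through
:func:`run_from_features`), and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ceusomics.cohort import Cohort, cohort_from_tables, load_cohort, write_cohort
from ceusomics.evaluation import (
    baseline_table,
    diagnostics_from_scores,
    net_benefit_curve,
    roc_auc,
    subgroup_indices,
    youden_threshold,
)
from ceusomics.features import default_catalogue, extract_cohort_features
from ceusomics.modeling import ModelReport, ModelSpec, PREDICTOR_SETS, run_models
from ceusomics.synthetic_data import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # 'synthetic' | 'directory'
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: Optional[str] = None
    out_dir: str = "run"
    corr_threshold: float = 0.95
    min_auc: float = 0.6
    C: float = 1.0
    sigma: float = 0.012
    n_repeats: int = 10
    train_fraction: float = 0.8
    n_folds: int = 10
    lasso_folds: int = 10
    lasso_repeats: int = 50
    n_lambda: int = 100
    master_seed: int = 0
    write_images: bool = True
    bootstrap_B: int = 2000

    def validate(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if self.mode == "directory":
            if self.input_dir is None or not Path(self.input_dir).is_dir():
                raise ValueError("directory mode requires an existing input_dir")
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")
        if not 0.5 <= self.min_auc < 1:
            raise ValueError("min_auc must be in [0.5, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _setup_logging(out_dir: Path) -> None:
    root = logging.getLogger("ceusomics")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _format_ci(ci) -> str:
    return f"({ci[0]:.3f}, {ci[1]:.3f})"


def _diagnostics_table(rows: Dict[str, object]) -> pd.DataFrame:
    records = []
    for name, row in rows.items():
        rec = {"model": name, **row.as_percent_row()}
        for metric, ci in row.ci.items():
            rec[f"{metric}_ci"] = _format_ci(ci)
        records.append(rec)
    return pd.DataFrame(records).set_index("model")


def evaluate_models(
    cohort: Cohort,
    reports: Dict[str, ModelReport],
    indices: Optional[np.ndarray] = None,
    thresholds: Optional[Dict[str, float]] = None,
    bootstrap_B: int = 2000,
    seed: int = 0,
) -> Dict[str, object]:
    """Score the best fitted model of each predictor set on ``indices`` of the
    cohort (default: everyone) without refitting.

    Returns per-model diagnostics rows, scores, probabilities, and the
    operating thresholds used (Youden on the scored subset unless supplied).
    """
    idx = np.arange(len(cohort)) if indices is None else np.asarray(indices)
    y = cohort.labels()[idx]
    reader = cohort.reader_scores()[idx]
    X = None if cohort.features is None else cohort.feature_matrix().iloc[idx]
    out: Dict[str, object] = {"rows": {}, "scores": {}, "probs": {}, "thresholds": {}}
    for name, report in reports.items():
        model = report.best.model
        scores = model.decision_scores(X, reader)
        probs = model.probabilities(X, reader) if model.spec.probability_calibration else None
        if thresholds is not None and name in thresholds:
            thr = thresholds[name]
        else:
            thr, _, _ = youden_threshold(roc_auc(scores, y))
        row = diagnostics_from_scores(scores, y, threshold=thr, B=bootstrap_B, seed=seed)
        out["rows"][name] = row
        out["scores"][name] = scores
        out["probs"][name] = probs
        out["thresholds"][name] = thr
    return out


def subgroup_eval(
    cohort: Cohort,
    reports: Dict[str, ModelReport],
    thresholds: Dict[str, float],
    afp_band: str = "<20",
    bootstrap_B: int = 2000,
    seed: int = 0,
) -> Dict[str, object]:
    """Re-evaluate the already-fitted models on the normal-AFP-malignant plus
    all-benign subgroup, at the full-cohort operating thresholds."""
    idx = subgroup_indices(cohort, afp_band=afp_band)
    return evaluate_models(
        cohort, reports, indices=idx, thresholds=thresholds, bootstrap_B=bootstrap_B, seed=seed
    )


def run_from_features(
    cohort: Cohort,
    config: RunConfig,
    out_dir: Path,
) -> Dict[str, object]:
    """Model + evaluation stages given a cohort that already has features."""
    specs = [
        ModelSpec(predictor_set=ps, C=config.C, sigma=config.sigma) for ps in PREDICTOR_SETS
    ]
    selection_kwargs = {
        "corr_threshold": config.corr_threshold,
        "min_auc": config.min_auc,
        "n_folds": config.lasso_folds,
        "n_repeats": config.lasso_repeats,
        "n_lambda": config.n_lambda,
    }
    reports = run_models(
        cohort,
        specs,
        n_repeats=config.n_repeats,
        master_seed=config.master_seed,
        train_fraction=config.train_fraction,
        n_folds=config.n_folds,
        selection_kwargs=selection_kwargs,
    )
    _write_json(out_dir / "model_report.json", {k: v.to_dict() for k, v in reports.items()})
    best_sel = reports["ultrasomics"].best.model.selection
    if best_sel is not None:
        _write_json(out_dir / "selection.json", best_sel.to_dict())

    # validation-set diagnostics of the best repeat of each model
    rows = {}
    thresholds = {}
    for name, report in reports.items():
        best = report.best
        va_idx = best.validation_idx
        y_va = cohort.labels()[va_idx]
        row = diagnostics_from_scores(
            best.validation_scores, y_va, B=config.bootstrap_B, seed=config.master_seed
        )
        rows[name] = row
        thresholds[name] = float(row.flags["threshold"])
        pd.DataFrame(
            {
                "patient_id": [cohort.ids[i] for i in va_idx],
                "label": y_va,
                "score": best.validation_scores,
                "prob": best.validation_probs if best.validation_probs is not None else np.nan,
            }
        ).to_csv(out_dir / f"scores_{name}.csv", index=False)
        roc = roc_auc(best.validation_scores, y_va)
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivities,
                "specificity": roc.specificities,
            }
        ).to_csv(out_dir / f"roc_{name}.csv", index=False)
        if best.validation_probs is not None:
            dca = net_benefit_curve(best.validation_probs, y_va)
            pd.DataFrame(
                {
                    "threshold": dca.thresholds,
                    "net_benefit_model": dca.net_benefit_model,
                    "net_benefit_all": dca.net_benefit_all,
                    "net_benefit_none": dca.net_benefit_none,
                }
            ).to_csv(out_dir / f"dca_{name}.csv", index=False)
    _diagnostics_table(rows).to_csv(out_dir / "diagnostics_validation.csv")

    # subgroup re-evaluation (no refit) at the validation thresholds
    try:
        sub = subgroup_eval(
            cohort, reports, thresholds, bootstrap_B=config.bootstrap_B, seed=config.master_seed
        )
        _diagnostics_table(sub["rows"]).to_csv(out_dir / "diagnostics_subgroup.csv")
    except ValueError as exc:
        logger.warning("subgroup evaluation skipped: %s", exc)
        sub = None

    baseline = baseline_table(cohort)
    baseline.to_csv(out_dir / "baseline_table.csv")
    return {"reports": reports, "rows": rows, "thresholds": thresholds, "subgroup": sub}


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    _write_json(out_dir / "config.json", config.to_dict())

    if config.mode == "synthetic":
        cohort = simulate_cohort(config.sim)
        if config.write_images:
            write_cohort(cohort, out_dir / "cohort")
    else:
        cohort = load_cohort(config.input_dir)

    if cohort.features is None:
        logger.info("extracting %d-feature vectors for %d patients", 3 * len(default_catalogue()), len(cohort))
        extract_cohort_features(cohort)
    cohort.features.to_csv(out_dir / "features.csv")
    cohort.covariate_frame().assign(reader_score=cohort.reader_scores()).to_csv(
        out_dir / "clinical.csv"
    )

    run_from_features(cohort, config, out_dir)
    return out_dir


def reload_feature_cohort(features_csv, clinical_csv) -> Cohort:
    """Rebuild a feature-only cohort from pipeline artifacts (replay path)."""
    features = pd.read_csv(features_csv, index_col=0)
    clinical = pd.read_csv(clinical_csv)
    if "patient_id" not in clinical.columns:
        clinical = clinical.rename(columns={clinical.columns[0]: "patient_id"})
    return cohort_from_tables(clinical, features)
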