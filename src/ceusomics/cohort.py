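"""Patient and cohort containers plus their on-disk CSV/PNG representation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ceusomics.imaging import PHASES, ImageWithROI, rasterize_roi

COVARIATE_COLUMNS = (
    "age",
    "gender",
    "hbsag_band",
    "hbvdna_band",
    "hcvab_band",
    "afp_band",
    "tumor_number",
    "tumor_size",
)

PHASE_PREFIX = {"baseline": "BL_", "arterial": "AP_", "portal": "PP_"}


@dataclass
class Patient:
    """One patient: a three-phase image triplet, reader score, label, covariates.

    ``triplet`` may be ``None`` for feature-only patients reloaded from a
    persisted feature matrix (the images are no longer needed downstream).
    """

    id: str
    label: int
    triplet: Optional[Dict[str, ImageWithROI]]
    reader_score: int
    covariates: Dict[str, object]

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")
        if self.triplet is not None and tuple(sorted(self.triplet)) != tuple(sorted(PHASES)):
            raise ValueError(f"triplet must contain exactly the phases {PHASES}")
        if self.reader_score not in (1, 2, 3):
            raise ValueError("reader_score must be 1, 2 or 3")


@dataclass
class Cohort:
    """An ordered collection of patients, optionally with extracted features."""

    patients: List[Patient]
    features: Optional[pd.DataFrame] = None  # rows indexed by patient id
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def ids(self) -> List[str]:
        return [p.id for p in self.patients]

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)

    def reader_scores(self) -> np.ndarray:
        return np.array([p.reader_score for p in self.patients], dtype=int)

    def covariate_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": p.id, "label": p.label, **p.covariates} for p in self.patients]
        return pd.DataFrame(rows).set_index("patient_id")

    def feature_matrix(self) -> pd.DataFrame:
        if self.features is None:
            raise ValueError("features have not been extracted for this cohort")
        return self.features.loc[self.ids]

    def subset(self, indices) -> "Cohort":
        idx = np.asarray(indices)
        patients = [self.patients[i] for i in idx]
        feats = None
        if self.features is not None:
            feats = self.features.loc[[p.id for p in patients]]
        return Cohort(patients=patients, features=feats, meta=dict(self.meta))


def cohort_from_tables(clinical: pd.DataFrame, features: Optional[pd.DataFrame] = None) -> Cohort:
    """Rebuild a feature-only cohort from the persisted clinical/feature CSVs."""
    patients = []
    for _, row in clinical.iterrows():
        covariates = {k: row[k] for k in COVARIATE_COLUMNS if k in row}
        patients.append(
            Patient(
                id=str(row["patient_id"]),
                label=int(row["label"]),
                triplet=None,
                reader_score=int(row["reader_score"]),
                covariates=covariates,
            )
        )
    if features is not None:
        features = features.copy()
        features.index = features.index.astype(str)
    return Cohort(patients=patients, features=features)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Persist a cohort as one 8-bit PNG per phase, an ROI-vertex CSV, a
    clinical CSV, and a JSON sidecar with the generating metadata."""
    from PIL import Image

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    roi_rows = []
    clin_rows = []
    for p in cohort.patients:
        for phase in PHASES if p.triplet is not None else ():
            img = p.triplet[phase]
            arr = np.asarray(img.pixels)
            if arr.dtype != np.uint8:
                arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(img_dir / f"{p.id}_{phase}.png")
            for k, (x, y) in enumerate(img.roi_polygon):
                roi_rows.append(
                    {"patient_id": p.id, "phase": phase, "vertex_index": k, "x": x, "y": y}
                )
        clin_rows.append(
            {"patient_id": p.id, "label": p.label, "reader_score": p.reader_score, **p.covariates}
        )
    pd.DataFrame(roi_rows).to_csv(out_dir / "rois.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(out_dir / "clinical.csv", index=False)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(cohort.meta, fh, indent=2, sort_keys=True, default=str)
    if cohort.features is not None:
        cohort.features.to_csv(out_dir / "features.csv")
    return out_dir


def load_cohort(in_dir) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from PIL import Image

    in_dir = Path(in_dir)
    clinical = pd.read_csv(in_dir / "clinical.csv", dtype={"patient_id": str})
    rois = pd.read_csv(in_dir / "rois.csv", dtype={"patient_id": str})

    patients = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        triplet = {}
        for phase in PHASES:
            with Image.open(in_dir / "images" / f"{pid}_{phase}.png") as im:
                pixels = np.asarray(im)
            sel = rois[(rois.patient_id == pid) & (rois.phase == phase)].sort_values("vertex_index")
            poly = sel[["x", "y"]].to_numpy(dtype=float)
            mask = rasterize_roi(poly, pixels.shape)
            triplet[phase] = ImageWithROI(pixels=pixels, roi_polygon=poly, mask=mask, phase=phase)
        covariates = {k: row[k] for k in COVARIATE_COLUMNS if k in row}
        patients.append(
            Patient(
                id=pid,
                label=int(row["label"]),
                triplet=triplet,
                reader_score=int(row["reader_score"]),
                covariates=covariates,
            )
        )
    meta = {}
    meta_path = in_dir / "cohort.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    features = None
    feat_path = in_dir / "features.csv"
    if feat_path.exists():
        features = pd.read_csv(feat_path, index_col=0)
        features.index = features.index.astype(str)
    return Cohort(patients=patients, features=features, meta=meta)
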