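"""Assembly of the per-image (1,044) and per-patient (3,132) feature vectors."""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from ceusomics.cohort import PHASE_PREFIX, Cohort
from ceusomics.features.catalogue import (
    ANGLES,
    FeatureCatalogue,
    GLCM_DISTANCES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    LEVEL_SETTINGS,
    default_catalogue,
)
from ceusomics.features.firstorder import first_order_features, gradient_features
from ceusomics.features.glcm import compute_glcm, glcm_features
from ceusomics.features.glrlm import compute_glrlm, glrlm_features
from ceusomics.features.shape import shape_features
from ceusomics.imaging import PHASES, ImageWithROI, quantize


class FeatureExtractionError(RuntimeError):
    """Raised with the offending feature name attached."""


def _angular_blocks(per_angle: Mapping[int, Dict[str, float]], feature_names) -> Dict[str, Dict[str, float]]:
    """Expand per-angle feature dicts into the 6 angular slots."""
    blocks = {f"a{angle}": dict(per_angle[angle]) for angle in ANGLES}
    mean_blk, range_blk = {}, {}
    for feat in feature_names:
        vals = np.array([per_angle[angle][feat] for angle in ANGLES])
        mean_blk[feat] = float(vals.mean())
        range_blk[feat] = float(vals.max() - vals.min())
    blocks["amean"] = mean_blk
    blocks["arange"] = range_blk
    return blocks


def extract_image_features(
    img: ImageWithROI, catalogue: Optional[FeatureCatalogue] = None
) -> Dict[str, float]:
    """Compute every catalogue feature for one image; returns name -> value."""
    catalogue = catalogue or default_catalogue()
    values: Dict[str, float] = {}
    values.update(first_order_features(img.pixels, img.mask))
    values.update(shape_features(img.mask, img.spacing))
    values.update(gradient_features(img.pixels, img.mask))

    level_settings = sorted({dict(e.parameters)["levels"] for e in catalogue.entries if e.family in ("glcm", "rlm")}) or list(LEVEL_SETTINGS)
    distances = sorted({dict(e.parameters)["distance"] for e in catalogue.entries if e.family == "glcm"}) or list(GLCM_DISTANCES)

    for lv in level_settings:
        q = quantize(img.pixels, img.mask, lv)
        for d in distances:
            per_angle = {angle: glcm_features(compute_glcm(q, d, angle)) for angle in ANGLES}
            for slot, blk in _angular_blocks(per_angle, GLCM_FEATURES).items():
                for feat, val in blk.items():
                    values[f"glcm_lv{lv}_d{d}_{slot}_{feat}"] = val
        per_dir = {angle: glrlm_features(compute_glrlm(q, angle)) for angle in ANGLES}
        for slot, blk in _angular_blocks(per_dir, GLRLM_FEATURES).items():
            for feat, val in blk.items():
                values[f"rlm_lv{lv}_{slot}_{feat}"] = val

    out = {}
    for name in catalogue.names():
        if name not in values:
            raise FeatureExtractionError(f"feature {name!r} was not computed")
        v = values[name]
        if not np.isfinite(v):
            raise FeatureExtractionError(f"feature {name!r} is not finite: {v}")
        out[name] = float(v)
    return out


def extract_features(
    triplet: Mapping[str, ImageWithROI],
    catalogue: Optional[FeatureCatalogue] = None,
    patient_id: str = "",
) -> pd.Series:
    """Concatenate per-phase features with BL_/AP_/PP_ prefixes (3 x 1,044)."""
    catalogue = catalogue or default_catalogue()
    if tuple(sorted(triplet)) != tuple(sorted(PHASES)):
        raise ValueError(f"triplet must contain exactly the phases {PHASES}")
    values = {}
    for phase in PHASES:
        prefix = PHASE_PREFIX[phase]
        try:
            for name, v in extract_image_features(triplet[phase], catalogue).items():
                values[prefix + name] = v
        except Exception as exc:
            raise FeatureExtractionError(f"[{patient_id or phase}] {exc}") from exc
    return pd.Series(values, name=patient_id or None)


def extract_cohort_features(
    cohort: Cohort, catalogue: Optional[FeatureCatalogue] = None
) -> pd.DataFrame:
    """Feature matrix for every patient (rows = patient ids); cached on the cohort."""
    catalogue = catalogue or default_catalogue()
    rows = [extract_features(p.triplet, catalogue, patient_id=p.id) for p in cohort.patients]
    X = pd.DataFrame(rows)
    X.index = pd.Index(cohort.ids, name="patient_id")
    cohort.features = X
    return X
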