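"""Synthetic two-class CEUS cohort generator.

Produces three-phase lesion images with class-dependent texture, reader
scores stochastically concordant with the class label, and clinical
covariates drawn from configurable per-class marginals, so the downstream
extraction/selection/modeling/evaluation chain can be exercised and tested
without any external data.

Image model: an elliptical lesion on a darker background.  Both classes share
a smooth correlated texture component whose amplitude tracks ``noise_sd``;
the malignant class additionally receives a bright/dark patch mixture whose
amplitude scales with ``texture_contrast_gap``, giving it higher co-occurrence
contrast and lower homogeneity.  Arterial-phase mean intensity exceeds the
baseline for both classes.  All randomness flows from one master seed through
``numpy`` ``SeedSequence`` spawning (one child per patient, sub-children per
phase), so any patient can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ceusomics.cohort import Cohort, Patient
from ceusomics.imaging import PHASES, ImageWithROI, rasterize_roi

GENDER_LABELS = ("M", "F")
HBSAG_BANDS = ("<=0.05", "0.05-250", ">250")
HBVDNA_BANDS = ("<100", "100-1e5", ">1e5")
HCVAB_BANDS = ("<1.0", ">=1.0")
AFP_BANDS = ("<20", "20-400", ">400")
TUMOR_NUMBER_BANDS = ("1", "2", ">=3")

#: per-class marginals for the default demo cohort (class 0 = benign FNH-like,
#: class 1 = malignant HCC-like)
DEFAULT_COVARIATE_MARGINALS = {
    0: {
        "age": (34.5, 11.7),
        "male_prob": 61 / 119,
        "hbsag": (0.975, 0.008, 0.017),
        "hbvdna": (0.992, 0.0, 0.008),
        "hcvab": (1.0, 0.0),
        "afp": (0.983, 0.017, 0.0),
        "tumor_number": (0.941, 0.034, 0.025),
        "tumor_size": (3.34, 1.80),
    },
    1: {
        "age": (54.0, 11.9),
        "male_prob": 92 / 107,
        "hbsag": (0.140, 0.318, 0.542),
        "hbvdna": (0.430, 0.411, 0.159),
        "hcvab": (0.981, 0.019),
        "afp": (0.355, 0.374, 0.271),
        "tumor_number": (0.860, 0.075, 0.065),
        "tumor_size": (4.76, 3.35),
    },
}

#: per-class per-phase mean lesion intensity on the 0-255 scale
DEFAULT_ENHANCEMENT_MEANS = {
    0: {"baseline": 85.0, "arterial": 175.0, "portal": 150.0},
    1: {"baseline": 95.0, "arterial": 160.0, "portal": 145.0},
}

#: reader-score probabilities over grades (1, 2, 3); defaults tuned so the
#: score-only AUC lands near 0.88 (closed form); tunable, not ground truth
DEFAULT_READER_GRADE_PROBS = {0: (0.65, 0.20, 0.15), 1: (0.05, 0.10, 0.85)}

_PATCH_AMPLITUDE = 18.0  # intensity units per unit of texture_contrast_gap
_ELLIPSE_DILATION = 1.05  # lesion fill extends slightly beyond the ROI polygon
_N_POLY_VERTICES = 36


def _check_probs(p: Sequence[float], what: str, n: int) -> None:
    p = tuple(float(v) for v in p)
    if len(p) != n:
        raise ValueError(f"{what} must have {n} entries, got {len(p)}")
    if any(v < 0 or v > 1 for v in p):
        raise ValueError(f"{what} entries must lie in [0, 1]")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1, got {sum(p)}")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator."""

    n_fnh: int = 119
    n_hcc: int = 107
    image_size: Tuple[int, int] = (128, 128)
    lesion_axes_range: Tuple[float, float] = (16.0, 34.0)
    texture_contrast_gap: float = 1.0
    enhancement_means: Dict[int, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENHANCEMENT_MEANS.items()}
    )
    noise_sd: float = 6.0
    reader_grade_probs: Dict[int, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_READER_GRADE_PROBS)
    )
    covariate_marginals: Dict[int, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_fnh < 1 or self.n_hcc < 1:
            raise ValueError("n_fnh and n_hcc must each be >= 1")
        rows, cols = self.image_size
        if rows < 32 or cols < 32:
            raise ValueError("image_size must be at least 32x32")
        lo, hi = self.lesion_axes_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_axes_range must satisfy 0 < lo <= hi")
        # largest semi-axis plus center jitter and fill dilation must fit
        if hi * _ELLIPSE_DILATION + _CENTER_JITTER + 2 > min(rows, cols) / 2:
            raise ValueError(
                f"lesion axes up to {hi} px exceed the bounds of a "
                f"{rows}x{cols} image; shrink lesion_axes_range or enlarge image_size"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.texture_contrast_gap < 0:
            raise ValueError("texture_contrast_gap must be non-negative")
        for cls in (0, 1):
            _check_probs(self.reader_grade_probs[cls], f"reader_grade_probs[{cls}]", 3)
            for phase in PHASES:
                if phase not in self.enhancement_means[cls]:
                    raise ValueError(f"enhancement_means[{cls}] is missing phase {phase!r}")
            m = self.covariate_marginals[cls]
            _check_probs(m["hbsag"], f"hbsag marginal[{cls}]", 3)
            _check_probs(m["hbvdna"], f"hbvdna marginal[{cls}]", 3)
            _check_probs(m["hcvab"], f"hcvab marginal[{cls}]", 2)
            _check_probs(m["afp"], f"afp marginal[{cls}]", 3)
            _check_probs(m["tumor_number"], f"tumor_number marginal[{cls}]", 3)

    @classmethod
    def null(cls, n_fnh: int = 100, n_hcc: int = 100, **kwargs) -> "SimConfig":
        """A no-signal configuration: identical texture, enhancement, and
        reader-score distributions for the two classes."""
        means = {"baseline": 90.0, "arterial": 165.0, "portal": 148.0}
        probs = (1 / 3, 1 / 3, 1 / 3)
        return cls(
            n_fnh=n_fnh,
            n_hcc=n_hcc,
            texture_contrast_gap=0.0,
            enhancement_means={0: dict(means), 1: dict(means)},
            reader_grade_probs={0: probs, 1: probs},
            **kwargs,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_CENTER_JITTER = 5.0


def _draw_geometry(cfg: SimConfig, rng: np.random.Generator) -> dict:
    rows, cols = cfg.image_size
    lo, hi = cfg.lesion_axes_range
    a, b = np.sort(rng.uniform(lo, hi, size=2))[::-1]
    theta = rng.uniform(0, np.pi)
    cy = rows / 2 + rng.uniform(-_CENTER_JITTER, _CENTER_JITTER)
    cx = cols / 2 + rng.uniform(-_CENTER_JITTER, _CENTER_JITTER)
    # ROI polygon: vertices on the ellipse with a small inward radial jitter,
    # so every mask pixel lies inside the (slightly dilated) lesion fill
    ang = np.linspace(0, 2 * np.pi, _N_POLY_VERTICES, endpoint=False)
    radial = 1.0 + rng.uniform(-0.03, 0.0, size=_N_POLY_VERTICES)
    ex = a * np.cos(ang) * radial
    ey = b * np.sin(ang) * radial
    px = cx + ex * np.cos(theta) - ey * np.sin(theta)
    py = cy + ex * np.sin(theta) + ey * np.cos(theta)
    return {"cx": cx, "cy": cy, "a": a, "b": b, "theta": theta, "polygon": np.column_stack([px, py])}


def _render_image(
    class_label: int, phase: str, cfg: SimConfig, geom: dict, rng: np.random.Generator
) -> ImageWithROI:
    rows, cols = cfg.image_size
    yy, xx = np.mgrid[0:rows, 0:cols]
    # evaluate the ellipse at pixel centers
    dx = (xx + 0.5) - geom["cx"]
    dy = (yy + 0.5) - geom["cy"]
    u = dx * np.cos(geom["theta"]) + dy * np.sin(geom["theta"])
    v = -dx * np.sin(geom["theta"]) + dy * np.cos(geom["theta"])
    a = geom["a"] * _ELLIPSE_DILATION
    b = geom["b"] * _ELLIPSE_DILATION
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    mean = float(cfg.enhancement_means[class_label][phase])
    img = np.full((rows, cols), 55.0)
    if cfg.noise_sd > 0:
        bg = gaussian_filter(rng.standard_normal((rows, cols)), 8.0)
        sd = bg.std()
        if sd > 0:
            img += bg / sd * cfg.noise_sd

    interior = np.full((rows, cols), mean)
    if cfg.noise_sd > 0:
        smooth = gaussian_filter(rng.standard_normal((rows, cols)), 3.0)
        sd = smooth.std()
        if sd > 0:
            interior += smooth / sd * cfg.noise_sd
    if class_label == 1 and cfg.texture_contrast_gap > 0:
        # fine-scale patches: a coarser field would be flattened back out by
        # the ROI-relative quantization and lose its co-occurrence contrast
        patches = np.sign(gaussian_filter(rng.standard_normal((rows, cols)), 1.0))
        patches[patches == 0] = 1.0
        interior += patches * cfg.texture_contrast_gap * _PATCH_AMPLITUDE
    img[inside] = interior[inside]
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=(rows, cols))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    polygon = geom["polygon"]
    mask = rasterize_roi(polygon, (rows, cols))
    return ImageWithROI(pixels=img, roi_polygon=polygon, mask=mask, phase=phase)


def simulate_lesion_image(class_label: int, phase: str, cfg: SimConfig, seed: int) -> ImageWithROI:
    """Generate one lesion image for (class, phase); pure in (inputs, seed)."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    cfg.validate()
    geom_rng, tex_rng = (np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2))
    geom = _draw_geometry(cfg, geom_rng)
    return _render_image(class_label, phase, cfg, geom, tex_rng)


def simulate_reader_scores(
    labels: Sequence[int], grade_probs: Dict[int, Sequence[float]], seed: int
) -> np.ndarray:
    """Draw one ordinal grade in {1,2,3} per patient from its class's triple."""
    for cls in (0, 1):
        _check_probs(grade_probs[cls], f"grade_probs[{cls}]", 3)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    u = rng.random(labels.shape[0])
    scores = np.empty(labels.shape[0], dtype=int)
    for cls in (0, 1):
        cum = np.cumsum(grade_probs[cls])
        sel = labels == cls
        scores[sel] = np.searchsorted(cum, u[sel], side="right") + 1
    np.clip(scores, 1, 3, out=scores)
    return scores


def _draw_covariates(class_label: int, cfg: SimConfig, rng: np.random.Generator) -> dict:
    m = cfg.covariate_marginals[class_label]
    age_mu, age_sd = m["age"]
    size_mu, size_sd = m["tumor_size"]
    size = rng.normal(size_mu, size_sd)
    while size < 0.8:  # lesions below 0.8 cm are not simulated
        size = rng.normal(size_mu, size_sd)
    return {
        "age": float(np.round(np.clip(rng.normal(age_mu, age_sd), 16, 90), 1)),
        "gender": GENDER_LABELS[0] if rng.random() < m["male_prob"] else GENDER_LABELS[1],
        "hbsag_band": HBSAG_BANDS[_draw_band(rng, m["hbsag"])],
        "hbvdna_band": HBVDNA_BANDS[_draw_band(rng, m["hbvdna"])],
        "hcvab_band": HCVAB_BANDS[_draw_band(rng, m["hcvab"])],
        "afp_band": AFP_BANDS[_draw_band(rng, m["afp"])],
        "tumor_number": TUMOR_NUMBER_BANDS[_draw_band(rng, m["tumor_number"])],
        "tumor_size": float(np.round(size, 2)),
    }


def _draw_band(rng: np.random.Generator, probs: Sequence[float]) -> int:
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right").clip(0, len(probs) - 1))


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full cohort of ``n_fnh + n_hcc`` patients.

    Patient ``i`` is regenerated from child ``i`` of ``SeedSequence(cfg.seed)``
    regardless of cohort size, so partial regeneration is stable.
    """
    cfg.validate()
    labels = [0] * cfg.n_fnh + [1] * cfg.n_hcc
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(len(labels))
    patients = []
    for i, (label, child) in enumerate(zip(labels, children)):
        geom_ss, bl_ss, ap_ss, pp_ss, misc_ss = child.spawn(5)
        geom = _draw_geometry(cfg, np.random.default_rng(geom_ss))
        triplet = {
            phase: _render_image(label, phase, cfg, geom, np.random.default_rng(ss))
            for phase, ss in zip(PHASES, (bl_ss, ap_ss, pp_ss))
        }
        misc_rng = np.random.default_rng(misc_ss)
        covariates = _draw_covariates(label, cfg, misc_rng)
        cum = np.cumsum(cfg.reader_grade_probs[label])
        score = int(np.searchsorted(cum, misc_rng.random(), side="right").clip(0, 2)) + 1
        patients.append(
            Patient(
                id=f"P{i + 1:04d}",
                label=label,
                triplet=triplet,
                reader_score=score,
                covariates=covariates,
            )
        )
    return Cohort(patients=patients, meta={"config": cfg.to_dict(), "seed": cfg.seed})
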