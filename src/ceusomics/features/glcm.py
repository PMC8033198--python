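"""Grey-level co-occurrence matrices and their 13 texture features.

Conventions fixed here and documented once: matrices are symmetrized (each
ordered pair is counted in both directions) and normalized to sum to 1;
entropies use log base 2 with ``0*log(0) = 0``; correlation uses the marginal
mean/SD of the symmetrized matrix and is defined as 1 for a constant (single
grey level) matrix.  Offsets, as ``(d_row, d_col)``: 0 deg -> ``(0, d)``,
45 deg -> ``(-d, d)``, 90 deg -> ``(-d, 0)``, 135 deg -> ``(-d, -d)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from ceusomics.features.catalogue import GLCM_FEATURES
from ceusomics.imaging import QuantizedROI

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegenerateGLCMError(ValueError):
    """No valid in-mask pixel pair exists for the requested offset."""


@dataclass
class GLCMatrix:
    probabilities: np.ndarray  # Ng x Ng, symmetric, sums to 1
    distance: int
    angle: int
    levels: int
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.levels, self.levels):
            raise ValueError("probability matrix must be Ng x Ng")
        if np.any(p < 0):
            raise ValueError("co-occurrence probabilities must be non-negative")
        if self.normalized and abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"normalized matrix must sum to 1, got {p.sum()}")
        if self.symmetric and not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("symmetrized matrix must equal its transpose")
        self.probabilities = p


def compute_glcm(q: QuantizedROI, distance: int, angle: int) -> GLCMatrix:
    """Count in-mask level pairs at the given offset, symmetrize, normalize."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in OFFSETS:
        raise ValueError(f"angle must be one of {tuple(OFFSETS)}")
    dr, dc = (distance * o for o in OFFSETS[angle])
    lv, mask = q.quantized, q.mask
    rows, cols = lv.shape

    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateGLCMError("offset exceeds image extent")
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise DegenerateGLCMError(
            f"no in-mask pixel pair for distance {distance}, angle {angle}"
        )
    ng = q.levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    sym = counts + counts.T
    p = sym / sym.sum()
    return GLCMatrix(probabilities=p, distance=distance, angle=angle, levels=ng)


def glcm_features(m: GLCMatrix) -> Dict[str, float]:
    """The 13 co-occurrence features of a normalized symmetric matrix."""
    if not m.normalized:
        raise ValueError("glcm_features requires a normalized matrix")
    p = m.probabilities
    ng = m.levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())

    # distributions of i+j and |i-j|
    sum_p = np.zeros(2 * ng + 1)
    np.add.at(sum_p, (ii + jj).ravel(), p.ravel())
    diff_p = np.zeros(ng)
    np.add.at(diff_p, np.abs(diff).ravel(), p.ravel())
    sp, dp = sum_p[sum_p > 0], diff_p[diff_p > 0]

    if var > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        correlation = 1.0

    out = {
        "energy": float((p**2).sum()),
        "contrast": float((p * diff**2).sum()),
        "correlation": correlation,
        "entropy": entropy,
        "homogeneity": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(diff))).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "max_probability": float(p.max()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "sum_average": float((np.arange(2 * ng + 1) * sum_p).sum()),
        "sum_entropy": float(-(sp * np.log2(sp)).sum()),
        "difference_entropy": float(-(dp * np.log2(dp)).sum()),
    }
    assert tuple(out) == GLCM_FEATURES
    return out
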