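"""First-order intensity statistics and gradient-magnitude ("textural") stats.

Conventions, applied uniformly: population moments (``ddof=0``); percentiles
by linear interpolation between order statistics (``numpy`` default);
histogram-based entropy/uniformity over 64 equal-width bins spanning the
in-mask ``[min, max]`` range, log base 2 with ``0*log(0) = 0``.  Moment ratios
of a constant sample (skewness, kurtosis, CV) are defined as 0.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import ndimage

from ceusomics.imaging import MIN_ROI_PIXELS, RoiError
from ceusomics.features.catalogue import FIRST_ORDER_STATS, GRADIENT_STATS, PERCENTILES

_N_HIST_BINS = 64


def _hist_probs(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=_N_HIST_BINS, range=(lo, hi))
    return counts / counts.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _checked_values(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must equal image shape")
    x = image[mask]
    if x.size < MIN_ROI_PIXELS:
        raise RoiError(f"ROI must contain at least {MIN_ROI_PIXELS} pixels, got {x.size}")
    return x


def first_order_features(image: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """The 42 histogram-family statistics of the in-mask intensities."""
    x = _checked_values(image, mask)
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    sd = np.sqrt(m2)
    if m2 > 0:
        skew = ((x - mean) ** 3).mean() / m2**1.5
        kurt = ((x - mean) ** 4).mean() / m2**2
        exkurt = kurt - 3.0
    else:
        skew = kurt = exkurt = 0.0
    pcts = {p: float(np.percentile(x, p)) for p in PERCENTILES}
    p10, p25, p75, p90 = pcts[10], pcts[25], pcts[75], pcts[90]
    trimmed = x[(x >= p10) & (x <= p90)]
    probs = _hist_probs(x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        mode = float(lo)
    else:
        edges = np.linspace(lo, hi, _N_HIST_BINS + 1)
        k = int(np.argmax(probs))
        mode = float((edges[k] + edges[k + 1]) / 2)
    out = {
        "mean": float(mean),
        "median": float(np.median(x)),
        "variance": float(m2),
        "stddev": float(sd),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "excess_kurtosis": float(exkurt),
        "minimum": float(lo),
        "maximum": float(hi),
        "range": float(hi - lo),
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "mean_abs_dev": float(np.abs(x - mean).mean()),
        "median_abs_dev": float(np.median(np.abs(x - np.median(x)))),
        "robust_mean_abs_dev": float(np.abs(trimmed - trimmed.mean()).mean()),
        "iqr": float(p75 - p25),
        "cv": float(sd / mean) if mean != 0 else 0.0,
        "entropy": _entropy_bits(probs),
        "uniformity": float((probs**2).sum()),
        "mode": mode,
        "p10p90_range": float(p90 - p10),
        "quartile_dispersion": float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
        "total": float(x.sum()),
    }
    assert tuple(out) == FIRST_ORDER_STATS
    result = {f"hist_{k}": v for k, v in out.items()}
    for p in PERCENTILES:
        result[f"hist_p{p:02d}"] = pcts[p]
    return result


def gradient_features(image: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """The 18 textural-family statistics of the Sobel gradient magnitude.

    The gradient is computed on the full image and masked afterwards; the
    mask is eroded by one pixel first so boundary gradients (lesion rim) do
    not contaminate the interior texture statistics.  The Sobel response is
    divided by 4, so an ideal step edge of height ``h`` has magnitude ``h``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask)
    if int(eroded.sum()) < MIN_ROI_PIXELS:
        raise RoiError("eroded ROI too small for gradient statistics")
    gx = ndimage.sobel(image, axis=1, mode="nearest") / 4.0
    gy = ndimage.sobel(image, axis=0, mode="nearest") / 4.0
    g = np.hypot(gx, gy)[eroded]

    mean = g.mean()
    m2 = ((g - mean) ** 2).mean()
    sd = np.sqrt(m2)
    if m2 > 0:
        skew = ((g - mean) ** 3).mean() / m2**1.5
        kurt = ((g - mean) ** 4).mean() / m2**2
    else:
        skew = kurt = 0.0
    p10, p25, p50, p75, p90 = np.percentile(g, [10, 25, 50, 75, 90])
    probs = _hist_probs(g)
    out = {
        "mean": float(mean),
        "stddev": float(sd),
        "variance": float(m2),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "minimum": float(g.min()),
        "maximum": float(g.max()),
        "range": float(g.max() - g.min()),
        "median": float(p50),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "iqr": float(p75 - p25),
        "energy": float((g**2).sum()),
        "entropy": _entropy_bits(probs),
        "uniformity": float((probs**2).sum()),
        "rms": float(np.sqrt((g**2).mean())),
    }
    assert tuple(out) == GRADIENT_STATS
    return {f"grad_{k}": v for k, v in out.items()}
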