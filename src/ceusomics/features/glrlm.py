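"""Grey-level run-length matrices and their 16 features.

A run is a maximal sequence of in-mask pixels of equal quantized level along
one of the four directions; runs break wherever the line leaves the mask.
``counts[i, j]`` holds the number of runs of level ``i+1`` and length
``j+1``.  Run entropy uses log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from ceusomics.features.catalogue import GLRLM_FEATURES
from ceusomics.imaging import QuantizedROI

DIRECTIONS = (0, 45, 90, 135)


class EmptyRunError(ValueError):
    pass


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # Ng x Lmax
    direction: int
    n_pixels: int
    levels: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.levels:
            raise ValueError("counts must be an Ng x Lmax matrix")
        if np.any(self.counts < 0):
            raise ValueError("run counts must be non-negative")

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def _direction_lines(arr: np.ndarray, direction: int) -> np.ndarray:
    """Rearrange so that each row is one traversal line of the direction.

    Diagonal directions use a skewed copy (out-of-line cells padded with the
    out-of-mask sentinel 0, which breaks runs exactly like a mask boundary):
    column ``c + r`` is constant along 45-degree lines and ``c - r`` along
    135-degree lines.
    """
    rows, cols = arr.shape
    if direction == 0:
        return arr
    if direction == 90:
        return arr.T
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    skew = np.zeros((rows, cols + rows - 1), dtype=arr.dtype)
    if direction == 45:
        skew[r, c + r] = arr
    elif direction == 135:
        skew[r, c + (rows - 1 - r)] = arr
    else:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    return skew.T


def compute_glrlm(q: QuantizedROI, direction: int) -> RunLengthMatrix:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if q.n_pixels == 0:
        raise EmptyRunError("mask is empty")
    ng = q.levels
    lines = _direction_lines(q.quantized, direction)
    # flatten all lines with a zero separator so runs cannot span lines
    flat = np.hstack([lines, np.zeros((lines.shape[0], 1), dtype=lines.dtype)]).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, flat.size - 1]
    levels = flat[starts]
    keep = levels > 0
    lengths = (ends - starts + 1)[keep]
    levels = levels[keep]
    max_len = max(q.quantized.shape)
    counts = np.zeros((ng, max_len), dtype=np.int64)
    np.add.at(counts, (levels - 1, lengths - 1), 1)
    # trim trailing all-zero run lengths
    nonzero = np.nonzero(counts.sum(axis=0))[0]
    lmax = int(nonzero[-1]) + 1 if nonzero.size else 1
    return RunLengthMatrix(counts=counts[:, :lmax], direction=direction, n_pixels=q.n_pixels, levels=ng)


def glrlm_features(r: RunLengthMatrix) -> Dict[str, float]:
    counts = r.counts.astype(float)
    nr = counts.sum()
    if nr == 0:
        raise EmptyRunError("run-length matrix contains no runs")
    ng, lmax = counts.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)  # grey level
    j = np.arange(1, lmax + 1)[None, :].astype(float)  # run length

    level_sums = counts.sum(axis=1)
    length_sums = counts.sum(axis=0)
    p = counts / nr
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p[p > 0]

    out = {
        "sre": float((counts / j**2).sum() / nr),
        "lre": float((counts * j**2).sum() / nr),
        "gln": float((level_sums**2).sum() / nr),
        "glnn": float((level_sums**2).sum() / nr**2),
        "rln": float((length_sums**2).sum() / nr),
        "rlnn": float((length_sums**2).sum() / nr**2),
        "rp": float(nr / r.n_pixels),
        "lglre": float((counts / i**2).sum() / nr),
        "hglre": float((counts * i**2).sum() / nr),
        "srlgle": float((counts / (i**2 * j**2)).sum() / nr),
        "srhgle": float((counts * i**2 / j**2).sum() / nr),
        "lrlgle": float((counts * j**2 / i**2).sum() / nr),
        "lrhgle": float((counts * i**2 * j**2).sum() / nr),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "rlv": float((p * (j - mu_j) ** 2).sum()),
        "run_entropy": float(-(nz * np.log2(nz)).sum()),
    }
    assert tuple(out) == GLRLM_FEATURES
    return out
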