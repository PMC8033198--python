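"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (per-pixel loops, pair enumeration) and
shares no code with the package implementations it checks.
"""

from __future__ import annotations

import struct

import numpy as np

STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(quantized: np.ndarray, mask: np.ndarray, levels: int, distance: int, angle: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by explicit pair loops."""
    rows, cols = quantized.shape
    dr, dc = (distance * s for s in STEPS[angle])
    counts = np.zeros((levels, levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                i, j = quantized[r, c] - 1, quantized[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glrlm(quantized: np.ndarray, mask: np.ndarray, levels: int, direction: int) -> dict:
    """Run counts {(level, length): n} by walking every line pixel by pixel."""
    rows, cols = quantized.shape
    dr, dc = STEPS[direction]
    counts: dict = {}

    def bump(lv, ln):
        if lv > 0 and ln > 0:
            counts[(lv, ln)] = counts.get((lv, ln), 0) + 1

    for r0 in range(rows):
        for c0 in range(cols):
            pr, pc = r0 - dr, c0 - dc
            if 0 <= pr < rows and 0 <= pc < cols:
                continue  # not the start of a line
            r, c = r0, c0
            run_lv, run_len = 0, 0
            while 0 <= r < rows and 0 <= c < cols:
                lv = quantized[r, c] if mask[r, c] else 0
                if lv == run_lv and lv > 0:
                    run_len += 1
                else:
                    bump(run_lv, run_len)
                    run_lv, run_len = lv, (1 if lv > 0 else 0)
                r, c = r + dr, c + dc
            bump(run_lv, run_len)
    return counts


def brute_auc(scores, labels) -> float:
    """AUC by enumerating every positive/negative pair; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def brute_quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning by scanning the bin edges per value."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values, dtype=int)
    w = (hi - lo) / levels
    out = np.empty(values.size, dtype=int)
    for idx, v in enumerate(values.ravel()):
        k = levels  # max maps to the top level
        for b in range(1, levels + 1):
            if v < lo + b * w:
                k = b
                break
        out[idx] = k
    return out.reshape(values.shape)


def write_minimal_dicom(
    path,
    pixels: np.ndarray,
    slope: float | None = None,
    intercept: float | None = None,
    spacing: float | None = None,
    n_frames: int | None = None,
) -> None:
    """Hand-assembled explicit-VR little-endian single-frame DICOM writer.

    Constructed byte by byte from the encoding rules, independently of the
    package's reader.
    """
    pixels = np.asarray(pixels, dtype=np.uint16)
    rows, cols = pixels.shape

    def elem(group, element, vr, value: bytes) -> bytes:
        head = struct.pack("<HH", group, element) + vr
        if vr in (b"OB", b"OW", b"SQ", b"UN", b"UT"):
            return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
        return head + struct.pack("<H", len(value)) + value

    def even_ascii(s: str) -> bytes:
        b = s.encode("ascii")
        return b + b" " if len(b) % 2 else b

    ts = even_ascii("1.2.840.10008.1.2.1").rstrip() + (b"\x00" if len("1.2.840.10008.1.2.1") % 2 else b"")
    meta_body = elem(0x0002, 0x0010, b"UI", ts)
    meta = elem(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body

    body = b""
    if n_frames is not None:
        body += elem(0x0028, 0x0008, b"IS", even_ascii(str(n_frames)))
    body += elem(0x0028, 0x0002, b"US", struct.pack("<H", 1))
    body += elem(0x0028, 0x0010, b"US", struct.pack("<H", rows))
    body += elem(0x0028, 0x0011, b"US", struct.pack("<H", cols))
    if spacing is not None:
        body += elem(0x0028, 0x0030, b"DS", even_ascii(f"{spacing}\\{spacing}"))
    body += elem(0x0028, 0x0100, b"US", struct.pack("<H", 16))
    body += elem(0x0028, 0x0103, b"US", struct.pack("<H", 0))
    if intercept is not None:
        body += elem(0x0028, 0x1052, b"DS", even_ascii(str(intercept)))
    if slope is not None:
        body += elem(0x0028, 0x1053, b"DS", even_ascii(str(slope)))
    body += elem(0x7FE0, 0x0010, b"OW", pixels.tobytes())

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)
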