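"""Minimal reader for single-frame, uncompressed, little-endian DICOM files.

Supports the two uncompressed little-endian transfer syntaxes (implicit and
explicit VR) and monochrome or interleaved-RGB pixel data, which covers the
still-frame exports this package consumes.  Multi-frame or compressed files
are rejected with :class:`UnsupportedDicomError`.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

# tags we interpret; everything else is skipped
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REPR = (0x0028, 0x0103)
_TAG_SAMPLES = (0x0028, 0x0002)
_TAG_N_FRAMES = (0x0028, 0x0008)
_TAG_PIXEL_SPACING = (0x0028, 0x0030)
_TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
_TAG_RESCALE_SLOPE = (0x0028, 0x1053)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)


class DicomParseError(ValueError):
    """Raised when a file is not parseable as DICOM."""


class UnsupportedDicomError(ValueError):
    """Raised for valid DICOM that this minimal reader does not support."""


def _iter_elements(buf: bytes, pos: int, explicit: bool):
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if explicit:
            vr = buf[pos : pos + 2]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 4)
                pos += 8
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 2)
                pos += 4
        else:
            vr = b""
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        if length == 0xFFFFFFFF:
            raise UnsupportedDicomError("undefined-length elements are not supported")
        value = buf[pos : pos + length]
        if len(value) != length:
            raise DicomParseError("truncated DICOM element")
        pos += length
        yield (group, elem), vr, value


def _int_value(vr: bytes, value: bytes) -> int:
    if vr in (b"US", b""):
        if len(value) == 2:
            return struct.unpack("<H", value)[0]
    if vr == b"UL" or (vr == b"" and len(value) == 4):
        return struct.unpack("<I", value)[0]
    if vr in (b"IS", b"DS", b"LO", b"SH"):
        return int(value.decode("ascii").strip("\x00 "))
    # implicit VR short integer fallback
    if len(value) == 2:
        return struct.unpack("<H", value)[0]
    return int(value.decode("ascii").strip("\x00 "))


def _float_value(value: bytes) -> float:
    return float(value.decode("ascii").strip("\x00 ").split("\\")[0])


def read_single_frame_dicom(path):
    """Parse one single-frame DICOM file.

    Returns ``(pixels, spacing)``: a float 2D array with rescale
    slope/intercept applied, and the row pixel spacing in mm when present.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomParseError("missing DICM magic; not a part-10 DICOM file")

    # file meta group (group 0002) is always explicit VR little endian
    pos = 132
    transfer_syntax = EXPLICIT_VR_LE
    for tag, vr, value in _iter_elements(buf, pos, explicit=True):
        if tag[0] > 0x0002:
            break
        if tag == (0x0002, 0x0010):
            transfer_syntax = value.decode("ascii").strip("\x00 ")
        pos = _element_end(buf, pos, explicit=True)

    if transfer_syntax == EXPLICIT_VR_LE:
        explicit = True
    elif transfer_syntax == IMPLICIT_VR_LE:
        explicit = False
    else:
        raise UnsupportedDicomError(f"unsupported transfer syntax {transfer_syntax!r}")

    fields = {}
    pixel_data = None
    for tag, vr, value in _iter_elements(buf, pos, explicit=explicit):
        if tag == _TAG_PIXEL_DATA:
            pixel_data = value
            break
        fields[tag] = (vr, value)

    if pixel_data is None:
        raise UnsupportedDicomError("file carries no pixel data")

    def geti(tag, default=None):
        if tag not in fields:
            return default
        vr, value = fields[tag]
        return _int_value(vr, value)

    n_frames = geti(_TAG_N_FRAMES, 1)
    if n_frames != 1:
        raise UnsupportedDicomError(f"multi-frame DICOM ({n_frames} frames) is not supported")
    rows = geti(_TAG_ROWS)
    cols = geti(_TAG_COLS)
    if rows is None or cols is None:
        raise DicomParseError("missing Rows/Columns")
    bits = geti(_TAG_BITS_ALLOC, 16)
    signed = geti(_TAG_PIXEL_REPR, 0) == 1
    samples = geti(_TAG_SAMPLES, 1)
    if bits == 8:
        dtype = np.int8 if signed else np.uint8
    elif bits == 16:
        dtype = np.int16 if signed else np.uint16
    else:
        raise UnsupportedDicomError(f"BitsAllocated={bits} is not supported")

    arr = np.frombuffer(pixel_data, dtype=dtype)
    if samples == 1:
        if arr.size < rows * cols:
            raise DicomParseError("pixel data shorter than Rows*Columns")
        arr = arr[: rows * cols].reshape(rows, cols).astype(float)
    elif samples == 3:
        if arr.size < rows * cols * 3:
            raise DicomParseError("pixel data shorter than Rows*Columns*3")
        rgb = arr[: rows * cols * 3].reshape(rows, cols, 3).astype(float)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise UnsupportedDicomError(f"SamplesPerPixel={samples} is not supported")

    slope = 1.0
    intercept = 0.0
    if _TAG_RESCALE_SLOPE in fields:
        slope = _float_value(fields[_TAG_RESCALE_SLOPE][1])
    if _TAG_RESCALE_INTERCEPT in fields:
        intercept = _float_value(fields[_TAG_RESCALE_INTERCEPT][1])
    arr = arr * slope + intercept

    spacing = None
    if _TAG_PIXEL_SPACING in fields:
        spacing = _float_value(fields[_TAG_PIXEL_SPACING][1])
    return arr, spacing


def _element_end(buf: bytes, pos: int, explicit: bool) -> int:
    group, elem = struct.unpack_from("<HH", buf, pos)
    pos += 4
    if explicit:
        vr = buf[pos : pos + 2]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 4)
            pos += 8
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 2)
            pos += 4
    else:
        (length,) = struct.unpack_from("<I", buf, pos)
        pos += 4
    return pos + length
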