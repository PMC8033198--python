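import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from ceusomics.imaging import ImageWithROI, rasterize_roi
from ceusomics.synthetic_data import SimConfig, simulate_lesion_image


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_fnh=6, n_hcc=6, image_size=(96, 96), lesion_axes_range=(14.0, 26.0), seed=123)


@pytest.fixture(scope="session")
def arterial_image(small_cfg) -> ImageWithROI:
    return simulate_lesion_image(1, "arterial", small_cfg, seed=7)


def make_image(pixels: np.ndarray, polygon=None, phase: str = "baseline") -> ImageWithROI:
    """Wrap a raw array as an ImageWithROI with a rectangle ROI by default."""
    pixels = np.asarray(pixels)
    rows, cols = pixels.shape
    if polygon is None:
        polygon = [(1.0, 1.0), (cols - 1.0, 1.0), (cols - 1.0, rows - 1.0), (1.0, rows - 1.0)]
    mask = rasterize_roi(polygon, (rows, cols))
    return ImageWithROI(pixels=pixels, roi_polygon=np.asarray(polygon, dtype=float), mask=mask, phase=phase)
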