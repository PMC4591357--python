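"""Grayscale image helpers.

All geometry in this package is in pixel units with 0-based (row, col)
array indexing; points handed across module boundaries are (x, y) pairs
with x = column and y = row.
"""

from __future__ import annotations

import numpy as np

# Rec. 601 luma weights, the standard choice for luminance conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray(img: np.ndarray) -> np.ndarray:
    """Coerce an 8/16-bit or float raster to a float64 luminance field.

    Color inputs (H, W, 3) or (H, W, 4) are converted with Rec. 601 luma
    weights; integer inputs keep their native scale (0..255 or 0..65535).
    """
    a = np.asarray(img)
    if a.ndim == 3:
        if a.shape[2] not in (3, 4):
            raise ValueError(f"expected a (H, W, 3|4) color image, got shape {a.shape}")
        a = a[..., :3].astype(np.float64) @ _LUMA
    elif a.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got ndim={a.ndim}")
    a = a.astype(np.float64, copy=False)
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def dynamic_range(img: np.ndarray) -> float:
    """Peak-to-peak luminance of an image; 1.0 for a constant image."""
    rng = float(np.ptp(img))
    return rng if rng > 0 else 1.0


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/PGM from disk and return a float luminance field."""
    import imageio.v3 as iio

    return as_gray(iio.imread(path))
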