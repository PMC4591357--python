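"""The 29-landmark face scheme and shape geometry helpers.

A *shape* is an (L, 2) float array of landmark (x, y) positions in
image pixels, L = 29 by default. The scheme mirrors the layout of the
29-point annotation style used for face-alignment training sets: brows,
eye contours, explicit eye centers, nose, mouth and chin, in a fixed
order. Having the eye centers as explicit landmarks is what lets the
affine-invariant selector reconstruct them from their neighbors.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import SimilarityTransform

__all__ = [
    "LANDMARK_SCHEME_29",
    "TEMPLATE_29",
    "N_LANDMARKS",
    "similarity_fit",
    "shape_box",
    "place_in_box",
    "normalize_to_box",
    "interocular_distance",
]

#: Landmark name -> row index. Coordinates are (x, y), x rightward,
#: y downward; "left" means the image-left side (subject's right).
LANDMARK_SCHEME_29 = {
    "left_brow_outer": 0, "left_brow_mid": 1, "left_brow_inner": 2,
    "right_brow_inner": 3, "right_brow_mid": 4, "right_brow_outer": 5,
    "left_eye_outer": 6, "left_eye_top": 7, "left_eye_inner": 8, "left_eye_bottom": 9,
    "right_eye_inner": 10, "right_eye_top": 11, "right_eye_outer": 12, "right_eye_bottom": 13,
    "left_eye_center": 14, "right_eye_center": 15,
    "nose_bridge": 16, "nose_tip": 17, "nose_left": 18, "nose_right": 19,
    "mouth_left": 20, "mouth_top": 21, "mouth_right": 22, "mouth_bottom": 23,
    "mouth_top_left": 24, "mouth_top_right": 25,
    "mouth_bottom_left": 26, "mouth_bottom_right": 27,
    "chin": 28,
}

N_LANDMARKS = 29

#: Canonical template in a unit face frame ([0, 1] x [0, 1] box).
TEMPLATE_29 = np.array([
    (0.20, 0.30), (0.30, 0.27), (0.40, 0.30),          # left brow
    (0.60, 0.30), (0.70, 0.27), (0.80, 0.30),          # right brow
    (0.22, 0.42), (0.30, 0.395), (0.38, 0.42), (0.30, 0.445),   # left eye contour
    (0.62, 0.42), (0.70, 0.395), (0.78, 0.42), (0.70, 0.445),   # right eye contour
    (0.30, 0.42), (0.70, 0.42),                        # eye centers
    (0.50, 0.45), (0.50, 0.60), (0.43, 0.62), (0.57, 0.62),     # nose
    (0.35, 0.75), (0.50, 0.72), (0.65, 0.75), (0.50, 0.79),     # mouth cardinal
    (0.425, 0.73), (0.575, 0.73), (0.425, 0.78), (0.575, 0.78), # mouth intermediate
    (0.50, 0.92),                                      # chin
])


def similarity_fit(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares similarity transform mapping src landmarks onto dst.

    Returns a 3x3 homogeneous matrix (rotation + uniform scale +
    translation). Raises if the source has no spatial extent.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if np.ptp(src, axis=0).max() < 1e-9:
        raise ValueError("degenerate shape: zero spatial extent")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(src, dst)
        if not tf:
            raise ValueError("similarity transform estimation failed")
        return tf.params
    tf = SimilarityTransform()
    if not tf.estimate(src, dst):
        raise ValueError("similarity transform estimation failed")
    return tf.params


def shape_box(shape: np.ndarray, margin: float = 0.0):
    """Axis-aligned bounding box (x, y, w, h) of a shape, expanded by margin."""
    shape = np.asarray(shape, dtype=np.float64)
    x0, y0 = shape.min(axis=0)
    x1, y1 = shape.max(axis=0)
    w, h = x1 - x0, y1 - y0
    return (x0 - margin * w, y0 - margin * h, w * (1 + 2 * margin), h * (1 + 2 * margin))


def normalize_to_box(shape: np.ndarray, box) -> np.ndarray:
    """Map a shape into a box-relative unit frame."""
    x, y, w, h = box
    shape = np.asarray(shape, dtype=np.float64)
    return (shape - [x, y]) / [w, h]


def place_in_box(unit_shape: np.ndarray, box) -> np.ndarray:
    """Map a unit-frame shape into image pixels via a box."""
    x, y, w, h = box
    return np.asarray(unit_shape, dtype=np.float64) * [w, h] + [x, y]


def interocular_distance(shape: np.ndarray) -> float:
    s = LANDMARK_SCHEME_29
    return float(np.linalg.norm(shape[s["right_eye_center"]] - shape[s["left_eye_center"]]))
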