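"""Face-detector plugin interface.

The pipeline only needs a callable ``image -> list of FaceBox``; any
external detector can be wrapped. Two bindings ship with the package:

* :class:`BrightRegionDetector` — a deliberately simple detector that
  thresholds the image (Otsu) and returns the bounding boxes of large
  bright connected regions, adequate for the schematic faces the
  synthetic generator produces and for smoke tests;
* :class:`GroundTruthBoxProvider` — returns boxes supplied up front,
  used in evaluation so detector quality never confounds results.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["FaceBox", "BrightRegionDetector", "GroundTruthBoxProvider", "NoFaceError"]

from dataclasses import dataclass


class NoFaceError(RuntimeError):
    """Raised when no face can be found in an image."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box in image pixels."""

    x: float
    y: float
    width: float
    height: float
    source: str = "detector"  # detector | previous-frame | manual

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"face box must have positive extent, got {self}")

    def as_tuple(self):
        return (self.x, self.y, self.width, self.height)

    def clamp(self, image_shape) -> "FaceBox":
        h, w = image_shape
        x0 = max(0.0, self.x)
        y0 = max(0.0, self.y)
        x1 = min(float(w), self.x + self.width)
        y1 = min(float(h), self.y + self.height)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"face box {self} lies outside image of shape {image_shape}")
        return FaceBox(x0, y0, x1 - x0, y1 - y0, self.source)


class BrightRegionDetector:
    """Largest-bright-region face detector for schematic/synthetic images.

    Finds the bright head ellipse by Otsu thresholding, then maps its
    bounding box to the landmark-box convention the aligner is trained
    with, using the known geometry of the schematic-face generator
    (head ellipse semi-axes and landmark template extents). Regions
    smaller than ``min_area_frac`` of the image are ignored.
    """

    def __init__(self, min_area_frac: float = 0.02):
        self.min_area_frac = min_area_frac
        # Calibration constants from the schematic-face recipe: the head
        # ellipse spans 0.84 x 1.10 of the template extent E and is
        # raised by 0.05 E above the landmark centroid.
        from .shapes import TEMPLATE_29

        self._tmpl_min = TEMPLATE_29.min(axis=0) - 0.5
        self._tmpl_max = TEMPLATE_29.max(axis=0) - 0.5
        self._ellipse_span = np.array([0.84, 1.10])
        self._ellipse_lift = 0.05
        self._tmpl_centroid = TEMPLATE_29.mean(axis=0) - 0.5

    def __call__(self, img: np.ndarray) -> list[FaceBox]:
        from .ferns import BOX_MARGIN

        img = np.asarray(img, dtype=np.float64)
        if np.ptp(img) < 1e-9:
            return []
        mask = img > threshold_otsu(img)
        labels = label(mask)
        boxes = []
        for region in sorted(regionprops(labels), key=lambda r: -r.area):
            if region.area < self.min_area_frac * img.size:
                continue
            r0, c0, r1, c1 = region.bbox
            extent = (c1 - c0) / self._ellipse_span[0]
            ex, ey = c0 + (c1 - c0) / 2.0, r0 + (r1 - r0) / 2.0
            # face-frame origin: ellipse center minus centroid offset + lift
            fx = ex - self._tmpl_centroid[0] * extent
            fy = ey + self._ellipse_lift * extent - self._tmpl_centroid[1] * extent
            x0 = fx + self._tmpl_min[0] * extent
            y0 = fy + self._tmpl_min[1] * extent
            x1 = fx + self._tmpl_max[0] * extent
            y1 = fy + self._tmpl_max[1] * extent
            w, h = x1 - x0, y1 - y0
            boxes.append(
                FaceBox(x0 - BOX_MARGIN * w, y0 - BOX_MARGIN * h,
                        w * (1 + 2 * BOX_MARGIN), h * (1 + 2 * BOX_MARGIN),
                        source="detector")
            )
        return boxes


class GroundTruthBoxProvider:
    """Returns a pre-supplied box regardless of image content."""

    def __init__(self, box: FaceBox):
        self.box = box

    def __call__(self, img: np.ndarray) -> list[FaceBox]:
        return [self.box]
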