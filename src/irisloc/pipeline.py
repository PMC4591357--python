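"""End-to-end eye-center localization: align, vote, select, evaluate.

For one image the pipeline runs

1. face acquisition (detector plugin, manual box, or previous frame),
2. cascaded-fern alignment (multi-initialization, averaged),
3. per-eye multi-scale isophote candidate generation,
4. AISC reconstruction from the aligned landmarks and selection of the
   candidate nearest the reconstruction (fallback: the reconstruction
   itself when no candidates exist).

Evaluation uses the normalized error e = max(d_left, d_right) / omega,
where d are the Euclidean eye-center errors and omega the true
inter-ocular distance (worst-eye convention; best/average variants are
reported alongside). Accuracy curves tabulate the fraction of images
with e <= tau over a threshold grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aisc, ferns
from .candidates import CandidateConfig, CandidateSet, collect_candidates
from .detectors import FaceBox, NoFaceError
from .isophote import NoCandidateError
from .shapes import LANDMARK_SCHEME_29

logger = logging.getLogger("irisloc")

__all__ = [
    "EyeEstimate",
    "EvalRecord",
    "detect_face",
    "eye_regions",
    "locate",
    "normalized_error",
    "accuracy_curve",
    "track",
    "DEFAULT_THRESHOLDS",
    "TrackingLostError",
]

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25)

EYE_LANDMARKS = {
    "left": ("left_eye_outer", "left_eye_top", "left_eye_inner", "left_eye_bottom",
             "left_eye_center"),
    "right": ("right_eye_inner", "right_eye_top", "right_eye_outer", "right_eye_bottom",
              "right_eye_center"),
}


class TrackingLostError(RuntimeError):
    """Raised when tracking fails for more consecutive frames than allowed."""


@dataclass
class EyeEstimate:
    """Final per-image result: both eye centers plus diagnostics."""

    left: np.ndarray  # (x, y)
    right: np.ndarray
    landmarks: np.ndarray  # (29, 2) aligned shape
    fallback: dict = field(default_factory=dict)  # side -> bool
    candidate_sets: dict = field(default_factory=dict)  # side -> CandidateSet


@dataclass(frozen=True)
class EvalRecord:
    d_left: float
    d_right: float
    omega: float
    e_worst: float
    e_best: float
    e_avg: float


def detect_face(img: np.ndarray, detector, manual_box: FaceBox | None = None) -> FaceBox:
    """Largest detected face, or the manual override box verbatim."""
    if manual_box is not None:
        return manual_box
    boxes = detector(img)
    if not boxes:
        raise NoFaceError("no face found")
    return max(boxes, key=lambda b: b.width * b.height).clamp(img.shape)


def eye_regions(
    landmarks: np.ndarray,
    image_shape,
    margin: float = 0.4,
    min_size: int = 24,
):
    """Axis-aligned crop boxes around each eye's landmarks.

    Each eye's landmark bounding box is expanded by ``margin`` (fraction
    per side), grown to at least ``min_size`` px in each dimension, and
    clamped to the image. Returns ``{side: (x0, y0, x1, y1)}`` as int
    pixel bounds.
    """
    s = LANDMARK_SCHEME_29
    h, w = image_shape
    out = {}
    for side, names in EYE_LANDMARKS.items():
        pts = landmarks[[s[n] for n in names]]
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        bw, bh = x1 - x0, y1 - y0
        if bw < 1e-6 or bh < 1e-6:
            raise ValueError(f"degenerate {side}-eye landmark spread")
        x0, x1 = x0 - margin * bw, x1 + margin * bw
        y0, y1 = y0 - margin * bh, y1 + margin * bh
        # grow to min_size, centered
        if x1 - x0 < min_size:
            cx = (x0 + x1) / 2
            x0, x1 = cx - min_size / 2, cx + min_size / 2
        if y1 - y0 < min_size:
            cy = (y0 + y1) / 2
            y0, y1 = cy - min_size / 2, cy + min_size / 2
        xi0, yi0 = max(0, int(np.floor(x0))), max(0, int(np.floor(y0)))
        xi1, yi1 = min(w, int(np.ceil(x1))), min(h, int(np.ceil(y1)))
        if xi1 - xi0 < 3 or yi1 - yi0 < 3:
            raise ValueError(f"{side}-eye region degenerate after clamping")
        out[side] = (xi0, yi0, xi1, yi1)
    return out


def locate(
    img: np.ndarray,
    box: FaceBox,
    model: ferns.CascadeModel,
    config: CandidateConfig | None = None,
    n_init: int = 5,
    seed: int = 0,
    mic_only: bool = False,
) -> EyeEstimate:
    """Full hybrid localization for one image.

    ``mic_only=True`` is the ablation baseline: the alignment still
    supplies the eye regions but the strongest isocenter is taken
    directly, skipping the shape-constraint selection.
    """
    img = np.asarray(img, dtype=np.float64)
    config = config or CandidateConfig()
    shape = ferns.predict(img, box.as_tuple(), model, n_init=n_init, seed=seed)
    regions = eye_regions(shape, img.shape)
    centers, fallback_flags, cand_sets = {}, {}, {}
    for side in ("left", "right"):
        x0, y0, x1, y1 = regions[side]
        crop = img[y0:y1, x0:x1]
        try:
            cands = collect_candidates(crop, region_offset=(x0, y0), config=config)
        except (ValueError, NoCandidateError) as exc:
            logger.info("candidate stage failed for %s eye: %s", side, exc)
            cands = CandidateSet()
        w = model.aisc[side]
        weights = aisc.ReconstructionWeights(
            omega=np.asarray(w["omega"]),
            basis=aisc.NeighborBasis(
                center_id=int(w["center_id"]),
                neighbor_ids=tuple(int(i) for i in w["neighbor_ids"]),
            ),
        )
        m_prime = aisc.reconstruct(shape, weights)
        if mic_only:
            if len(cands) > 0:
                best = max(cands, key=lambda c: (c.rank_in_map == 1, c.response))
                centers[side] = np.array([best.x, best.y])
                fallback_flags[side] = False
            else:
                centers[side] = m_prime
                fallback_flags[side] = True
        else:
            centers[side], fallback_flags[side] = aisc.select(cands, m_prime)
        cand_sets[side] = cands
    logger.info(
        "locate: %d/%d candidates (L/R), fallback=%s",
        len(cand_sets["left"]), len(cand_sets["right"]), fallback_flags,
    )
    return EyeEstimate(
        left=centers["left"],
        right=centers["right"],
        landmarks=shape,
        fallback=fallback_flags,
        candidate_sets=cand_sets,
    )


def normalized_error(
    est: EyeEstimate, truth_left, truth_right, convention: str = "worst"
) -> EvalRecord:
    """Normalized eye-center error record for one image.

    ``convention`` only affects which value a caller should read as the
    headline number; all three (worst/best/avg) are always computed.
    The legacy printed-sum variant ((d_l + d_r)/omega) is available as
    convention='sum' and is stored in e_worst's place.
    """
    truth_left = np.asarray(truth_left, dtype=np.float64)
    truth_right = np.asarray(truth_right, dtype=np.float64)
    omega = float(np.linalg.norm(truth_right - truth_left))
    if omega <= 0:
        raise ValueError("coincident ground-truth eye centers")
    d_left = float(np.linalg.norm(est.left - truth_left))
    d_right = float(np.linalg.norm(est.right - truth_right))
    if convention == "sum":
        e_worst = (d_left + d_right) / omega
    elif convention == "worst":
        e_worst = max(d_left, d_right) / omega
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return EvalRecord(
        d_left=d_left,
        d_right=d_right,
        omega=omega,
        e_worst=e_worst,
        e_best=min(d_left, d_right) / omega,
        e_avg=0.5 * (d_left + d_right) / omega,
    )


def accuracy_curve(records, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Fraction of records with e <= tau, per convention and threshold."""
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    rows = []
    for tau in thresholds:
        rows.append(
            {
                "threshold": tau,
                "worst": np.mean([r.e_worst <= tau for r in records]),
                "best": np.mean([r.e_best <= tau for r in records]),
                "avg": np.mean([r.e_avg <= tau for r in records]),
            }
        )
    return pd.DataFrame(rows)


def track(
    frames,
    model: ferns.CascadeModel,
    detector=None,
    config: CandidateConfig | None = None,
    seed: int = 0,
    max_failures: int = 5,
    first_box: FaceBox | None = None,
) -> list[EyeEstimate]:
    """Frame-to-frame tracking over an ordered frame sequence.

    Frame 1 uses the detector (or ``first_box``); each later frame
    derives its face box from the previous frame's landmarks' bounding
    box (same margin convention as training boxes). A failed frame
    re-runs detection; ``max_failures`` consecutive failures raise
    :class:`TrackingLostError`.
    """
    estimates: list[EyeEstimate] = []
    box: FaceBox | None = first_box
    failures = 0
    for i, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=np.float64)
        if box is None:
            box = detect_face(frame, detector)
        try:
            est = locate(frame, box, model, config=config, seed=seed)
            failures = 0
        except (ValueError, NoFaceError) as exc:
            logger.info("frame %d failed (%s); re-running detection", i, exc)
            failures += 1
            if failures > max_failures:
                raise TrackingLostError(f"lost track at frame {i}") from exc
            box = None
            if detector is None:
                raise TrackingLostError(f"no detector to recover at frame {i}") from exc
            box = detect_face(frame, detector)
            est = locate(frame, box, model, config=config, seed=seed)
        estimates.append(est)
        x, y, w, h = ferns.landmark_face_box(est.landmarks)
        box = FaceBox(x, y, w, h, source="previous-frame").clamp(frame.shape)
    return estimates
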