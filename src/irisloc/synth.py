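"""Seeded synthetic fixtures: eye patches and schematic faces.

Two generators make the whole pipeline trainable and testable without
any dataset download:

* :func:`render_eye` draws an anti-aliased eye patch — bright sclera,
  dark circular iris with a darker pupil — with a known center and
  radius, plus optional eyelid occlusion, a corneal glint, additive
  noise, and dark-bar distractors standing in for eyebrows.

* :func:`render_face` draws a schematic frontal face whose features
  (brows, sclera/iris/pupil, nose, mouth) are rendered directly from a
  29-landmark ground-truth shape, posed by translation, scale, in-plane
  rotation, and a horizontal shear standing in for yaw.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .shapes import LANDMARK_SCHEME_29, TEMPLATE_29

__all__ = [
    "EyeFixtureSpec",
    "FaceFixtureSpec",
    "render_eye",
    "render_face",
    "make_dataset",
    "sample_face_specs",
]


def _soft_disk(h: int, w: int, cx: float, cy: float, radius: float, edge: float = 1.0):
    """Anti-aliased disk mask: 1 inside, 0 outside, linear ramp at the rim."""
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)
    return np.clip((radius + edge / 2 - dist) / edge, 0.0, 1.0)


def _soft_ellipse(h, w, cx, cy, rx, ry, edge=1.0):
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot((xx - cx) / max(rx, 1e-9), (yy - cy) / max(ry, 1e-9))
    scale = min(rx, ry)
    return np.clip((1.0 + edge / (2 * scale) - dist) * scale / edge, 0.0, 1.0)


def _blend(canvas, mask, value):
    return canvas * (1.0 - mask) + value * mask


@dataclass(frozen=True)
class EyeFixtureSpec:
    """Recipe for one synthetic eye patch with known iris center."""

    size: tuple[int, int] = (48, 48)  # (height, width)
    iris_center: tuple[float, float] = (24.0, 24.0)  # (x, y)
    iris_radius: float = 10.0
    pupil_radius: float = 4.0
    sclera_intensity: float = 220.0
    iris_intensity: float = 90.0
    pupil_intensity: float = 30.0
    eyelid_coverage: float = 0.0  # fraction of iris height hidden from the top
    glint: tuple[float, float, float] | None = None  # (dx, dy, radius) rel. center
    noise_sigma: float = 0.0  # fraction of dynamic range
    distractors: tuple[dict, ...] = ()  # e.g. {"kind": "bar", "y": 8, "height": 4, ...}
    seed: int = 0

    def validate(self) -> None:
        h, w = self.size
        if not (0 < self.pupil_radius < self.iris_radius < min(h, w) / 2):
            raise ValueError(
                "require 0 < pupil_radius < iris_radius < min(size)/2, got "
                f"pupil={self.pupil_radius}, iris={self.iris_radius}, size={self.size}"
            )
        if not (self.pupil_intensity < self.iris_intensity < self.sclera_intensity):
            raise ValueError("intensities must be ordered pupil < iris < sclera")
        if not 0.0 <= self.eyelid_coverage <= 1.0:
            raise ValueError(f"eyelid_coverage must be in [0, 1], got {self.eyelid_coverage}")


def render_eye(spec: EyeFixtureSpec):
    """Render an eye patch; returns ``(image, (cx, cy))`` with the exact center."""
    spec.validate()
    h, w = spec.size
    cx, cy = spec.iris_center
    img = np.full((h, w), spec.sclera_intensity, dtype=np.float64)
    img = _blend(img, _soft_disk(h, w, cx, cy, spec.iris_radius), spec.iris_intensity)
    img = _blend(img, _soft_disk(h, w, cx, cy, spec.pupil_radius), spec.pupil_intensity)
    if spec.glint is not None:
        gx, gy, gr = spec.glint
        img = _blend(img, _soft_disk(h, w, cx + gx, cy + gy, gr), spec.sclera_intensity + 20)
    for d in spec.distractors:
        if d.get("kind", "bar") != "bar":
            raise ValueError(f"unknown distractor kind: {d!r}")
        y0 = float(d["y"])
        bar_h = float(d.get("height", 4.0))
        x0 = float(d.get("x", 0.0))
        bar_w = float(d.get("width", w))
        val = float(d.get("intensity", spec.pupil_intensity))
        yy, xx = np.mgrid[0:h, 0:w]
        mask_y = np.clip(np.minimum(yy - y0 + 1, y0 + bar_h - yy + 1), 0, 1)
        mask_x = np.clip(np.minimum(xx - x0 + 1, x0 + bar_w - xx + 1), 0, 1)
        img = _blend(img, mask_y * mask_x, val)
    if spec.eyelid_coverage > 0:
        # Lid edge sweeps from the iris top (coverage 0) to its bottom
        # (coverage 1); everything above the edge becomes lid/skin.
        lid_y = cy + (2.0 * spec.eyelid_coverage - 1.0) * spec.iris_radius
        yy = np.arange(h, dtype=np.float64)[:, None]
        lid_mask = np.clip(lid_y - yy + 0.5, 0.0, 1.0) * np.ones((1, w))
        img = _blend(img, lid_mask, spec.sclera_intensity - 30)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        amp = spec.noise_sigma * (spec.sclera_intensity - spec.pupil_intensity)
        img = img + rng.normal(0.0, amp, size=img.shape)
    return img, (cx, cy)


# ---------------------------------------------------------------------------
# Schematic faces


@dataclass(frozen=True)
class FaceFixtureSpec:
    """Recipe for one schematic face with 29-landmark ground truth.

    Pose is an affine map applied to the canonical template: uniform
    scale, in-plane rotation (degrees), horizontal shear (standing in
    for yaw), then translation, all about the canvas center. Jitter is
    i.i.d. Gaussian per landmark, applied after posing; features are
    rendered from the jittered landmarks so image and annotation always
    agree.
    """

    canvas: tuple[int, int] = (128, 128)  # (height, width)
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    rotation_deg: float = 0.0
    shear: float = 0.0
    jitter_sigma: float = 0.0
    noise_sigma: float = 0.0
    skin_intensity: float = 190.0
    background_intensity: float = 60.0
    feature_intensity: float = 70.0
    sclera_intensity: float = 235.0
    iris_intensity: float = 90.0
    pupil_intensity: float = 30.0
    brow_weight: float = 1.0  # thickness multiplier for eyebrow bars
    render_iris: bool = True  # False emulates closed eyes
    eyelid_coverage: float = 0.0  # fraction of iris height hidden from the top
    glint: bool = False  # small specular highlight on each iris
    face_extent: float = 100.0  # template span on the canvas, px
    seed: int = 0


def _pose_matrix(spec: FaceFixtureSpec) -> np.ndarray:
    th = np.deg2rad(spec.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, spec.shear], [0.0, 1.0]])
    return spec.scale * rot @ shear


def face_landmarks(spec: FaceFixtureSpec) -> np.ndarray:
    """Ground-truth 29x2 landmark array for a spec (before rendering)."""
    h, w = spec.canvas
    center = np.array([w / 2.0, h / 2.0])
    base = (TEMPLATE_29 - 0.5) * spec.face_extent
    posed = base @ _pose_matrix(spec).T + center + np.asarray(spec.translation)
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        posed = posed + rng.normal(0.0, spec.jitter_sigma, size=posed.shape)
    return posed


def _thick_segment(h, w, p0, p1, thickness):
    """Soft mask of a line segment with round caps."""
    yy, xx = np.mgrid[0:h, 0:w]
    p = np.stack([xx, yy], axis=-1).astype(np.float64)
    d = np.asarray(p1, dtype=np.float64) - np.asarray(p0, dtype=np.float64)
    len2 = float(d @ d)
    if len2 < 1e-12:
        dist = np.hypot(xx - p0[0], yy - p0[1])
    else:
        t = np.clip(((p - p0) @ d) / len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(p - proj, axis=-1)
    return np.clip(thickness / 2 + 0.5 - dist, 0.0, 1.0)


def render_face(spec: FaceFixtureSpec):
    """Render a schematic face; returns ``(image, landmarks_29x2)``."""
    h, w = spec.canvas
    lm = face_landmarks(spec)
    s = LANDMARK_SCHEME_29
    img = np.full((h, w), spec.background_intensity, dtype=np.float64)

    # Head: ellipse fitted to the landmark spread.
    cx, cy = lm[:, 0].mean(), lm[:, 1].mean() - 0.05 * spec.face_extent * spec.scale
    rx = 0.42 * spec.face_extent * spec.scale
    ry = 0.55 * spec.face_extent * spec.scale
    img = _blend(img, _soft_ellipse(h, w, cx, cy, rx, ry), spec.skin_intensity)

    iod = np.linalg.norm(lm[s["right_eye_center"]] - lm[s["left_eye_center"]])
    if spec.brow_weight > 0:
        brow_th = max(1.5, 0.09 * iod) * spec.brow_weight
        for a, b in [("left_brow_outer", "left_brow_mid"), ("left_brow_mid", "left_brow_inner"),
                     ("right_brow_inner", "right_brow_mid"), ("right_brow_mid", "right_brow_outer")]:
            img = _blend(img, _thick_segment(h, w, lm[s[a]], lm[s[b]], brow_th),
                         spec.feature_intensity)

    for side in ("left", "right"):
        ec = lm[s[f"{side}_eye_center"]]
        outer, inner = lm[s[f"{side}_eye_outer"]], lm[s[f"{side}_eye_inner"]]
        top, bottom = lm[s[f"{side}_eye_top"]], lm[s[f"{side}_eye_bottom"]]
        ew = np.linalg.norm(outer - inner) / 2.0
        eh = np.linalg.norm(top - bottom) / 2.0
        # closed eyes (render_iris False) stay smooth skin: no sclera either
        if spec.render_iris:
            img = _blend(img, _soft_ellipse(h, w, ec[0], ec[1], ew, max(eh, 2.0)),
                         spec.sclera_intensity)
            ir = 0.40 * np.linalg.norm(outer - inner) * 0.5
            img = _blend(img, _soft_disk(h, w, ec[0], ec[1], ir), spec.iris_intensity)
            img = _blend(img, _soft_disk(h, w, ec[0], ec[1], 0.45 * ir), spec.pupil_intensity)
            if spec.glint:
                img = _blend(img, _soft_disk(h, w, ec[0] + 0.35 * ir, ec[1] - 0.35 * ir,
                                             max(0.3 * ir, 1.0)), 255.0)
        if spec.eyelid_coverage > 0:
            ir = 0.40 * np.linalg.norm(outer - inner) * 0.5
            lid_y = ec[1] + (2.0 * spec.eyelid_coverage - 1.0) * ir
            yy = np.arange(h, dtype=np.float64)[:, None]
            lid_rows = np.clip(lid_y - yy + 0.5, 0.0, 1.0) * np.ones((1, w))
            eye_mask = _soft_ellipse(h, w, ec[0], ec[1], ew + 1, max(eh, 2.0) + 1)
            img = _blend(img, lid_rows * eye_mask, spec.skin_intensity - 10)

    img = _blend(img, _thick_segment(h, w, lm[s["nose_bridge"]], lm[s["nose_tip"]], 1.5),
                 spec.feature_intensity + 60)
    for n in ("nose_left", "nose_right"):
        img = _blend(img, _soft_disk(h, w, lm[s[n]][0], lm[s[n]][1], 1.5),
                     spec.feature_intensity)
    mouth_pts = [lm[s[n]] for n in ("mouth_left", "mouth_top_left", "mouth_top",
                                    "mouth_top_right", "mouth_right", "mouth_bottom_right",
                                    "mouth_bottom", "mouth_bottom_left", "mouth_left")]
    for a, b in zip(mouth_pts[:-1], mouth_pts[1:]):
        img = _blend(img, _thick_segment(h, w, a, b, 2.0), spec.feature_intensity + 30)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 2)
        amp = spec.noise_sigma * (spec.sclera_intensity - spec.background_intensity)
        img = img + rng.normal(0.0, amp, size=img.shape)
    return img, lm


def sample_face_specs(
    n: int,
    seed: int,
    canvas: tuple[int, int] = (128, 128),
    translation_px: float = 5.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    rotation_deg: float = 10.0,
    shear_max: float = 0.1,
    jitter_sigma: float = 0.5,
    noise_sigma: float = 0.02,
    eyelid_range: tuple[float, float] = (0.0, 0.0),
    glint_prob: float = 0.0,
    **overrides,
) -> list[FaceFixtureSpec]:
    """Draw n face specs with poses sampled from the default study ranges."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        specs.append(
            FaceFixtureSpec(
                canvas=canvas,
                translation=tuple(rng.uniform(-translation_px, translation_px, 2)),
                scale=float(rng.uniform(*scale_range)),
                rotation_deg=float(rng.uniform(-rotation_deg, rotation_deg)),
                shear=float(rng.uniform(-shear_max, shear_max)),
                jitter_sigma=jitter_sigma,
                noise_sigma=noise_sigma,
                eyelid_coverage=float(rng.uniform(*eyelid_range)),
                glint=bool(rng.random() < glint_prob),
                seed=int(rng.integers(0, 2**31 - 1)),
                **overrides,
            )
        )
    return specs


def distractor_trial_specs(n: int, seed: int) -> list[FaceFixtureSpec]:
    """Study conditions for the robustness ablation trials.

    Emulates the regime where a plain maximum-isocenter estimate fails:
    heavy dark eyebrows close to the eye plus degraded irises (partial
    eyelid closure on every face, a specular glint on half), so the
    strongest isocenter frequently sits on the brow or lid edge while a
    weaker candidate remains at the true center.
    """
    return sample_face_specs(
        n, seed, brow_weight=2.5, feature_intensity=45.0,
        eyelid_range=(0.3, 0.6), glint_prob=0.5, noise_sigma=0.04,
    )


def make_dataset(n: int, out_dir, seed: int = 0, spec_overrides: dict | None = None):
    """Write n rendered faces + annotations to disk; returns the manifest path.

    Produces ``face_%03d.png`` images, ``face_%03d.pts`` landmark files
    (points-list dialect), ``face_%03d.eye`` eye-center files, and a
    ``manifest.csv`` recording each sample's seed and pose.
    """
    import imageio.v3 as iio

    from .io import write_eye_file, write_landmarks_pts

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = sample_face_specs(n, seed, **(spec_overrides or {}))
    scheme = LANDMARK_SCHEME_29
    rows = []
    for i, spec in enumerate(specs):
        img, lm = render_face(spec)
        name = f"face_{i:03d}"
        iio.imwrite(out / f"{name}.png", np.clip(img, 0, 255).astype(np.uint8))
        write_landmarks_pts(out / f"{name}.pts", lm)
        left = lm[scheme["left_eye_center"]]
        right = lm[scheme["right_eye_center"]]
        write_eye_file(out / f"{name}.eye", left, right)
        rows.append(
            dict(filename=f"{name}.png", seed=spec.seed, scale=spec.scale,
                 rotation_deg=spec.rotation_deg, shear=spec.shear,
                 tx=spec.translation[0], ty=spec.translation[1]))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
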