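"""Multi-scale eye-center candidate generation.

One center map can be fooled by eyebrows, eyelids or glints, so the
pipeline builds five center maps of the same eye region under
increasingly wide Gaussian smoothing, blurs each with a small mean
filter, and keeps the two strongest, mutually separated isocenters per
map — up to ten candidates per eye, pooled in base-image coordinates.
The downstream shape-constraint selector then picks among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import isophote
from .isophote import CenterMap, NoCandidateError

__all__ = [
    "ScaleBank",
    "Candidate",
    "CandidateSet",
    "CandidateConfig",
    "build_scale_bank",
    "blur_map",
    "top2",
    "collect_candidates",
]

#: Reference eye-region width (px) at which the fixed-pixel defaults
#: (21-px separation, 6-px mean filter) were tuned; scaled modes divide
#: the current region width by this.
W_REF = 50.0

#: Geometric Gaussian-sigma schedule at W_REF, scaled by region width.
BASE_SIGMAS = (1.0, 1.5, 2.25, 3.4, 5.1)


@dataclass(frozen=True)
class CandidateConfig:
    """Knobs of the multi-scale candidate stage.

    sigmas: explicit Gaussian widths, or None to scale BASE_SIGMAS by
        region_width / 60.
    min_separation_px: required distance between the two per-map picks.
    separation_scaling / blur_scaling: 'scaled' multiplies the pixel
        value by region_width / W_REF; 'fixed' uses it verbatim.
    r_bounds_frac: displacement-magnitude bounds as fractions of the
        region width.
    """

    sigmas: tuple[float, ...] | None = None
    min_separation_px: float = 21.0
    separation_scaling: str = "scaled"
    blur_size: int = 6
    blur_scaling: str = "scaled"
    r_bounds_frac: tuple[float, float] = (0.05, 0.5)
    derivative_scheme: str = "central"

    def resolved_sigmas(self, region_width: int) -> tuple[float, ...]:
        if self.sigmas is not None:
            return tuple(self.sigmas)
        s = region_width / 60.0
        return tuple(b * s for b in BASE_SIGMAS)

    def resolved_separation(self, region_width: int) -> float:
        if self.separation_scaling == "fixed":
            return self.min_separation_px
        return self.min_separation_px * region_width / W_REF

    def resolved_blur(self, region_width: int) -> int:
        if self.blur_scaling == "fixed":
            return self.blur_size
        return max(2, round(self.blur_size * region_width / W_REF))


@dataclass(frozen=True)
class ScaleBank:
    """Five differently-smoothed center maps of one eye region."""

    sigmas: tuple[float, ...]
    maps: tuple[CenterMap, ...]


@dataclass(frozen=True)
class Candidate:
    """One scored eye-center candidate in base-image coordinates."""

    x: float
    y: float
    response: float
    scale_index: int
    rank_in_map: int


@dataclass(frozen=True)
class CandidateSet:
    """Up to ten candidates (two per scale) for one eye."""

    candidates: tuple[Candidate, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def build_scale_bank(
    eye_img: np.ndarray, sigmas, config: CandidateConfig | None = None
) -> ScaleBank:
    """Run the voting pipeline at each Gaussian scale of an eye region."""
    config = config or CandidateConfig()
    eye_img = np.asarray(eye_img, dtype=np.float64)
    h, w = eye_img.shape
    if h < 16 or w < 16:
        raise ValueError(f"eye region too small for multi-scale voting: {eye_img.shape}")
    sigmas = tuple(float(s) for s in sigmas)
    if len(sigmas) != 5 or any(s <= 0 for s in sigmas):
        raise ValueError(f"expected 5 positive sigmas, got {sigmas}")
    if any(b > a for a, b in zip(sigmas[1:], sigmas[:-1])):
        raise ValueError(f"sigmas must be non-decreasing, got {sigmas}")
    lo, hi = config.r_bounds_frac
    r_bounds = (lo * w, hi * w)
    maps = []
    for sigma in sigmas:
        sm = isophote.smooth(eye_img, sigma)
        d = isophote.derivatives(sm, scheme=config.derivative_scheme)
        k, _ = isophote.curvature(d)
        vf = isophote.displacement(d)
        wgt = isophote.curvedness(d)
        maps.append(isophote.accumulate(vf, wgt, k, r_bounds))
    return ScaleBank(sigmas=sigmas, maps=tuple(maps))


def blur_map(cm: CenterMap, size: tuple[int, int] = (6, 6)) -> CenterMap:
    """Box-average a center map (reflect borders).

    Even-sized kernels anchor at cell (size//2, size//2), i.e. the
    lower-right of center. Constants pass through unchanged; total mass
    is conserved whenever the outer size//2 ring of the map is empty.
    """
    sh, sw = size
    if sh <= 0 or sw <= 0:
        raise ValueError(f"blur size must be positive, got {size}")
    votes = ndimage.uniform_filter(cm.votes, size=size, mode="reflect")
    return CenterMap(votes=votes, n_votes=cm.n_votes)


def top2(cm: CenterMap, min_separation: float):
    """The map's strongest cell plus the strongest cell far enough away.

    Returns a list of one or two ``((row, col), response)`` pairs: the
    global maximum, and the highest-response cell at Euclidean distance
    >= ``min_separation`` from it. If no such cell has positive
    response, only the first point is returned.
    """
    (r0, c0), v0 = isophote.mic(cm)
    rr, cc = np.ogrid[: cm.votes.shape[0], : cm.votes.shape[1]]
    far = (rr - r0) ** 2 + (cc - c0) ** 2 >= min_separation**2
    masked = np.where(far, cm.votes, -np.inf)
    idx = int(np.argmax(masked))
    r1, c1 = np.unravel_index(idx, cm.votes.shape)
    v1 = float(masked[r1, c1])
    if not np.isfinite(v1) or v1 <= 0:
        return [((r0, c0), v0)]
    return [((r0, c0), v0), ((int(r1), int(c1)), v1)]


def _refine_peak(votes: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Sub-pixel peak position: mass centroid of the 3x3 neighborhood.

    Standard accumulator-peak interpolation; shifts the integer cell by
    at most one pixel and keeps identical maps giving identical peaks.
    """
    h, w = votes.shape
    r0, r1 = max(r - 1, 0), min(r + 2, h)
    c0, c1 = max(c - 1, 0), min(c + 2, w)
    win = votes[r0:r1, c0:c1]
    total = win.sum()
    if total <= 0:
        return float(r), float(c)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((win * rr).sum() / total), float((win * cc).sum() / total)


def collect_candidates(
    eye_img: np.ndarray,
    region_offset: tuple[float, float] = (0.0, 0.0),
    config: CandidateConfig | None = None,
) -> CandidateSet:
    """Pool up to ten separation-constrained isocenters for one eye.

    ``region_offset`` is the (x, y) of the eye region's top-left corner
    in the base image; candidate coordinates are translated into
    base-image coordinates. Maps with no votes contribute nothing; an
    all-empty bank yields an empty set (the pipeline then falls back to
    the alignment estimate).
    """
    config = config or CandidateConfig()
    eye_img = np.asarray(eye_img, dtype=np.float64)
    w = eye_img.shape[1]
    sigmas = config.resolved_sigmas(w)
    bank = build_scale_bank(eye_img, sigmas, config)
    sep = config.resolved_separation(w)
    blur = config.resolved_blur(w)
    ox, oy = region_offset
    out = []
    for si, cm in enumerate(bank.maps):
        if cm.n_votes == 0:
            continue
        blurred = blur_map(cm, (blur, blur))
        try:
            picks = top2(blurred, sep)
        except NoCandidateError:
            continue
        for rank, ((r, c), v) in enumerate(picks, start=1):
            if v <= 0:
                continue
            rf, cf = _refine_peak(blurred.votes, r, c)
            out.append(
                Candidate(x=cf + ox, y=rf + oy, response=v, scale_index=si, rank_in_map=rank)
            )
    return CandidateSet(candidates=tuple(out))
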