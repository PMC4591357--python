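"""Isophote-curvature center voting for a single eye-region image.

An isophote is a curve of constant luminance; around the iris/pupil
boundary isophotes are approximately circular, and every pixel on such a
curve can estimate the circle's center from local derivatives alone.

For a luminance field L(x, y) with first derivatives Lx, Ly and second
derivatives Lxx, Lxy, Lyy, the isophote curvature (the reciprocal of the
radius of the osculating circle) is

    k = - (Ly^2 Lxx - 2 Lx Lxy Ly + Lx^2 Lyy) / (Lx^2 + Ly^2)^(3/2)

and the displacement vector from the pixel to the estimated circle
center is

    {Dx, Dy} = - {Lx, Ly} (Lx^2 + Ly^2) / (Ly^2 Lxx - 2 Lx Lxy Ly + Lx^2 Lyy)

Each pixel casts a vote of weight equal to its curvedness
sqrt(Lxx^2 + 2 Lxy^2 + Lyy^2) at the cell its displacement vector points
to; the accumulator is the *center map* and its global maximum the
maximum isocenter (MIC), the basic eye-center estimate.

Sign convention: for a dark interior on a bright surround (an iris on
sclera), curvature is negative and the displacement points inward, so
only negative-curvature votes are accumulated by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DerivativeStack",
    "VectorField",
    "CenterMap",
    "smooth",
    "derivatives",
    "curvature",
    "displacement",
    "curvedness",
    "accumulate",
    "mic",
    "NoCandidateError",
]


class NoCandidateError(RuntimeError):
    """Raised when a center map holds no votes to extract a MIC from."""


@dataclass(frozen=True)
class DerivativeStack:
    """First- and second-order derivatives of a luminance field.

    x is the column axis, y the row axis; all five fields share the
    source image's shape.
    """

    Lx: np.ndarray
    Ly: np.ndarray
    Lxx: np.ndarray
    Lxy: np.ndarray
    Lyy: np.ndarray

    @property
    def shape(self):
        return self.Lx.shape


@dataclass(frozen=True)
class VectorField:
    """Per-pixel displacement to the estimated isophote center.

    ``valid`` masks pixels whose curvature denominator is large enough
    for the displacement to be numerically meaningful.
    """

    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class CenterMap:
    """Vote accumulator aligned to an eye-region image."""

    votes: np.ndarray
    n_votes: int

    @property
    def shape(self):
        return self.votes.shape


def smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-filter an image with reflect border handling."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = np.asarray(img, dtype=np.float64)
    return ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")


def derivatives(img: np.ndarray, scheme: str = "central") -> DerivativeStack:
    """Compute the five derivative fields of a (smoothed) image.

    ``scheme='central'`` uses central differences, which are exact for
    quadratic luminance fields at interior pixels; ``scheme='sobel'``
    uses the Sobel operator. Lxy is the x-derivative of the y-derivative.
    """
    img = np.asarray(img, dtype=np.float64)
    if min(img.shape) < 3:
        raise ValueError(f"image must be at least 3x3 for derivatives, got {img.shape}")
    if scheme == "central":
        Ly, Lx = np.gradient(img)
        Lyy, Lxy = np.gradient(Ly)
        _, Lxx = np.gradient(Lx)
    elif scheme == "sobel":
        # Sobel kernels include a factor of 8 (smoothing x derivative);
        # normalize so a unit ramp yields unit derivative.
        Lx = ndimage.sobel(img, axis=1, mode="reflect") / 8.0
        Ly = ndimage.sobel(img, axis=0, mode="reflect") / 8.0
        Lxx = ndimage.sobel(Lx, axis=1, mode="reflect") / 8.0
        Lxy = ndimage.sobel(Ly, axis=1, mode="reflect") / 8.0
        Lyy = ndimage.sobel(Ly, axis=0, mode="reflect") / 8.0
    else:
        raise ValueError(f"unknown derivative scheme: {scheme!r}")
    return DerivativeStack(Lx=Lx, Ly=Ly, Lxx=Lxx, Lxy=Lxy, Lyy=Lyy)


def _denominator(d: DerivativeStack) -> np.ndarray:
    """Second-order directional term shared by curvature and displacement."""
    return d.Ly**2 * d.Lxx - 2.0 * d.Lx * d.Lxy * d.Ly + d.Lx**2 * d.Lyy


def _tolerance(d: DerivativeStack, rel_tol: float) -> float:
    # Scale the underflow tolerance with the squared gradient magnitude
    # so validity is invariant to affine intensity rescaling.
    g2 = d.Lx**2 + d.Ly**2
    peak = float(g2.max())
    return rel_tol * peak if peak > 0 else rel_tol


def curvature(d: DerivativeStack, rel_tol: float = 1e-8):
    """Isophote curvature field and its validity mask.

    Returns ``(k, valid)``; pixels where the gradient magnitude cube
    underflows are invalid (flat regions have no defined isophote).
    """
    g2 = d.Lx**2 + d.Ly**2
    g32 = g2**1.5
    valid = g32 > _tolerance(d, rel_tol) ** 1.5
    k = np.zeros_like(g2)
    np.divide(-_denominator(d), g32, out=k, where=valid)
    return k, valid


def displacement(d: DerivativeStack, rel_tol: float = 1e-8) -> VectorField:
    """Per-pixel displacement vectors to the estimated isophote centers.

    Pixels whose denominator magnitude falls below a tolerance scaled to
    the image's squared dynamic range are flagged invalid rather than
    producing exploding vectors.
    """
    den = _denominator(d)
    g2 = d.Lx**2 + d.Ly**2
    valid = np.abs(den) > _tolerance(d, rel_tol)
    dx = np.zeros_like(g2)
    dy = np.zeros_like(g2)
    np.divide(-d.Lx * g2, den, out=dx, where=valid)
    np.divide(-d.Ly * g2, den, out=dy, where=valid)
    return VectorField(dx=dx, dy=dy, valid=valid)


def curvedness(d: DerivativeStack) -> np.ndarray:
    """Second-order structure magnitude used as the vote weight.

    sqrt(Lxx^2 + 2 Lxy^2 + Lyy^2); non-negative everywhere, zero on
    flat and linear luminance fields.
    """
    return np.sqrt(d.Lxx**2 + 2.0 * d.Lxy**2 + d.Lyy**2)


def accumulate(
    vf: VectorField,
    w: np.ndarray,
    k: np.ndarray,
    r_bounds: tuple[float, float],
    dark_center_only: bool = True,
) -> CenterMap:
    """Accumulate curvedness-weighted votes into a center map.

    Each valid pixel whose displacement magnitude lies in ``r_bounds``
    casts a vote of weight ``w`` at the rounded cell its displacement
    points to; votes landing outside the image are discarded, as is the
    outermost 1-px ring of voters (border derivatives are one-sided).
    With ``dark_center_only`` (the default) only negative-curvature
    votes — dark interior, bright surround — are kept.
    """
    r_min, r_max = r_bounds
    if not (0 < r_min < r_max):
        raise ValueError(f"require 0 < r_min < r_max, got {r_bounds}")
    h, wd = vf.dx.shape
    mag = np.hypot(vf.dx, vf.dy)
    voters = vf.valid & (mag >= r_min) & (mag <= r_max)
    if dark_center_only:
        voters &= k < 0
    voters[0, :] = voters[-1, :] = False
    voters[:, 0] = voters[:, -1] = False

    rows, cols = np.nonzero(voters)
    tr = np.round(rows + vf.dy[rows, cols]).astype(np.intp)
    tc = np.round(cols + vf.dx[rows, cols]).astype(np.intp)
    inside = (tr >= 0) & (tr < h) & (tc >= 0) & (tc < wd)
    tr, tc = tr[inside], tc[inside]
    weights = w[rows, cols][inside]

    votes = np.zeros((h, wd))
    np.add.at(votes, (tr, tc), weights)
    return CenterMap(votes=votes, n_votes=int(tr.size))


def mic(cm: CenterMap):
    """Maximum isocenter: location and value of the map's global maximum.

    Returns ``((row, col), response)``. Ties are broken by smallest row
    then smallest column (row-major argmax order).
    """
    if cm.n_votes == 0:
        raise NoCandidateError("center map holds no votes")
    idx = int(np.argmax(cm.votes))
    r, c = np.unravel_index(idx, cm.votes.shape)
    return (int(r), int(c)), float(cm.votes[r, c])
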