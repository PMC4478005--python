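"""Otolith image to outline to radial profile.

A grayscale image of a single otolith is thresholded, the largest connected
foreground component (hole-filled) is traced as a closed sub-pixel polygon,
and the polygon is reduced to a single-valued *radial profile*: the distance
from the area centroid to the outline at 2^J equally spaced angles.  The
radial profile is the raw material for the wavelet shape descriptors.

Coordinate convention: outlines live in ordinary mathematical axes — x to
the right, y upward, counter-clockwise orientation.  Images are row-major
with row 0 at the top, so boundary coordinates from an image are flipped to
``y = (H - 1) - row`` on extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from shapely.geometry import Point, Polygon

from .io_core import ValidationError

__all__ = [
    "ExtractionError",
    "Outline",
    "RadiusVector",
    "binarize",
    "extract_outline",
    "centroid",
    "radial_profile",
]


class ExtractionError(RuntimeError):
    """No usable otolith outline could be obtained from the input."""


@dataclass
class Outline:
    """Closed polygon tracing one otolith perimeter, counter-clockwise.

    ``points`` is an (N, 2) array of (x, y); the closing edge from the last
    point back to the first is implicit.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValidationError("outline needs an (N, 2) array with N >= 3")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("outline contains non-finite coordinates")
        # drop a duplicated closing vertex so every vertex is unique
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def ensure_ccw(self) -> "Outline":
        if self.signed_area() < 0:
            return Outline(self.points[::-1].copy())
        return self


@dataclass
class RadiusVector:
    """Centroid-to-outline distances on a regular angular grid.

    ``radii[i]`` is the radius at angle ``360 * i / len(radii)`` degrees,
    measured counter-clockwise from the +x axis.
    """

    radii: np.ndarray
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        n = r.size
        if n < 16 or (n & (n - 1)) != 0:
            raise ValidationError(f"radius vector length must be a power of two >= 16, got {n}")
        if not np.all(r > 0):
            raise ValidationError("all radii must be positive")
        self.radii = r

    @property
    def angles_deg(self) -> np.ndarray:
        n = self.radii.size
        return 360.0 * np.arange(n) / n


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize(image: np.ndarray, method: str = "otsu", polarity: str = "auto") -> np.ndarray:
    """Threshold a grayscale image into a boolean otolith mask.

    polarity:
      * ``"light"`` — otolith brighter than background;
      * ``"dark"``  — otolith darker than background;
      * ``"auto"``  — pick the minority-pixel side; if both sides are
        similar in size, prefer the side whose largest connected component
        sits closest to the image center.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValidationError("image must be 2-D and at least 64x64")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite intensities")
    if img.max() == img.min():
        raise ExtractionError("no foreground: image is constant")
    if method != "otsu":
        raise ValidationError(f"unknown threshold method {method!r}")

    t = filters.threshold_otsu(img)
    light = img > t
    dark = ~light
    if polarity == "light":
        mask = light
    elif polarity == "dark":
        mask = dark
    elif polarity == "auto":
        mask = _pick_foreground(light, dark)
    else:
        raise ValidationError(f"unknown polarity {polarity!r}")
    if not mask.any():
        raise ExtractionError("no foreground: threshold left an empty mask")
    return mask


def _pick_foreground(light: np.ndarray, dark: np.ndarray) -> np.ndarray:
    nl, nd = int(light.sum()), int(dark.sum())
    if nl == 0:
        return dark
    if nd == 0:
        return light
    frac = nl / light.size
    if frac < 0.4:
        return light
    if frac > 0.6:
        return dark
    # ambiguous split: most-central largest component wins
    center = (np.array(light.shape) - 1) / 2.0
    scale = float(np.hypot(*light.shape))

    def centrality(mask: np.ndarray) -> float:
        lab, n = ndimage.label(mask)
        if n == 0:
            return np.inf
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        com = ndimage.center_of_mass(mask, lab, biggest)
        return float(np.hypot(com[0] - center[0], com[1] - center[1])) / scale

    return light if centrality(light) <= centrality(dark) else dark


# ---------------------------------------------------------------------------
# outline extraction
# ---------------------------------------------------------------------------


def extract_outline(mask: np.ndarray) -> Outline:
    """Trace the boundary of the largest foreground component.

    Interior holes are filled first, so the result is always a single simple
    closed curve.  A component touching the image border triggers a warning
    (the otolith may be clipped) but still yields an outline.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not m.any():
        raise ExtractionError("no foreground component in mask")

    lab, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        m = lab == keep
    m = ndimage.binary_fill_holes(m)

    if (
        m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
    ):
        warnings.warn("largest component touches the image border; otolith may be clipped")

    # pad so find_contours always closes the curve, then undo the offset
    padded = np.pad(m.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ExtractionError("no contour found at level 0.5")
    contour = max(contours, key=len) - 1.0  # (row, col), remove pad offset
    H = m.shape[0]
    xy = np.column_stack([contour[:, 1], (H - 1) - contour[:, 0]])
    return Outline(xy).ensure_ccw()


def centroid(outline: Outline) -> tuple[float, float]:
    """Area centroid of the outline polygon (shoelace moments)."""
    pts = outline.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12 * max(1.0, float(np.abs(pts).max()) ** 2):
        raise ExtractionError("degenerate (zero-area) outline polygon")
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy


def radial_profile(outline: Outline, n_angles: int = 512) -> RadiusVector:
    """Sample centroid-to-boundary distances at ``n_angles`` equal angles.

    For each ray the *farthest* intersection with the polygon boundary is
    taken, so concave indentations (the excisurae) show up as radius minima
    and the profile is always single-valued.  The centroid must lie inside
    the polygon.
    """
    if n_angles < 16 or (n_angles & (n_angles - 1)) != 0:
        raise ValidationError(f"n_angles must be a power of two >= 16, got {n_angles}")
    out = outline.ensure_ccw()
    cx, cy = centroid(out)
    if not Polygon(out.points).contains(Point(cx, cy)):
        raise ExtractionError(
            "centroid lies outside the outline polygon; the shape is too "
            "concave for a radial profile — review this specimen manually"
        )

    p = out.points - np.array([cx, cy])
    q = np.roll(p, -1, axis=0)
    e = q - p  # edge vectors, (E, 2)

    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    d = np.column_stack([np.cos(theta), np.sin(theta)])  # (A, 2)

    # ray c + t*d meets edge p + u*e where t = (p x e)/(d x e), u = (p x d)/(d x e)
    dxe = d[:, 0:1] * e[None, :, 1] - d[:, 1:2] * e[None, :, 0]  # (A, E)
    pxe = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]  # (E,)
    pxd = p[None, :, 0] * d[:, 1:2] - p[None, :, 1] * d[:, 0:1]  # (A, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = pxe[None, :] / dxe
        u = pxd / dxe
    valid = (np.abs(dxe) > 1e-300) & (u >= -1e-12) & (u < 1.0 + 1e-12) & (t > 0)
    t = np.where(valid, t, -np.inf)
    radii = t.max(axis=1)
    if not np.all(np.isfinite(radii)):
        raise ExtractionError("a ray from the centroid found no boundary intersection")
    return RadiusVector(radii=radii, centroid=(cx, cy))
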