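"""Ribcage masking: a closed cubic B-spline through rib centroids.

The liver is enclosed by the ribcage, so discarding everything outside a
smooth curve through the per-slice rib centroids removes the intercostal
muscle and most non-liver tissue before segmentation.  Bright bone
components are reduced to centroids, ordered by polar angle around the
body centroid, and joined by a closed (periodic) B-spline of degree 3
evaluated with De Boor's recursion.  Slices with too few ribs fall back to
the union of centroids from the neighbouring slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .preprocess import AIR_HU


class InsufficientCentroidsError(RuntimeError):
    """Fewer than 4 rib centroids: no closed spline can be fitted."""


class DegenerateCurveError(RuntimeError):
    """Centroids are collinear/degenerate; the curve encloses no area."""


@dataclass
class RibCentroidSet:
    """Angle-ordered rib centroids of one slice."""

    points: np.ndarray  # (n, 2) of (row, col)
    source_slice: int = -1

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class RibcageCurve:
    """Sampled closed spline and the binary mask of its interior."""

    polyline: np.ndarray  # (samples + 1, 2), first point == last point
    interior: np.ndarray  # 2D bool

    @property
    def interior_area(self) -> int:
        return int(self.interior.sum())


def detect_rib_centroids(
    slice_hu: np.ndarray,
    body_mask: np.ndarray,
    bone_hu_threshold: float = 200.0,
    area_limits: tuple[int, int] = (20, 2000),
    source_slice: int = -1,
) -> RibCentroidSet:
    """Centroids of bone-bright connected components, ordered by angle.

    Components are thresholded at ``bone_hu_threshold`` inside the body and
    kept when their pixel count lies within ``area_limits``.  Touching ribs
    merge into a single component and contribute one centroid.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise InsufficientCentroidsError("empty body mask")
    bone = (np.asarray(slice_hu) > bone_hu_threshold) & body_mask
    labels, n = ndimage.label(bone)
    pts = []
    for i in range(1, n + 1):
        comp = labels == i
        area = int(comp.sum())
        if area_limits[0] <= area <= area_limits[1]:
            pts.append(ndimage.center_of_mass(comp))
    if len(pts) < 4:
        raise InsufficientCentroidsError(f"found {len(pts)} rib centroids; need >= 4")
    pts = np.asarray(pts, dtype=np.float64)
    center = pts.mean(axis=0)
    angles = np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1])
    return RibCentroidSet(points=pts[np.argsort(angles)], source_slice=source_slice)


def deboor_point(t: float, knots: np.ndarray, ctrl: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate a B-spline curve at parameter ``t`` by De Boor's recursion."""
    k = int(np.searchsorted(knots, t, side="right")) - 1
    k = min(max(k, degree), len(ctrl) - 1)
    d = [ctrl[j + k - degree].astype(np.float64) for j in range(degree + 1)]
    for r in range(1, degree + 1):
        for j in range(degree, r - 1, -1):
            i = j + k - degree
            denom = knots[i + degree + 1 - r] - knots[i]
            alpha = 0.0 if denom == 0 else (t - knots[i]) / denom
            d[j] = (1.0 - alpha) * d[j - 1] + alpha * d[j]
    return d[degree]


def periodic_bspline_setup(points: np.ndarray, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Control points and uniform knot vector of the closed curve.

    The n input points are wrapped with their first ``degree`` points so
    that a uniform knot vector produces a C^(degree-1) closed curve over
    the parameter interval [degree, degree + n).
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    ctrl = np.concatenate([points, points[:degree]])
    knots = np.arange(n + 2 * degree + 1, dtype=np.float64)
    return ctrl, knots


def fit_ribcage_spline(
    centroids: RibCentroidSet,
    shape: tuple[int, int] | None = None,
    degree: int = 3,
    samples: int = 360,
) -> RibcageCurve:
    """Fit the closed degree-3 B-spline and rasterise its interior.

    The curve is sampled at ``samples`` parameters and closed by repeating
    the first sample; the interior mask is a polygon fill of the sampled
    polyline.
    """
    if centroids.count < 4:
        raise InsufficientCentroidsError(f"{centroids.count} centroids; need >= 4")
    ctrl, knots = periodic_bspline_setup(centroids.points, degree)
    n = centroids.count
    ts = degree + n * np.arange(samples) / samples
    pts = np.array([deboor_point(t, knots, ctrl, degree) for t in ts])
    polyline = np.vstack([pts, pts[:1]])
    # shoelace area to reject degenerate (collinear) centroid sets
    r, c = pts[:, 0], pts[:, 1]
    area2 = abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    if area2 < 1.0:
        raise DegenerateCurveError("spline curve encloses (near-)zero area")
    if shape is None:
        shape = (int(np.ceil(pts[:, 0].max())) + 2, int(np.ceil(pts[:, 1].max())) + 2)
    rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
    interior = np.zeros(shape, dtype=bool)
    interior[rr, cc] = True
    return RibcageCurve(polyline=polyline, interior=interior)


def mask_inside_ribcage(slice_arr: np.ndarray, curve: RibcageCurve) -> np.ndarray:
    """Set everything outside the ribcage interior to air (-1000 HU)."""
    slice_arr = np.asarray(slice_arr, dtype=np.float64)
    if curve.interior.shape != slice_arr.shape:
        raise ValueError("interior mask shape does not match slice")
    return np.where(curve.interior, slice_arr, AIR_HU)


def fallback_centroids(
    neighbors: list[RibCentroidSet], source_slice: int = -1
) -> RibCentroidSet:
    """Union of neighbouring slices' centroids, re-ordered by angle.

    Used when a slice is rib-poor or its masked area drops steeply versus
    its neighbours; the overlaid points let the spline be refit.
    """
    pts = [s.points for s in neighbors if s is not None and s.count > 0]
    if not pts:
        raise InsufficientCentroidsError("no neighbouring slice has centroids")
    merged = np.vstack(pts)
    center = merged.mean(axis=0)
    angles = np.arctan2(merged[:, 0] - center[0], merged[:, 1] - center[1])
    merged = merged[np.argsort(angles)]
    if len(merged) < 4:
        raise InsufficientCentroidsError(f"fallback yields {len(merged)} centroids; need >= 4")
    return RibCentroidSet(points=merged, source_slice=source_slice)
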