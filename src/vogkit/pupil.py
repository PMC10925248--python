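"""Dark-pupil detection: thresholding, connected-component filtering and
three interchangeable localization methods (centroid, convex hull, ellipse
fit).

The pupil is the darkest large structure in an infrared eye image.  All
methods share the front end ``binarize_dark`` -> ``find_pupil_component``;
they differ only in how the selected component is summarized as an ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, find_contours

from vogkit.core.settings import PipelineSettings
from vogkit.core.types import Ellipse, Point

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


class PupilMethod(Enum):
    CENTROID = "centroid"
    CONVEX_HULL = "convex_hull"
    ELLIPSE_FIT = "ellipse_fit"


@dataclass
class BlobComponent:
    """One 8-connected component of the dark mask."""

    mask: np.ndarray  # full-size boolean mask of this component only
    area_px2: int
    bbox: Tuple[int, int, int, int]  # (y0, x0, y1, x1), half-open
    centroid: Point  # (x, y)

    def pixel_coords(self) -> np.ndarray:
        """(N, 2) array of (x, y) member pixel coordinates."""
        ys, xs = np.nonzero(self.mask)
        return np.column_stack([xs, ys]).astype(float)


@dataclass
class PupilResult:
    ellipse: Optional[Ellipse]
    method: PupilMethod
    found: bool


def binarize_dark(image: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean mask of pixels strictly darker than ``threshold``."""
    return np.asarray(image) < threshold


def open_mask(mask: np.ndarray) -> np.ndarray:
    """3x3 morphological opening (one iteration) to suppress salt noise."""
    return ndimage.binary_opening(mask, structure=_STRUCT8)


def find_pupil_component(
    mask: np.ndarray, min_size_px2: int, max_size_px2: int
) -> Optional[BlobComponent]:
    """Largest 8-connected component with area in [min, max].

    Tie-break between equal-area candidates: centroid nearest the image
    center (then lowest label, for determinism).
    """
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    qualifying = [
        (i + 1, a) for i, a in enumerate(areas) if min_size_px2 <= a <= max_size_px2
    ]
    if not qualifying:
        return None
    max_area = max(a for _, a in qualifying)
    candidates = [lab for lab, a in qualifying if a == max_area]
    if len(candidates) > 1:
        h, w = mask.shape
        img_center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        centroids = ndimage.center_of_mass(mask, labels, candidates)  # (y, x)
        dists = [
            np.hypot(cx - img_center[0], cy - img_center[1]) for cy, cx in centroids
        ]
        candidates = [lab for _, lab in sorted(zip(dists, candidates))][:1]
    label = candidates[0]
    comp = labels == label
    ys, xs = np.nonzero(comp)
    return BlobComponent(
        mask=comp,
        area_px2=int(max_area),
        bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
        centroid=Point(float(xs.mean()), float(ys.mean())),
    )


def pupil_centroid(component: BlobComponent) -> Point:
    """Arithmetic mean of member pixel coordinates (sub-pixel)."""
    if component.area_px2 == 0:
        raise ValueError("empty component")
    return component.centroid


def component_contour(component: BlobComponent) -> np.ndarray:
    """Sub-pixel boundary of the component as (N, 2) (x, y) points."""
    contours = find_contours(component.mask.astype(float), 0.5)
    if not contours:
        raise ValueError("component has no contour")
    contour = max(contours, key=len)  # rows are (row, col) = (y, x)
    return contour[:, ::-1]


def fit_ellipse(points: np.ndarray) -> Ellipse:
    """Direct least-squares conic fit constrained to an ellipse.

    ``points`` is (N>=5, 2) of (x, y).  Raises ValueError on degenerate
    input (fewer than 5 points, collinear points, or a non-elliptical fit).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 5:
        raise ValueError("fit_ellipse needs at least 5 (x, y) points")
    if np.linalg.matrix_rank(points - points.mean(axis=0)) < 2:
        raise ValueError("points are collinear")
    model = EllipseModel.from_estimate(points)
    if not model:
        raise ValueError("ellipse fit failed (degenerate conic)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise ValueError("ellipse fit produced a degenerate conic")
    return Ellipse.from_params(xc, yc, 2 * a, 2 * b, math.degrees(theta))


def _ellipse_residuals(points: np.ndarray, ellipse: Ellipse) -> np.ndarray:
    """Approximate radial distance of each point from the ellipse boundary."""
    phi = math.radians(ellipse.angle_deg)
    c, s = math.cos(phi), math.sin(phi)
    dx = points[:, 0] - ellipse.center.x
    dy = points[:, 1] - ellipse.center.y
    u = (dx * c + dy * s) / (ellipse.major_axis / 2.0)
    w = (-dx * s + dy * c) / (ellipse.minor_axis / 2.0)
    rho = np.hypot(u, w)
    return np.abs(rho - 1.0) * (ellipse.minor_axis / 2.0)


def _refit_trimmed(points: np.ndarray, ellipse: Ellipse) -> Ellipse:
    """One robust re-fit pass: drop boundary points far off the first fit
    (glint bumps, eyelid chords) and fit again on the inliers."""
    resid = _ellipse_residuals(points, ellipse)
    cutoff = max(0.75, 4.0 * float(np.median(resid)))
    inliers = resid < cutoff
    if inliers.sum() < max(10, 0.5 * len(points)) or inliers.all():
        return ellipse
    try:
        return fit_ellipse(points[inliers])
    except ValueError:
        return ellipse


def _densify_polygon(vertices: np.ndarray, step: float = 2.0) -> np.ndarray:
    """Sample points along polygon edges so sparse hulls still fit ellipses."""
    out: List[np.ndarray] = []
    n = len(vertices)
    for i in range(n):
        p, q = vertices[i], vertices[(i + 1) % n]
        length = float(np.hypot(*(q - p)))
        k = max(1, int(math.ceil(length / step)))
        t = np.arange(k) / k
        out.append(p[None, :] + t[:, None] * (q - p)[None, :])
    return np.concatenate(out, axis=0)


def pupil_convex_hull(component: BlobComponent) -> Tuple[Optional[np.ndarray], PupilResult]:
    """Convex hull of the pixel set, with an ellipse fitted to the hull.

    Robust to concave occlusions (eyelid notches): the hull bridges the
    notch so the fitted center stays near the true pupil center.
    """
    coords = component.pixel_coords()
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return None, PupilResult(None, PupilMethod.CONVEX_HULL, False)
    vertices = coords[hull.vertices]
    try:
        ellipse = fit_ellipse(_densify_polygon(vertices))
    except ValueError:
        return vertices, PupilResult(None, PupilMethod.CONVEX_HULL, False)
    return vertices, PupilResult(ellipse, PupilMethod.CONVEX_HULL, True)


def _grayscale_contour(
    image: np.ndarray, component: BlobComponent, threshold: int
) -> Optional[np.ndarray]:
    """Iso-intensity contour of the original image at the threshold level.

    Interpolating the actual intensity crossing gives sub-pixel accuracy the
    binary mask cannot; falls back to None if no suitable closed contour
    encloses the component centroid.
    """
    y0, x0, y1, x1 = component.bbox
    pad = 2
    h, w = image.shape
    ys, ye = max(0, y0 - pad), min(h, y1 + pad)
    xs, xe = max(0, x0 - pad), min(w, x1 + pad)
    sub = image[ys:ye, xs:xe].astype(float)
    contours = find_contours(sub, float(threshold))
    cx, cy = component.centroid.x - xs, component.centroid.y - ys
    best = None
    for c in contours:
        if len(c) < 8 or not np.allclose(c[0], c[-1]):
            continue
        # winding test: does the contour enclose the component centroid?
        dy = c[:, 0] - cy
        dx = c[:, 1] - cx
        angles = np.unwrap(np.arctan2(dy, dx))
        if abs(angles[-1] - angles[0]) < math.pi:
            continue
        if best is None or len(c) > len(best):
            best = c
    if best is None:
        return None
    pts = best[:, ::-1].copy()  # (x, y)
    pts[:, 0] += xs
    pts[:, 1] += ys
    return pts


def equivalent_circle(center: Point, area_px2: float) -> Ellipse:
    d = 2.0 * math.sqrt(area_px2 / math.pi)
    return Ellipse(center, d, d, 0.0)


def track_pupil(
    image: np.ndarray,
    settings: PipelineSettings,
    method: Optional[PupilMethod] = None,
) -> PupilResult:
    """Full dark-pupil stage: binarize -> clean -> select blob -> summarize.

    Returns ``found=False`` (no ellipse) on blinks or when no component is
    within the configured size range.
    """
    if method is None:
        method = PupilMethod(settings.method)
    roi = settings.roi_rect()
    offset = (0.0, 0.0)
    sub = np.asarray(image)
    if roi is not None:
        x0, y0, x1, y1 = roi
        sub = sub[y0:y1, x0:x1]
        offset = (float(x0), float(y0))

    mask = open_mask(binarize_dark(sub, settings.pupil_threshold))
    component = find_pupil_component(mask, settings.min_size_px2, settings.max_size_px2)
    if component is None:
        return PupilResult(None, method, False)

    if method is PupilMethod.CENTROID:
        center = pupil_centroid(component)
        ellipse = equivalent_circle(
            Point(center.x + offset[0], center.y + offset[1]), component.area_px2
        )
        return PupilResult(ellipse, method, True)

    if method is PupilMethod.CONVEX_HULL:
        _, result = pupil_convex_hull(component)
        if result.found and offset != (0.0, 0.0):
            e = result.ellipse
            result = PupilResult(
                Ellipse(Point(e.center.x + offset[0], e.center.y + offset[1]),
                        e.major_axis, e.minor_axis, e.angle_deg),
                method, True,
            )
        return result

    # ellipse_fit: prefer the grayscale iso-contour at the threshold level
    points = _grayscale_contour(sub, component, settings.pupil_threshold)
    if points is None:
        points = component_contour(component)
    try:
        ellipse = fit_ellipse(points)
        ellipse = _refit_trimmed(points, ellipse)
    except ValueError:
        return PupilResult(None, method, False)
    if offset != (0.0, 0.0):
        ellipse = Ellipse(
            Point(ellipse.center.x + offset[0], ellipse.center.y + offset[1]),
            ellipse.major_axis, ellipse.minor_axis, ellipse.angle_deg,
        )
    return PupilResult(ellipse, method, True)
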