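"""Ocular torsion from the iris pattern.

An annulus around the pupil is unwrapped into polar coordinates; the
per-angle mean intensity gives a 1-D angular profile whose circular shift
relative to a reference profile is the torsion angle.  The shift is found
by normalized circular cross-correlation over integer sample shifts,
refined by parabolic interpolation around the peak.

Sign convention: positive torsion is a rotation of the iris pattern from
+x toward +y in image coordinates (counter-clockwise with y downward on
screen appearing clockwise; the convention is recorded in file headers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from vogkit.core.types import Point


@dataclass
class PolarIrisImage:
    """n_radii x n_angles samples of the iris annulus.

    Column m is angle theta_m = 360*m/n_angles degrees; row k is radius
    r_inner + k*(r_outer-r_inner)/(n_radii-1).  ``valid`` is False where the
    sample fell outside the image.
    """

    samples: np.ndarray
    valid: np.ndarray
    r_inner: float
    r_outer: float

    @property
    def n_angles(self) -> int:
        return self.samples.shape[1]


@dataclass
class IrisProfile:
    """Mean-subtracted per-angle intensity with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    frame_number: Optional[int] = None

    @property
    def n_angles(self) -> int:
        return len(self.values)


@dataclass
class TorsionResult:
    torsion_deg: float
    peak_correlation: float
    valid: bool
    reason: str = ""


def unwrap_polar(
    image: np.ndarray,
    center: Point,
    r_inner: float,
    r_outer: float,
    n_angles: int = 720,
    n_radii: int = 20,
) -> PolarIrisImage:
    """Bilinear resampling of the annulus around ``center``."""
    if not (r_outer > r_inner > 0):
        raise ValueError("need r_outer > r_inner > 0")
    h, w = image.shape
    if not (0 <= center.x < w and 0 <= center.y < h):
        raise ValueError("center outside image")
    radii = np.linspace(r_inner, r_outer, n_radii)
    thetas = 2.0 * np.pi * np.arange(n_angles) / n_angles
    xs = center.x + radii[:, None] * np.cos(thetas)[None, :]
    ys = center.y + radii[:, None] * np.sin(thetas)[None, :]
    valid = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not valid.any():
        raise ValueError("annulus entirely outside image")
    samples = ndimage.map_coordinates(
        image.astype(float), [ys, xs], order=1, mode="constant", cval=0.0
    )
    return PolarIrisImage(samples, valid, float(r_inner), float(r_outer))


def iris_profile(polar: PolarIrisImage, frame_number: Optional[int] = None) -> IrisProfile:
    """Per-angle mean over valid radii, mean-subtracted over valid angles.

    An angle is masked when fewer than 50% of its radii are valid.
    """
    n_radii = polar.samples.shape[0]
    counts = polar.valid.sum(axis=0)
    angle_valid = counts >= 0.5 * n_radii
    if not angle_valid.any():
        raise ValueError("all angles masked")
    sums = np.where(polar.valid, polar.samples, 0.0).sum(axis=0)
    means = np.zeros_like(sums)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    values = means - means[angle_valid].mean()
    values[~angle_valid] = 0.0
    return IrisProfile(values, angle_valid, frame_number)


def measure_torsion(
    profile: IrisProfile,
    reference: IrisProfile,
    max_shift_deg: float = 15.0,
    correlation_threshold: float = 0.5,
) -> TorsionResult:
    """Torsion of ``profile`` relative to ``reference``.

    Positive result means the probe pattern equals the reference rotated by
    +torsion (probe(theta) ~= reference(theta - torsion)).  ``valid`` is
    False when the correlation peak is below threshold, the shift saturates
    the search range, or fewer than 25% of angles are jointly valid.
    """
    n = profile.n_angles
    if reference.n_angles != n:
        raise ValueError("profile and reference must have the same n_angles")
    step = 360.0 / n
    m = int(round(max_shift_deg / step))
    shifts = np.arange(-m, m + 1)

    corr = np.full(len(shifts), -np.inf)
    min_joint = max(8, int(0.25 * n))
    for i, s in enumerate(shifts):
        ref_v = np.roll(reference.values, s)
        ref_ok = np.roll(reference.valid, s)
        joint = profile.valid & ref_ok
        if joint.sum() < min_joint:
            continue
        a = profile.values[joint]
        b = ref_v[joint]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        if denom <= 0:
            continue
        corr[i] = float((a * b).sum() / denom)

    if not np.isfinite(corr).any():
        return TorsionResult(0.0, 0.0, False, "insufficient_valid_angles")

    best = int(np.argmax(corr))
    peak = float(corr[best])
    # parabolic refinement on the three points around the peak
    delta = 0.0
    if 0 < best < len(shifts) - 1 and np.isfinite(corr[best - 1]) and np.isfinite(corr[best + 1]):
        y0, y1, y2 = corr[best - 1], corr[best], corr[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
    torsion = (shifts[best] + delta) * step

    if peak < correlation_threshold:
        return TorsionResult(torsion, peak, False, "low_correlation")
    if best in (0, len(shifts) - 1):
        return TorsionResult(torsion, peak, False, "saturated")
    return TorsionResult(torsion, peak, True)


class TorsionTracker:
    """Holds the reference profile (zero-torsion posture)."""

    def __init__(self, max_shift_deg: float = 15.0, correlation_threshold: float = 0.5):
        self.max_shift_deg = max_shift_deg
        self.correlation_threshold = correlation_threshold
        self.reference: Optional[IrisProfile] = None

    def set_reference(self, profile: IrisProfile) -> None:
        if profile is None or not np.asarray(profile.valid).any():
            raise ValueError("invalid reference profile")
        self.reference = profile

    def measure(self, profile: IrisProfile) -> TorsionResult:
        if self.reference is None:
            return TorsionResult(0.0, 0.0, False, "no_reference")
        return measure_torsion(
            profile, self.reference, self.max_shift_deg, self.correlation_threshold
        )
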