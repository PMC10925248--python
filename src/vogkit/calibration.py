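"""Pixel-to-degree calibration.

Two routes: a geometric eye model (pupil displacement on a rotating sphere
of known pixel radius) and a per-axis polynomial regression fitted against
known fixation targets.  Conventions: horizontal gaze positive rightward in
image x; vertical gaze positive upward, i.e. image y negated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from vogkit.core.types import EyeDatum, Point


class CalibrationError(ValueError):
    pass


@dataclass
class CalibratedSample:
    h_deg: float
    v_deg: float
    torsion_deg: Optional[float] = None
    valid: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# Geometric eye model
# ---------------------------------------------------------------------------

@dataclass
class EyeModel:
    """Eyeball rotating behind the camera plane.

    ``center_ref`` is the pupil-center pixel at primary gaze; ``radius_px``
    the rotation radius in pixels, so a gaze of theta displaces the pupil by
    radius_px * sin(theta).
    """

    center_ref: Point
    radius_px: float

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise CalibrationError("radius_px must be positive")


def fit_eye_model(
    samples: Sequence[Point],
    radius_px: Optional[float] = None,
    known_pair: Optional[Tuple[float, float]] = None,
    max_dispersion_px: float = 5.0,
) -> EyeModel:
    """Reference center from steady-fixation samples; radius from a setting
    or from a known-amplitude fixation pair.

    ``known_pair`` is (delta_pixels, delta_degrees) between two fixations of
    known angular separation: radius = delta_px / sin(delta_deg).
    """
    if len(samples) == 0:
        raise CalibrationError("no samples")
    pts = np.asarray([(p.x, p.y) for p in samples], dtype=float)
    center = np.median(pts, axis=0)
    rms_disp = float(np.sqrt(((pts - center) ** 2).sum(axis=1).mean()))
    if rms_disp > max_dispersion_px:
        raise CalibrationError(
            f"fixation unstable: dispersion {rms_disp:.2f} px > {max_dispersion_px} px"
        )
    if radius_px is None:
        if known_pair is None:
            raise CalibrationError("need radius_px or a known fixation pair")
        delta_px, delta_deg = known_pair
        radius_px = estimate_radius(delta_px, delta_deg)
    return EyeModel(Point(float(center[0]), float(center[1])), float(radius_px))


def estimate_radius(delta_px: float, delta_deg: float) -> float:
    """Closed form r = delta_px / sin(delta_deg)."""
    s = math.sin(math.radians(delta_deg))
    if s == 0:
        raise CalibrationError("zero angular separation")
    return abs(delta_px / s)


def model_pixels_to_degrees(model: EyeModel, pupil_center: Point) -> CalibratedSample:
    """h = asin(dx / r); v = -asin(dy / r) (image y down, gaze up positive)."""
    dx = pupil_center.x - model.center_ref.x
    dy = pupil_center.y - model.center_ref.y
    r = model.radius_px
    if abs(dx) > r or abs(dy) > r:
        return CalibratedSample(float("nan"), float("nan"), valid=False,
                                reason="out_of_range")
    return CalibratedSample(
        math.degrees(math.asin(dx / r)),
        -math.degrees(math.asin(dy / r)),
    )


# ---------------------------------------------------------------------------
# Regression calibration
# ---------------------------------------------------------------------------

def _design_matrix(features: np.ndarray, degree: int) -> np.ndarray:
    x, y = features[:, 0], features[:, 1]
    cols = [np.ones_like(x), x, y]
    if degree >= 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


@dataclass
class RegressionCalibration:
    """Per-axis polynomial mapping raw pixel features to gaze degrees."""

    coef_h: np.ndarray
    coef_v: np.ndarray
    residual_rms: Tuple[float, float]
    n_targets: int
    degree: int = 1
    feature: str = "pupil"  # pupil | pupil_cr
    torsion_ref_deg: float = 0.0

    def predict(self, feature_xy: Point) -> Tuple[float, float]:
        row = _design_matrix(np.array([[feature_xy.x, feature_xy.y]]), self.degree)[0]
        return float(row @ self.coef_h), float(row @ self.coef_v)

    def apply_to_datum(self, datum: EyeDatum) -> EyeDatum:
        sample = apply_calibration(self, datum)
        if sample.valid:
            datum.h_deg = sample.h_deg
            datum.v_deg = sample.v_deg
            if sample.torsion_deg is not None:
                datum.torsion_deg = sample.torsion_deg
        return datum


def fit_regression(
    raw_features: Sequence[Tuple[float, float]],
    targets: Sequence[Tuple[float, float]],
    degree: int = 1,
    feature: str = "pupil",
) -> RegressionCalibration:
    """Per-axis least squares against known target angles.

    Requires at least 3 non-collinear targets (more for degree 2); raises
    ``CalibrationError`` on rank deficiency (e.g. collinear targets).
    """
    X = np.asarray(raw_features, dtype=float)
    T = np.asarray(targets, dtype=float)
    if X.shape != T.shape or X.ndim != 2 or X.shape[1] != 2:
        raise CalibrationError("features and targets must both be (N, 2)")
    A = _design_matrix(X, degree)
    if X.shape[0] < A.shape[1]:
        raise CalibrationError(
            f"need at least {A.shape[1]} targets for degree {degree}"
        )
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise CalibrationError("targets are collinear (rank-deficient design)")
    coef_h, _, _, _ = np.linalg.lstsq(A, T[:, 0], rcond=None)
    coef_v, _, _, _ = np.linalg.lstsq(A, T[:, 1], rcond=None)
    res_h = float(np.sqrt(np.mean((A @ coef_h - T[:, 0]) ** 2)))
    res_v = float(np.sqrt(np.mean((A @ coef_v - T[:, 1]) ** 2)))
    return RegressionCalibration(coef_h, coef_v, (res_h, res_v), X.shape[0],
                                 degree, feature)


def datum_feature(datum: EyeDatum, feature: str) -> Optional[Point]:
    if feature == "pupil_cr":
        return datum.pupil_cr_vector
    if datum.pupil is None:
        return None
    return datum.pupil.center


def apply_calibration(cal: RegressionCalibration, datum: EyeDatum) -> CalibratedSample:
    """Map one datum's raw feature through the fitted calibration."""
    feat = datum_feature(datum, cal.feature)
    if feat is None:
        return CalibratedSample(float("nan"), float("nan"), valid=False,
                                reason="missing_feature")
    h, v = cal.predict(feat)
    torsion = None
    if datum.torsion_deg is not None:
        torsion = datum.torsion_deg - cal.torsion_ref_deg
    return CalibratedSample(h, v, torsion)


@dataclass
class EyeModelCalibration:
    """Adapter exposing the eye model through the session interface."""

    model: EyeModel
    torsion_ref_deg: float = 0.0

    def apply_to_datum(self, datum: EyeDatum) -> EyeDatum:
        if datum.pupil is None:
            return datum
        sample = model_pixels_to_degrees(self.model, datum.pupil.center)
        if sample.valid:
            datum.h_deg = sample.h_deg
            datum.v_deg = sample.v_deg
            if datum.torsion_deg is not None:
                datum.torsion_deg = datum.torsion_deg - self.torsion_ref_deg
        return datum


# ---------------------------------------------------------------------------
# Target schedules and calibration files
# ---------------------------------------------------------------------------

@dataclass
class TargetDwell:
    t_start: float
    t_end: float
    h_deg: float
    v_deg: float


def read_target_schedule(path) -> List[TargetDwell]:
    """Lines of ``t_start t_end h_deg v_deg`` (whitespace separated)."""
    dwells = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise CalibrationError(
                f"{path}:{lineno}: expected 't_start t_end h_deg v_deg'"
            )
        t0, t1, h, v = map(float, parts)
        dwells.append(TargetDwell(t0, t1, h, v))
    return dwells


def aggregate_fixation(
    times: np.ndarray, features: np.ndarray, dwell: TargetDwell
) -> Optional[Tuple[float, float]]:
    """Median feature over the middle 50% of the dwell window."""
    span = dwell.t_end - dwell.t_start
    t0 = dwell.t_start + 0.25 * span
    t1 = dwell.t_end - 0.25 * span
    sel = (times >= t0) & (times <= t1) & np.isfinite(features).all(axis=1)
    if not sel.any():
        return None
    med = np.median(features[sel], axis=0)
    return float(med[0]), float(med[1])


def save_calibration(cal: RegressionCalibration, path) -> None:
    lines = [
        "# vogkit calibration v1",
        "# conventions: h +rightward (image x); v +upward (image y negated)",
        f"feature = {cal.feature}",
        f"degree = {cal.degree}",
        f"n_targets = {cal.n_targets}",
        f"torsion_ref_deg = {cal.torsion_ref_deg!r}",
        "coef_h = " + " ".join(repr(float(c)) for c in cal.coef_h),
        "coef_v = " + " ".join(repr(float(c)) for c in cal.coef_v),
        f"residual_rms_h = {float(cal.residual_rms[0])!r}",
        f"residual_rms_v = {float(cal.residual_rms[1])!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_calibration(path) -> RegressionCalibration:
    values = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or "=" not in line:
            continue
        key, val = line.split("=", 1)
        values[key.strip()] = val.strip()
    try:
        return RegressionCalibration(
            coef_h=np.array([float(c) for c in values["coef_h"].split()]),
            coef_v=np.array([float(c) for c in values["coef_v"].split()]),
            residual_rms=(float(values["residual_rms_h"]),
                          float(values["residual_rms_v"])),
            n_targets=int(values["n_targets"]),
            degree=int(values["degree"]),
            feature=values["feature"],
            torsion_ref_deg=float(values.get("torsion_ref_deg", 0.0)),
        )
    except KeyError as exc:
        raise CalibrationError(f"{path}: missing field {exc}") from None
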