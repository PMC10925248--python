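"""Synthetic infrared eye-image generator with analytic ground truth.

Renders a dark elliptical pupil on a textured iris disk over bright sclera,
with optional glints (P1), a dimmer lens reflection (P4), eyelid occlusion
and additive Gaussian noise.  The projection model is deliberately simple
(no corneal refraction, no perspective): a gaze of (h, v) displaces the
pupil center by radius_px * (sin h, -sin v) and foreshortens the pupil
along the displacement direction by cos(eccentricity).  The iris texture is
a sum of angular harmonics, so the torsion correlation peak is analytically
predictable; harmonic numbers should be coprime to avoid aliasing.

Every rendered quantity is recorded in a TruthRow, making the generator a
self-contained oracle for the tracking pipelines.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from vogkit.core.types import Point
from vogkit import video_io


@dataclass
class GlintSpec:
    """One rendered reflection: Gaussian spot of given amplitude and sigma.

    ``offset`` is relative to the eye center; ``gaze_gain`` scales how much
    the spot follows the pupil displacement (0 = fixed in the image).
    """

    offset: Tuple[float, float] = (30.0, 22.0)
    amplitude: float = 250.0
    sigma: float = 1.5
    gaze_gain: float = 0.0


@dataclass
class SyntheticScene:
    width: int = 400
    height: int = 300
    eye_center: Tuple[float, float] = (200.0, 150.0)
    radius_px: float = 259.1
    gaze_h_deg: float = 0.0
    gaze_v_deg: float = 0.0
    torsion_deg: float = 0.0
    pupil_radius: float = 22.0
    iris_radius: float = 80.0
    pupil_value: float = 10.0
    iris_base: float = 130.0
    sclera_value: float = 205.0
    # angular harmonics of the iris texture: (k, amplitude, phase_rad);
    # amplitudes keep the darkest iris sector well above pupil_threshold
    harmonics: Tuple[Tuple[int, float, float], ...] = (
        (5, 16.0, 0.0),
        (9, 11.0, 1.0),
        (13, 8.0, 2.2),
    )
    glints: Tuple[GlintSpec, ...] = (GlintSpec(),)
    p4_enabled: bool = False
    p4_offset: Tuple[float, float] = (9.0, 6.0)
    p4_gain: float = 0.3
    p4_amplitude: float = 200.0
    p4_sigma: float = 1.2
    eyelid_coverage: float = 0.0  # fraction of the iris diameter hidden from top
    eyelid_value: float = 185.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pupil_radius < self.iris_radius:
            raise ValueError("pupil_radius must be smaller than iris_radius")
        peak = self.iris_base + sum(a for _, a, _ in self.harmonics)
        if peak > 255 or self.iris_base - sum(a for _, a, _ in self.harmonics) < 0:
            raise ValueError("iris texture amplitudes leave the [0, 255] range")
        if not (0.0 <= self.eyelid_coverage <= 1.0):
            raise ValueError("eyelid_coverage must be in [0, 1]")


@dataclass
class TruthRow:
    """Analytic ground truth for one rendered frame."""

    frame_number: int
    h_deg: float
    v_deg: float
    torsion_deg: float
    pupil_x: float
    pupil_y: float
    pupil_major: float
    pupil_minor: float
    pupil_angle: float
    glint_x: float = float("nan")
    glint_y: float = float("nan")
    p4_x: float = float("nan")
    p4_y: float = float("nan")


TRUTH_COLUMNS = [f.name for f in dataclasses.fields(TruthRow)]


def _projection(scene: SyntheticScene):
    """Pupil center, foreshortening and major-axis direction for one gaze."""
    sh = math.sin(math.radians(scene.gaze_h_deg))
    sv = math.sin(math.radians(scene.gaze_v_deg))
    offset = np.array([scene.radius_px * sh, -scene.radius_px * sv])
    sin_ecc = min(math.hypot(sh, sv), 1.0)
    cos_ecc = math.sqrt(max(0.0, 1.0 - sin_ecc * sin_ecc))
    if sin_ecc > 1e-12:
        d_along = np.array([sh, -sv]) / sin_ecc
    else:
        d_along = np.array([1.0, 0.0])
    center = np.asarray(scene.eye_center, dtype=float) + offset
    return center, offset, cos_ecc, d_along


def render_frame(
    scene: SyntheticScene,
    frame_number: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, TruthRow]:
    """Render one frame and its ground truth."""
    center, offset, cos_ecc, d_along = _projection(scene)
    pcx, pcy = center
    d_perp = np.array([-d_along[1], d_along[0]])

    ys, xs = np.mgrid[0: scene.height, 0: scene.width]
    dx = xs - pcx
    dy = ys - pcy

    img = np.full((scene.height, scene.width), scene.sclera_value, dtype=float)

    # iris disk (kept circular; the annular unwrap assumes this too)
    r = np.hypot(dx, dy)
    alpha_iris = np.clip(scene.iris_radius - r + 0.5, 0.0, 1.0)
    theta = np.arctan2(dy, dx)
    tau = math.radians(scene.torsion_deg)
    iris_val = np.full_like(img, scene.iris_base)
    for k, amp, phase in scene.harmonics:
        iris_val += amp * np.cos(k * (theta - tau) - phase)
    img = img * (1 - alpha_iris) + iris_val * alpha_iris

    # pupil: ellipse with minor axis along the gaze direction
    a = scene.pupil_radius                # semi-major, perpendicular to gaze
    b = scene.pupil_radius * cos_ecc      # semi-minor, along gaze direction
    u = dx * d_along[0] + dy * d_along[1]
    w = dx * d_perp[0] + dy * d_perp[1]
    rho = np.sqrt((u / b) ** 2 + (w / a) ** 2)
    edge_scale = 2 * a * b / (a + b)      # harmonic mean: ~px per unit rho
    alpha_pupil = np.clip(0.5 - (rho - 1.0) * edge_scale, 0.0, 1.0)
    img = img * (1 - alpha_pupil) + scene.pupil_value * alpha_pupil

    # eyelid covering the top of the iris
    if scene.eyelid_coverage > 0:
        y_lid = pcy - scene.iris_radius + scene.eyelid_coverage * 2 * scene.iris_radius
        alpha_lid = np.clip(y_lid - ys + 0.5, 0.0, 1.0)
        img = img * (1 - alpha_lid) + scene.eyelid_value * alpha_lid

    # reflections blend toward their amplitude (not additive) so the peak
    # intensity equals the spec'd amplitude regardless of the background —
    # this keeps the P1 > P4 intensity ordering meaningful
    def blend_spot(im, pos, amplitude, sigma):
        g = np.exp(-((xs - pos[0]) ** 2 + (ys - pos[1]) ** 2) / (2 * sigma ** 2))
        return im * (1 - g) + amplitude * g

    glint_truth = (float("nan"), float("nan"))
    eye_center = np.asarray(scene.eye_center, dtype=float)
    for i, g in enumerate(scene.glints):
        pos = eye_center + np.asarray(g.offset) + g.gaze_gain * offset
        img = blend_spot(img, pos, g.amplitude, g.sigma)
        if i == 0:
            glint_truth = (float(pos[0]), float(pos[1]))

    p4_truth = (float("nan"), float("nan"))
    if scene.p4_enabled:
        pos = eye_center + np.asarray(scene.p4_offset) + scene.p4_gain * offset
        img = blend_spot(img, pos, scene.p4_amplitude, scene.p4_sigma)
        p4_truth = (float(pos[0]), float(pos[1]))

    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma, img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    angle = math.degrees(math.atan2(d_perp[1], d_perp[0])) % 180.0
    truth = TruthRow(
        frame_number=frame_number,
        h_deg=scene.gaze_h_deg,
        v_deg=scene.gaze_v_deg,
        torsion_deg=scene.torsion_deg,
        pupil_x=float(pcx),
        pupil_y=float(pcy),
        pupil_major=2 * a,
        pupil_minor=2 * b,
        pupil_angle=angle,
        glint_x=glint_truth[0],
        glint_y=glint_truth[1],
        p4_x=p4_truth[0],
        p4_y=p4_truth[1],
    )
    return image, truth


def render_sequence(
    trajectory: Sequence[Tuple[float, float, float]],
    scene: SyntheticScene,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[np.ndarray], List[TruthRow]]:
    """Render one frame per (h_deg, v_deg, torsion_deg) triple.

    A single seeded generator (from ``scene.seed`` unless given) drives the
    noise of all frames, so the same seed yields bit-identical sequences.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    frames, truths = [], []
    for i, (h, v, t) in enumerate(trajectory):
        frame_scene = dataclasses.replace(
            scene, gaze_h_deg=h, gaze_v_deg=v, torsion_deg=t
        )
        image, truth = render_frame(frame_scene, frame_number=i, rng=rng)
        frames.append(image)
        truths.append(truth)
    return frames, truths


def write_truth(path, truths: Sequence[TruthRow]) -> None:
    lines = ["# vogkit truth v1", "# columns: " + "\t".join(TRUTH_COLUMNS)]
    for t in truths:
        lines.append("\t".join(repr(getattr(t, c)) if c != "frame_number"
                               else str(t.frame_number) for c in TRUTH_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_truth(path) -> List[TruthRow]:
    truths = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        values = dict(zip(TRUTH_COLUMNS, parts))
        truths.append(TruthRow(**{
            k: (int(v) if k == "frame_number" else float(v))
            for k, v in values.items()
        }))
    return truths


def generate_sequence(
    trajectory: Sequence[Tuple[float, float, float]],
    scene: SyntheticScene,
    video_path,
    truth_path,
    fps: float = 500.0,
) -> Tuple[List[np.ndarray], List[TruthRow]]:
    """Render a trajectory and write a lossless video plus a truth file."""
    frames, truths = render_sequence(trajectory, scene)
    video_io.write_raw_video(video_path, frames, fps=fps)
    write_truth(truth_path, truths)
    return frames, truths


# ---------------------------------------------------------------------------
# Canned trajectories
# ---------------------------------------------------------------------------

def fixation_trajectory(
    n_frames: int, jitter_deg: float = 0.0, seed: int = 0,
    h0: float = 0.0, v0: float = 0.0,
) -> List[Tuple[float, float, float]]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_frames):
        jh = rng.normal(0, jitter_deg) if jitter_deg else 0.0
        jv = rng.normal(0, jitter_deg) if jitter_deg else 0.0
        out.append((h0 + jh, v0 + jv, 0.0))
    return out


def torsion_ramp_trajectory(
    start_deg: float = -10.0, stop_deg: float = 10.0, step_deg: float = 1.0
) -> List[Tuple[float, float, float]]:
    n = int(round((stop_deg - start_deg) / step_deg)) + 1
    return [(0.0, 0.0, start_deg + i * step_deg) for i in range(n)]


def sine_gaze_trajectory(
    n_frames: int, fs: float = 500.0, freq_hz: float = 1.0, amplitude_deg: float = 5.0
) -> List[Tuple[float, float, float]]:
    t = np.arange(n_frames) / fs
    h = amplitude_deg * np.sin(2 * np.pi * freq_hz * t)
    return [(float(hi), 0.0, 0.0) for hi in h]


def grid_trajectory(
    extent_deg: float = 10.0, n_per_axis: int = 3
) -> List[Tuple[float, float, float]]:
    """n x n calibration target grid, row-major from top-left."""
    vals = np.linspace(-extent_deg, extent_deg, n_per_axis)
    return [(float(h), float(v), 0.0) for v in vals[::-1] for h in vals]
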