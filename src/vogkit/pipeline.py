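"""The combined eye-tracking pipeline plugin.

Composes the dark-pupil stage with optional glint, torsion and dual-
Purkinje stages.  ``process`` is a pure function of (frame, settings,
reference state); the torsion reference is primed once via
``process_for_reference`` before workers start, so multi-worker sessions
are deterministic.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from vogkit.core.registry import PluginKind, default_registry
from vogkit.core.settings import PipelineSettings
from vogkit.core.types import EyeDatum, Frame, Quality
from vogkit.dpi import detect_purkinje
from vogkit.glints import detect_glints
from vogkit.pupil import PupilMethod, binarize_dark, open_mask, track_pupil
from vogkit.torsion import TorsionTracker, iris_profile, unwrap_polar

QUICK_SETTINGS = [
    "pupil_threshold", "min_size_px2", "max_size_px2", "roi",
    "glint_threshold", "glint_min_size_px2", "glint_max_size_px2", "max_glints",
    "iris_width_px", "max_shift_deg", "correlation_threshold",
    "p1_threshold", "p4_threshold", "p4_search_radius",
]


class EyeTrackingPipeline:
    """Pupil + glint (+ torsion, + DPI) tracking for one eye stream."""

    def __init__(self, settings: Optional[PipelineSettings] = None):
        self.settings = settings if settings is not None else PipelineSettings()
        self.torsion = TorsionTracker(
            max_shift_deg=self.settings.max_shift_deg,
            correlation_threshold=self.settings.correlation_threshold,
        )

    def get_quick_settings_list(self):
        return list(QUICK_SETTINGS)

    # ------------------------------------------------------------------
    def _iris_annulus(self, image: np.ndarray, pupil):
        """Annulus radii follow the pupil each frame, tolerating dilation."""
        r_inner = pupil.major_axis / 2.0 + 2.0
        r_outer = r_inner + self.settings.iris_width_px
        return unwrap_polar(
            image, pupil.center, r_inner, r_outer,
            n_angles=self.settings.n_angles, n_radii=self.settings.n_radii,
        )

    def process_for_reference(self, frame: Frame) -> bool:
        """Set the torsion reference (zero posture) from this frame."""
        if not self.settings.torsion_enabled:
            return False
        result = track_pupil(frame.image, self.settings)
        if not result.found:
            return False
        polar = self._iris_annulus(frame.image, result.ellipse)
        profile = iris_profile(polar, frame_number=frame.frame_number)
        self.torsion.set_reference(profile)
        return True

    def process(self, frame: Frame) -> EyeDatum:
        s = self.settings
        datum = EyeDatum(frame.frame_number, frame.timestamp, frame.eye)

        pupil = track_pupil(frame.image, s)
        if pupil.found:
            datum.pupil = pupil.ellipse
        else:
            datum.quality = Quality.PUPIL_NOT_FOUND

        if s.glints_enabled:
            exclude = None
            if pupil.found:
                exclude = open_mask(binarize_dark(frame.image, s.pupil_threshold))
            datum.glints = detect_glints(
                frame.image, s.glint_threshold,
                s.glint_min_size_px2, s.glint_max_size_px2,
                max_glints=s.max_glints, exclude_mask=exclude,
            )

        if s.torsion_enabled and pupil.found:
            polar = self._iris_annulus(frame.image, pupil.ellipse)
            profile = iris_profile(polar, frame_number=frame.frame_number)
            result = self.torsion.measure(profile)
            datum.torsion_peak = result.peak_correlation
            if result.valid:
                datum.torsion_deg = result.torsion_deg
            elif datum.quality is Quality.OK:
                datum.quality = Quality.TORSION_LOW_CORRELATION

        if s.dpi_enabled:
            pair = detect_purkinje(
                frame.image, s.p1_threshold, s.p4_threshold, s.p4_search_radius,
                s.glint_min_size_px2, s.glint_max_size_px2,
            )
            if pair.p1 is not None and not pair.ambiguous:
                datum.p1 = pair.p1.center
            if pair.p4 is not None:
                datum.p4 = pair.p4.center

        return datum


def _method_factory(method: PupilMethod):
    def make(settings: Optional[PipelineSettings] = None) -> EyeTrackingPipeline:
        settings = settings if settings is not None else PipelineSettings()
        settings.method = method.value
        return EyeTrackingPipeline(settings)

    return make


def register_builtin_plugins(registry=default_registry) -> None:
    from vogkit.video_io import open_video

    registry.register(PluginKind.PIPELINE, "tracker", EyeTrackingPipeline)
    for method in PupilMethod:
        registry.register(PluginKind.PIPELINE, method.value, _method_factory(method))
    registry.register(PluginKind.SOURCE, "video", open_video)
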