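"""Offline reprocessing: one recorded video -> one data file."""

from __future__ import annotations

from typing import Optional

from vogkit.calibration import load_calibration
from vogkit.core.session import SessionReport, run_session
from vogkit.core.settings import TrackerSettings, load_settings
from vogkit.core.types import Eye
from vogkit.pipeline import EyeTrackingPipeline
from vogkit.recording import DataFileWriter
from vogkit.video_io import open_video


def process_video(
    video_path,
    out_path,
    settings: Optional[TrackerSettings] = None,
    settings_path=None,
    calibration_path=None,
    timestamps_path=None,
    n_workers: Optional[int] = None,
    eye: Eye = Eye.LEFT,
) -> SessionReport:
    """Reprocess a recorded video with the given parameters.

    Output is deterministic: the same (video, settings, calibration) yields
    a byte-identical data file regardless of worker count.
    """
    if settings is None:
        settings = load_settings(settings_path) if settings_path else TrackerSettings()
    source = open_video(
        video_path, timestamps_path=timestamps_path,
        nominal_fps=settings.system.nominal_fps, eye=eye,
    )
    pipeline = EyeTrackingPipeline(settings.pipeline)
    calibration = load_calibration(calibration_path) if calibration_path else None
    sink = DataFileWriter(out_path, settings_hash=settings.content_hash(),
                          fs=source.fps)
    if n_workers is None and settings.system.n_workers > 0:
        n_workers = min(settings.system.n_workers, settings.system.max_workers)
    return run_session(
        source, pipeline, calibration, [sink],
        n_workers=n_workers,
        buffer_capacity=settings.system.buffer_capacity,
        realtime=settings.system.realtime,
    )
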