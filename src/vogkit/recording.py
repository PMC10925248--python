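"""Frame-by-frame data files and post-hoc trace metrics.

The data file is tab-separated text: ``#``-prefixed header lines carrying
the format version, column list, settings hash and conventions, then one
row per (frame, eye).  Missing measurements are written as the token
``nan``.  Event markers are ``#EVENT`` comment lines interleaved at their
frame position so rows keep a fixed schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from vogkit.core.types import Eye, EyeDatum, Quality

FORMAT_VERSION = "1"

COLUMNS = [
    "frame_number", "timestamp_s", "eye",
    "pupil_x", "pupil_y", "pupil_major", "pupil_minor", "pupil_angle",
    "glint1_x", "glint1_y", "torsion_deg",
    "p1_x", "p1_y", "p4_x", "p4_y",
    "h_deg", "v_deg", "quality",
]

_NAN = float("nan")


@dataclass
class DataRow:
    frame_number: int
    timestamp_s: float
    eye: str
    pupil_x: float = _NAN
    pupil_y: float = _NAN
    pupil_major: float = _NAN
    pupil_minor: float = _NAN
    pupil_angle: float = _NAN
    glint1_x: float = _NAN
    glint1_y: float = _NAN
    torsion_deg: float = _NAN
    p1_x: float = _NAN
    p1_y: float = _NAN
    p4_x: float = _NAN
    p4_y: float = _NAN
    h_deg: float = _NAN
    v_deg: float = _NAN
    quality: str = "ok"

    def __eq__(self, other) -> bool:  # NaN-aware field equality
        if not isinstance(other, DataRow):
            return NotImplemented
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, float) and isinstance(b, float):
                if math.isnan(a) and math.isnan(b):
                    continue
                if a != b:
                    return False
            elif a != b:
                return False
        return True


def datum_to_row(datum: EyeDatum) -> DataRow:
    row = DataRow(datum.frame_number, datum.timestamp, datum.eye.value,
                  quality=datum.quality.value)
    if datum.pupil is not None:
        e = datum.pupil
        row.pupil_x, row.pupil_y = e.center.x, e.center.y
        row.pupil_major, row.pupil_minor = e.major_axis, e.minor_axis
        row.pupil_angle = e.angle_deg
    if datum.glints:
        g = datum.glints[0].center
        row.glint1_x, row.glint1_y = g.x, g.y
    if datum.torsion_deg is not None:
        row.torsion_deg = datum.torsion_deg
    if datum.p1 is not None:
        row.p1_x, row.p1_y = datum.p1.x, datum.p1.y
    if datum.p4 is not None:
        row.p4_x, row.p4_y = datum.p4.x, datum.p4.y
    if datum.h_deg is not None:
        row.h_deg = datum.h_deg
    if datum.v_deg is not None:
        row.v_deg = datum.v_deg
    return row


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


class DataFileError(ValueError):
    pass


class DataFileWriter:
    """Streams rows to a tab-separated data file, enforcing frame order."""

    def __init__(self, path, settings_hash: str = "", fs: Optional[float] = None,
                 extra_header: Sequence[str] = ()):
        self.path = Path(path)
        self._fh = open(self.path, "w", encoding="utf-8")
        self._last_frame: Optional[int] = None
        self._fh.write(f"# vogkit data v{FORMAT_VERSION}\n")
        self._fh.write("# conventions: x right, y down; h +right, v +up; "
                       "torsion + from +x toward +y\n")
        if settings_hash:
            self._fh.write(f"# settings_hash: {settings_hash}\n")
        if fs:
            self._fh.write(f"# fs_hz: {fs!r}\n")
        for line in extra_header:
            self._fh.write(f"# {line}\n")
        self._fh.write("# columns: " + "\t".join(COLUMNS) + "\n")

    def write_row(self, row: DataRow) -> None:
        if self._last_frame is not None and row.frame_number < self._last_frame:
            raise DataFileError(
                f"rows out of order: frame {row.frame_number} after {self._last_frame}"
            )
        self._last_frame = row.frame_number
        cells = [_format_cell(getattr(row, c if c != "timestamp_s" else "timestamp_s"))
                 for c in COLUMNS]
        self._fh.write("\t".join(cells) + "\n")

    # session sink interface
    def write(self, datum: EyeDatum) -> None:
        self.write_row(datum_to_row(datum))

    def write_event(self, timestamp: float, label: str,
                    frame_number: Optional[int] = None) -> None:
        fn = self._last_frame if frame_number is None else frame_number
        self._fh.write(f"#EVENT\t{fn}\t{timestamp!r}\t{label}\n")

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.flush()
            self._fh.close()


def write_rows(path, rows: Sequence[DataRow], settings_hash: str = "",
               fs: Optional[float] = None) -> None:
    writer = DataFileWriter(path, settings_hash=settings_hash, fs=fs)
    try:
        for row in rows:
            writer.write_row(row)
    finally:
        writer.close()


def read_rows(path):
    """Parse a data file; returns (rows, events) where events are
    (frame_number, timestamp, label) markers."""
    rows: List[DataRow] = []
    events = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(),
                                  start=1):
        if line.startswith("#EVENT\t"):
            _, fn, ts, label = line.split("\t", 3)
            events.append((None if fn == "None" else int(fn), float(ts), label))
            continue
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(COLUMNS):
            raise DataFileError(
                f"{path}:{lineno}: expected {len(COLUMNS)} columns, got {len(parts)}"
            )
        try:
            row = DataRow(
                frame_number=int(parts[0]),
                timestamp_s=float(parts[1]),
                eye=parts[2],
                **{
                    col: float(parts[i])
                    for i, col in enumerate(COLUMNS)
                    if col not in ("frame_number", "timestamp_s", "eye", "quality")
                },
                quality=parts[-1],
            )
        except ValueError as exc:
            raise DataFileError(f"{path}:{lineno}: {exc}") from None
        rows.append(row)
    return rows, events


# ---------------------------------------------------------------------------
# Trace metrics
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Uniformly sampled series (degrees) with NaN gaps."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.values = np.asarray(self.values, dtype=float)


def velocity(trace: Trace) -> Trace:
    """Central-difference derivative; one-sided at the endpoints.

    A NaN sample makes its central-difference neighbors NaN (the difference
    involving it is undefined) — noise amplification is half that of a
    forward difference, which matters for RMS-velocity noise metrics.
    """
    x = trace.values
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * trace.fs / 2.0
    v[0] = (x[1] - x[0]) * trace.fs
    v[-1] = (x[-1] - x[-2]) * trace.fs
    return Trace(v, trace.fs)


def rms(series) -> float:
    """Root mean square over non-NaN samples."""
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        raise ValueError("all samples are NaN")
    return float(np.sqrt(np.mean(x[ok] ** 2)))


# ---------------------------------------------------------------------------
# Batch reprocessing
# ---------------------------------------------------------------------------

@dataclass
class BatchJob:
    video: str
    settings: str  # path to a settings file ('' = defaults)
    out_path: str
    calibration: str = ""  # path to a calibration file, optional
    timestamps: str = ""


def batch_process(jobs: Sequence[BatchJob]):
    """Run each job independently; failures are isolated per job.

    Returns a list of SessionReport (with ``source_error`` set on failure).
    """
    from vogkit.offline import process_video  # deferred: avoids import cycle
    from vogkit.core.session import SessionReport

    reports = []
    for job in jobs:
        try:
            report = process_video(
                job.video,
                settings_path=job.settings or None,
                calibration_path=job.calibration or None,
                timestamps_path=job.timestamps or None,
                out_path=job.out_path,
            )
        except Exception as exc:  # noqa: BLE001 - per-job isolation
            report = SessionReport(source_error=f"{type(exc).__name__}: {exc}")
        reports.append(report)
    return reports


def eye_enum(name: str) -> Eye:
    return Eye(name)


def quality_enum(name: str) -> Quality:
    return Quality(name)
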