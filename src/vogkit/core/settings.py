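"""Typed settings with text-file round-trip.

Settings are declared as dataclass fields (name, type, default) grouped into
sections.  The on-disk format is flat ``section.key = value`` text, UTF-8,
with ``#`` comments.  Saving then loading is the identity; unknown keys are
rejected with a message; missing keys take their declared defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Union


class SettingsError(ValueError):
    """Raised for unknown keys or values that do not parse as the declared type."""


def _parse_bool(text: str, key: str) -> bool:
    low = text.strip().lower()
    if low in ("true", "yes", "on", "1"):
        return True
    if low in ("false", "no", "off", "0"):
        return False
    raise SettingsError(f"setting '{key}': cannot parse {text!r} as bool")


def _parse_value(text: str, ftype: type, key: str) -> Any:
    text = text.strip()
    try:
        if ftype is bool:
            return _parse_bool(text, key)
        if ftype is int:
            return int(text)
        if ftype is float:
            return float(text)
        if ftype is str:
            return text
    except SettingsError:
        raise
    except ValueError:
        raise SettingsError(
            f"setting '{key}': cannot parse {text!r} as {ftype.__name__}"
        ) from None
    raise SettingsError(f"setting '{key}': unsupported type {ftype!r}")


def _format_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


@dataclass
class SettingsSection:
    """Base for a named group of typed settings."""

    def set_value(self, key: str, raw: Union[str, Any]) -> None:
        by_name = {f.name: f for f in fields(self)}
        if key not in by_name:
            raise SettingsError(
                f"unknown setting '{key}'; known: {', '.join(sorted(by_name))}"
            )
        ftype = by_name[key].type
        if isinstance(ftype, str):  # string annotations under future imports
            ftype = {"int": int, "float": float, "bool": bool, "str": str}[ftype]
        if isinstance(raw, str):
            value = _parse_value(raw, ftype, key)
        else:
            value = ftype(raw)
        setattr(self, key, value)

    def items(self):
        return [(f.name, getattr(self, f.name)) for f in fields(self)]


@dataclass
class SystemSettings(SettingsSection):
    n_workers: int = 0  # 0 = use available CPUs, capped below
    max_workers: int = 8
    buffer_capacity: int = 64
    realtime: bool = False  # drop frames when the buffer is full
    nominal_fps: float = 500.0


@dataclass
class PipelineSettings(SettingsSection):
    """Parameters of the combined eye-tracking pipeline.

    ``roi`` is "x0,y0,x1,y1" (half-open) or empty for the whole frame.
    """

    method: str = "ellipse_fit"  # centroid | convex_hull | ellipse_fit
    pupil_threshold: int = 80
    min_size_px2: int = 150
    max_size_px2: int = 50000
    roi: str = ""
    glints_enabled: bool = True
    glint_threshold: int = 220
    glint_min_size_px2: int = 1
    glint_max_size_px2: int = 500
    max_glints: int = 4
    torsion_enabled: bool = False
    iris_width_px: int = 40
    n_angles: int = 720
    n_radii: int = 20
    max_shift_deg: float = 15.0
    correlation_threshold: float = 0.5
    dpi_enabled: bool = False
    p1_threshold: int = 220
    p4_threshold: int = 170
    p4_search_radius: float = 40.0

    def roi_rect(self):
        """Parsed ROI as (x0, y0, x1, y1) ints, or None."""
        if not self.roi:
            return None
        parts = [p for p in self.roi.replace(" ", "").split(",") if p]
        if len(parts) != 4:
            raise SettingsError(f"setting 'roi': expected 4 integers, got {self.roi!r}")
        try:
            return tuple(int(p) for p in parts)
        except ValueError:
            raise SettingsError(
                f"setting 'roi': expected 4 integers, got {self.roi!r}"
            ) from None


@dataclass
class CalibrationSettings(SettingsSection):
    mode: str = "none"  # none | eye_model | regression
    feature: str = "auto"  # auto | pupil | pupil_cr
    radius_px: float = 260.0
    degree: int = 1


# Live-adjustable settings (remote setSetting); everything else requires a
# session restart.
LIVE_SETTINGS = frozenset(
    {
        "pupil_threshold",
        "glint_threshold",
        "min_size_px2",
        "max_size_px2",
        "p1_threshold",
        "p4_threshold",
        "correlation_threshold",
    }
)


@dataclass
class TrackerSettings:
    """All settings for one session, grouped in three sections."""

    system: SystemSettings = field(default_factory=SystemSettings)
    pipeline: PipelineSettings = field(default_factory=PipelineSettings)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)

    def sections(self):
        return [(f.name, getattr(self, f.name)) for f in fields(self)]

    def set_value(self, dotted_key: str, raw: Union[str, Any]) -> None:
        if "." not in dotted_key:
            raise SettingsError(
                f"setting key must be 'section.key', got {dotted_key!r}"
            )
        section_name, key = dotted_key.split(".", 1)
        by_name = dict(self.sections())
        if section_name not in by_name:
            raise SettingsError(
                f"unknown settings section '{section_name}'; "
                f"known: {', '.join(sorted(by_name))}"
            )
        by_name[section_name].set_value(key, raw)

    def content_hash(self) -> str:
        """Stable hash of all values; recorded in data-file headers."""
        text = "\n".join(
            f"{s}.{k}={_format_value(v)}"
            for s, sec in self.sections()
            for k, v in sec.items()
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def copy(self) -> "TrackerSettings":
        return dataclasses.replace(
            self,
            system=dataclasses.replace(self.system),
            pipeline=dataclasses.replace(self.pipeline),
            calibration=dataclasses.replace(self.calibration),
        )


def save_settings(settings: TrackerSettings, path) -> None:
    lines = ["# vogkit settings", ""]
    for section_name, section in settings.sections():
        for key, value in section.items():
            lines.append(f"{section_name}.{key} = {_format_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def load_settings(path) -> TrackerSettings:
    """Parse a ``section.key = value`` text file; missing keys keep defaults."""
    settings = TrackerSettings()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SettingsError(f"{path}:{lineno}: expected 'section.key = value'")
        key, value = line.split("=", 1)
        try:
            settings.set_value(key.strip(), value)
        except SettingsError as exc:
            raise SettingsError(f"{path}:{lineno}: {exc}") from None
    return settings
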