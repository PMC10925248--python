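"""Frame sources and sinks: lossless video containers, timestamp side-cars
and geometric pre-processing (split/crop/rotate/flip).

Two containers are supported, both bit-exact:

* uncompressed 8-bit grayscale AVI (``.avi``, BI_RGB with a gray palette),
  written and parsed directly — no codec, so round-trips are lossless;
* PNG image sequences (``frame_%06d.png`` in a directory).

Timestamp side-car files hold one float (seconds) per line, one per frame.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from vogkit.core.types import Eye, Frame


class VideoFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Uncompressed 8-bit AVI container (RIFF / 'DIB ' / BI_RGB + gray palette)
# ---------------------------------------------------------------------------

def _bmp_stride(width: int) -> int:
    return (width + 3) // 4 * 4


def write_avi(path, frames: Sequence[np.ndarray], fps: float = 500.0) -> None:
    """Write 8-bit grayscale frames as an uncompressed AVI."""
    frames = [np.asarray(f) for f in frames]
    for f in frames:
        if f.ndim != 2 or f.dtype != np.uint8:
            raise VideoFormatError("frames must be 2-D uint8 arrays")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise VideoFormatError(f"frames have mixed shapes: {sorted(shapes)}")
    height, width = frames[0].shape if frames else (0, 0)
    stride = _bmp_stride(width)
    frame_bytes = stride * height

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(list_type: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", list_type + payload)

    n = len(frames)
    rate = max(1, int(round(fps * 1000)))
    scale = 1000
    usec_per_frame = int(round(1_000_000 * scale / rate)) if rate else 0

    avih = struct.pack(
        "<IIIIIIIIIIIIII",
        usec_per_frame,          # dwMicroSecPerFrame
        frame_bytes * rate // scale if scale else 0,  # dwMaxBytesPerSec
        0,                       # dwPaddingGranularity
        0x10,                    # dwFlags: AVIF_HASINDEX
        n,                       # dwTotalFrames
        0,                       # dwInitialFrames
        1,                       # dwStreams
        frame_bytes,             # dwSuggestedBufferSize
        width,
        height,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        scale, rate,
        0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, width, height,
    )
    # BITMAPINFOHEADER + 256-entry grayscale palette
    bih = struct.pack(
        "<IiiHHIIiiII",
        40, width, height, 1, 8,
        0,                       # BI_RGB (uncompressed)
        frame_bytes, 0, 0, 256, 256,
    )
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = bih + palette

    movi_payload = b"movi"
    index_entries = []
    offset = 4  # relative to start of 'movi' fourcc
    for f in frames:
        rows = f[::-1]  # BMP convention: bottom-up row order
        if stride != width:
            padded = np.zeros((height, stride), dtype=np.uint8)
            padded[:, :width] = rows
            payload = padded.tobytes()
        else:
            payload = rows.tobytes()
        movi_payload += chunk(b"00db", payload)
        index_entries.append((b"00db", 0x10, offset, len(payload)))
        offset += 8 + len(payload) + (len(payload) % 2)

    idx1 = b"".join(
        struct.pack("<4sIII", cc, flags, off, size)
        for cc, flags, off, size in index_entries
    )

    hdrl = list_chunk(
        b"hdrl",
        chunk(b"avih", avih) + list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)),
    )
    riff_payload = b"AVI " + hdrl + chunk(b"LIST", movi_payload) + chunk(b"idx1", idx1)
    data = b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload
    Path(path).write_bytes(data)


def read_avi(path) -> Tuple[List[np.ndarray], float]:
    """Read an uncompressed 8-bit AVI; returns (frames, fps)."""
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise VideoFormatError(f"{path}: not a RIFF/AVI file")

    width = height = None
    compression = None
    fps = 0.0
    frames: List[np.ndarray] = []

    def parse(start: int, end: int) -> None:
        nonlocal width, height, compression, fps
        pos = start
        while pos + 8 <= end:
            fourcc = data[pos:pos + 4]
            (size,) = struct.unpack_from("<I", data, pos + 4)
            body_start = pos + 8
            body_end = body_start + size
            if fourcc == b"LIST":
                parse(body_start + 4, body_end)
            elif fourcc == b"strh":
                scale, rate = struct.unpack_from("<II", data, body_start + 20)
                if scale:
                    fps = rate / scale
            elif fourcc == b"strf":
                (_, w, h, _, bitcount, comp) = struct.unpack_from(
                    "<IiiHHI", data, body_start
                )
                width, height, compression = w, abs(h), comp
                if bitcount != 8:
                    raise VideoFormatError(
                        f"{path}: only 8-bit grayscale supported, got {bitcount}-bit"
                    )
                if comp != 0:
                    raise VideoFormatError(
                        f"{path}: compressed stream (biCompression={comp:#x}); "
                        "only raw uncompressed video is supported"
                    )
            elif fourcc in (b"00db", b"00dc"):
                if width is None:
                    raise VideoFormatError(f"{path}: frame chunk before stream header")
                stride = _bmp_stride(width)
                raw = np.frombuffer(data[body_start:body_end], dtype=np.uint8)
                if raw.size != stride * height:
                    raise VideoFormatError(f"{path}: frame chunk size mismatch")
                img = raw.reshape(height, stride)[:, :width][::-1].copy()
                frames.append(img)
            pos = body_end + (size % 2)

    parse(12, len(data))
    if width is None:
        raise VideoFormatError(f"{path}: no video stream found")
    return frames, fps


# ---------------------------------------------------------------------------
# PNG sequences
# ---------------------------------------------------------------------------

def write_png_sequence(directory, frames: Sequence[np.ndarray]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) > 1:
        raise VideoFormatError(f"frames have mixed shapes: {sorted(shapes)}")
    for i, f in enumerate(frames):
        f = np.asarray(f)
        if f.ndim != 2 or f.dtype != np.uint8:
            raise VideoFormatError("frames must be 2-D uint8 arrays")
        iio.imwrite(directory / f"frame_{i:06d}.png", f)


def read_png_sequence(directory) -> List[np.ndarray]:
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    return [np.asarray(iio.imread(p)) for p in paths]


# ---------------------------------------------------------------------------
# Frame sources / sinks
# ---------------------------------------------------------------------------

def write_raw_video(path, frames: Sequence[np.ndarray], fps: float = 500.0) -> None:
    """Lossless write: ``.avi`` file or a directory of PNGs."""
    path = Path(path)
    if path.suffix.lower() == ".avi":
        write_avi(path, frames, fps=fps)
    else:
        write_png_sequence(path, frames)


def read_timestamps(path) -> np.ndarray:
    values = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise VideoFormatError(f"{path}:{lineno}: bad timestamp {line!r}") from None
    return np.asarray(values, dtype=float)


class VideoSource:
    """Iterable of Frames from a lossless video file or PNG directory."""

    def __init__(
        self,
        path,
        timestamps_path=None,
        nominal_fps: float = 500.0,
        eye: Eye = Eye.BOTH,
    ):
        self.path = Path(path)
        self.eye = eye
        if not self.path.exists():
            raise FileNotFoundError(str(self.path))
        if self.path.is_dir():
            self._frames = read_png_sequence(self.path)
            self.fps = nominal_fps
        else:
            self._frames, fps = read_avi(self.path)
            self.fps = fps or nominal_fps
        if timestamps_path is not None:
            ts = read_timestamps(timestamps_path)
            if len(ts) != len(self._frames):
                raise VideoFormatError(
                    f"timestamp count ({len(ts)}) != frame count ({len(self._frames)})"
                )
            self._timestamps = ts
        else:
            self._timestamps = np.arange(len(self._frames)) / self.fps

    def __len__(self) -> int:
        return len(self._frames)

    def __iter__(self) -> Iterator[Frame]:
        for i, img in enumerate(self._frames):
            yield Frame(i, float(self._timestamps[i]), self.eye, img)


def open_video(path, timestamps_path=None, nominal_fps: float = 500.0,
               eye: Eye = Eye.BOTH) -> VideoSource:
    return VideoSource(path, timestamps_path, nominal_fps, eye)


class VideoSink:
    """Collects frames and writes a lossless video on close."""

    def __init__(self, path, fps: float = 500.0):
        self.path = Path(path)
        self.fps = fps
        self._images: List[np.ndarray] = []

    def write(self, frame: Frame) -> None:
        self._images.append(frame.image)

    def close(self) -> None:
        write_raw_video(self.path, self._images, fps=self.fps)


# ---------------------------------------------------------------------------
# Geometric pre-processing
# ---------------------------------------------------------------------------

class Split(enum.Enum):
    NONE = "none"
    LEFT_RIGHT_HALVES = "left_right_halves"


class Flip(enum.Enum):
    NONE = "none"
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


@dataclass
class SourceGeometry:
    """How raw camera frames map to per-eye images.

    Order of operations: split -> crop -> rotate -> flip.  Crop rectangles
    are half-open [x0, x1) x [y0, y1) in post-split coordinates.
    """

    split: Split = Split.NONE
    crop: Optional[Tuple[int, int, int, int]] = None
    rotation_deg: int = 0  # multiples of 90, counter-clockwise in array terms
    flip: Flip = Flip.NONE

    def __post_init__(self) -> None:
        if self.rotation_deg % 90 != 0:
            raise ValueError("rotation must be a multiple of 90 degrees")


def _apply_geometry(img: np.ndarray, geometry: SourceGeometry) -> np.ndarray:
    if geometry.crop is not None:
        x0, y0, x1, y1 = geometry.crop
        h, w = img.shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(
                f"crop [{x0},{x1})x[{y0},{y1}) outside image bounds {w}x{h}"
            )
        img = img[y0:y1, x0:x1]
    k = (geometry.rotation_deg // 90) % 4
    if k:
        img = np.rot90(img, k)
    if geometry.flip is Flip.HORIZONTAL:
        img = img[:, ::-1]
    elif geometry.flip is Flip.VERTICAL:
        img = img[::-1, :]
    return np.ascontiguousarray(img)


def preprocess(frame: Frame, geometry: SourceGeometry,
               right_geometry: Optional[SourceGeometry] = None) -> List[Frame]:
    """Map a raw frame to one or two per-eye frames.

    With ``split=left_right_halves`` the left half becomes the LEFT eye and
    the right half the RIGHT eye; ``geometry`` applies to the left,
    ``right_geometry`` (default: same) to the right.
    """
    if geometry.split is Split.NONE:
        return [
            Frame(frame.frame_number, frame.timestamp, frame.eye,
                  _apply_geometry(frame.image, geometry))
        ]
    h, w = frame.image.shape
    half = w // 2
    left_img = frame.image[:, :half]
    right_img = frame.image[:, half: 2 * half]
    rg = right_geometry if right_geometry is not None else geometry
    return [
        Frame(frame.frame_number, frame.timestamp, Eye.LEFT,
              _apply_geometry(left_img, geometry)),
        Frame(frame.frame_number, frame.timestamp, Eye.RIGHT,
              _apply_geometry(right_img, rg)),
    ]
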