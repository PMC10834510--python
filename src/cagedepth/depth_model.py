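"""Core 16-bit depth-frame types, bit-plane transforms, and depth I/O.

Top-down home-cage monitoring stores each video frame as a single-channel
16-bit image whose pixel values are distances from the camera to the scene,
nominally in millimetres; the value 0 is reserved for invalid pixels
(sensor dropout / no return).

The codec never compresses 16-bit data directly.  Every frame is split into
two 8-bit *bit planes* -- the most-significant byte (MSB) and the
least-significant byte (LSB) of each sample, with

    value = msb * 256 + lsb

The MSB plane changes slowly (coarse geometry) and compresses losslessly to
almost nothing; the LSB plane carries the rapidly varying fine detail and
may be compressed lossily.  This module owns the frame/sequence containers,
the exact split/merge transforms, depth-range handling, and the plain-file
readers and writers (16-bit grayscale PNG sequences and raw ``.d16``
little-endian dumps with a JSON header).

Conventions used throughout the package: pixel coordinates are 0-based,
x rightward, y downward; raw binary depth is little-endian unsigned 16-bit,
row-major from the top-left.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: Maximum representable depth sample (16-bit unsigned).
FULL_MAX = 65535

#: Depth ceiling when the depth stream is spatially aligned to the RGB
#: camera.  Alignment degrades if the value range is too large; for mouse
#: recordings values in [0, 4096] suffice.
ALIGNED_MAX = 4096

RangeMode = Literal["aligned", "full"]
_RANGE_MODES = ("aligned", "full")


@dataclasses.dataclass(frozen=True, eq=False)
class DepthFrame:
    """One 16-bit single-channel depth image.

    Parameters
    ----------
    values
        ``(height, width)`` array of unsigned 16-bit depth samples
        (millimetres).  0 marks invalid / no-depth pixels.
    timestamp
        Seconds since recording start.
    frame_index
        Ordinal position in the parent sequence, >= 0.
    """

    values: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"depth frame must be 2-D, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"depth frame must be non-empty, got shape {v.shape}")
        if v.dtype != np.uint16:
            if np.issubdtype(v.dtype, np.integer) and v.min() >= 0 and v.max() <= FULL_MAX:
                v = v.astype(np.uint16)
            else:
                raise ValueError(
                    f"depth samples must be unsigned 16-bit, got dtype {v.dtype}"
                )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    def equals(self, other: "DepthFrame") -> bool:
        """Pixel-for-pixel equality (metadata ignored)."""
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclasses.dataclass(frozen=True, eq=False)
class BitPlanePair:
    """The two 8-bit images (MSB, LSB) produced by splitting a depth frame."""

    msb: np.ndarray
    lsb: np.ndarray

    def __post_init__(self) -> None:
        for name in ("msb", "lsb"):
            p = np.asarray(getattr(self, name))
            if p.ndim != 2:
                raise ValueError(f"{name} plane must be 2-D, got shape {p.shape}")
            if p.dtype != np.uint8:
                raise ValueError(f"{name} plane must be uint8, got {p.dtype}")
        if self.msb.shape != self.lsb.shape:
            raise ValueError(
                f"plane dimension mismatch: msb {self.msb.shape} vs lsb {self.lsb.shape}"
            )


@dataclasses.dataclass(eq=False)
class DepthSequence:
    """An ordered run of depth frames with a common geometry.

    Invariants: ``frame_index`` strictly increasing from 0, all frames share
    dimensions, and in ``aligned`` range mode every sample is <= 4096.
    """

    frames: list[DepthFrame]
    frame_rate: float = 15.0
    range_mode: RangeMode = "aligned"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.range_mode not in _RANGE_MODES:
            raise ValueError(f"unknown range_mode {self.range_mode!r}")
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        shape = self.frames[0].values.shape
        for i, f in enumerate(self.frames):
            if f.values.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.values.shape}, expected {shape}"
                )
            if f.frame_index != i:
                raise ValueError(
                    f"frame_index must increase from 0; frame {i} has index {f.frame_index}"
                )
        if self.range_mode == "aligned":
            peak = max(int(f.values.max()) for f in self.frames)
            if peak > ALIGNED_MAX:
                raise ValueError(
                    f"aligned-mode sample {peak} exceeds {ALIGNED_MAX}; "
                    "clamp with clamp_to_range or use range_mode='full'"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def width(self) -> int:
        return self.frames[0].width

    @property
    def height(self) -> int:
        return self.frames[0].height

    @property
    def raw_bytes(self) -> int:
        """Uncompressed size: 2 bytes per pixel per frame."""
        return len(self.frames) * self.width * self.height * 2

    def to_array(self) -> np.ndarray:
        """Stack into a ``(n_frames, height, width)`` uint16 array."""
        return np.stack([f.values for f in self.frames])

    @classmethod
    def from_array(
        cls,
        stack: np.ndarray,
        frame_rate: float = 15.0,
        range_mode: RangeMode = "aligned",
    ) -> "DepthSequence":
        """Build a sequence from a ``(n, h, w)`` array; timestamps from frame rate."""
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError(f"expected (n, h, w) stack, got shape {stack.shape}")
        frames = [
            DepthFrame(stack[i], timestamp=i / frame_rate, frame_index=i)
            for i in range(stack.shape[0])
        ]
        return cls(frames, frame_rate=frame_rate, range_mode=range_mode)

    def equals(self, other: "DepthSequence") -> bool:
        return len(self) == len(other) and all(
            a.equals(b) for a, b in zip(self.frames, other.frames)
        )


# ---------------------------------------------------------------------------
# Bit-plane transforms
# ---------------------------------------------------------------------------

def split_frame(frame: DepthFrame) -> BitPlanePair:
    """Split a 16-bit frame into its MSB and LSB byte planes.

    For every pixel ``msb = value // 256`` and ``lsb = value % 256``.
    """
    v = frame.values
    return BitPlanePair(msb=(v >> 8).astype(np.uint8), lsb=(v & 0xFF).astype(np.uint8))


def merge_planes(pair: BitPlanePair, *, timestamp: float = 0.0, frame_index: int = 0) -> DepthFrame:
    """Recombine an MSB/LSB plane pair into the original 16-bit frame.

    Exact inverse of :func:`split_frame`: ``value = msb * 256 + lsb``.
    """
    values = (pair.msb.astype(np.uint16) << 8) | pair.lsb.astype(np.uint16)
    return DepthFrame(values, timestamp=timestamp, frame_index=frame_index)


def clamp_to_range(frame: DepthFrame, mode: RangeMode) -> DepthFrame:
    """Force a frame into the declared depth range.

    In ``aligned`` mode samples above 4096 are clamped to 4096 (sensor
    glitches should not abort long recordings); the clamped-pixel count is
    logged.  In ``full`` mode the frame passes through unchanged.
    """
    if mode == "full":
        return frame
    if mode != "aligned":
        raise ValueError(f"unknown range_mode {mode!r}")
    n_over = int(np.count_nonzero(frame.values > ALIGNED_MAX))
    if n_over == 0:
        return frame
    logger.info(
        "clamp_to_range frame=%d clamped_pixels=%d ceiling=%d",
        frame.frame_index, n_over, ALIGNED_MAX,
    )
    return DepthFrame(
        np.minimum(frame.values, ALIGNED_MAX),
        timestamp=frame.timestamp,
        frame_index=frame.frame_index,
    )


def clamp_sequence(seq: DepthSequence, mode: RangeMode) -> DepthSequence:
    """Apply :func:`clamp_to_range` to every frame and retag the range mode."""
    return DepthSequence(
        [clamp_to_range(f, mode) for f in seq.frames],
        frame_rate=seq.frame_rate,
        range_mode=mode,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_png_sequence(seq: DepthSequence, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write each frame as a zero-padded 16-bit grayscale PNG.

    Files are named ``<prefix>_000000.png`` etc.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in seq.frames:
        p = out_dir / f"{prefix}_{f.frame_index:06d}.png"
        iio.imwrite(p, f.values)
        paths.append(p)
    return paths


def read_png_sequence(
    in_dir: str | Path,
    frame_rate: float = 15.0,
    range_mode: RangeMode = "aligned",
) -> DepthSequence:
    """Read a directory of 16-bit grayscale PNGs, sorted by filename."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG frames found in {in_dir}")
    stack = np.stack([np.asarray(iio.imread(p)).astype(np.uint16) for p in paths])
    return DepthSequence.from_array(stack, frame_rate=frame_rate, range_mode=range_mode)


def write_d16(seq: DepthSequence, path: str | Path) -> Path:
    """Write a raw binary depth dump (little-endian uint16, row-major).

    A JSON header ``<path>.json`` records width, height, frame_count,
    frame_rate, range_mode and endianness.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = seq.to_array().astype("<u2")
    path.write_bytes(stack.tobytes())
    header = {
        "width": seq.width,
        "height": seq.height,
        "frame_count": len(seq),
        "frame_rate": seq.frame_rate,
        "range_mode": seq.range_mode,
        "endianness": "little",
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2))
    return path


def read_d16(path: str | Path) -> DepthSequence:
    """Read a raw ``.d16`` dump written by :func:`write_d16`."""
    path = Path(path)
    header_path = Path(str(path) + ".json")
    if not header_path.exists():
        raise FileNotFoundError(f"missing .d16 header {header_path}")
    header = json.loads(header_path.read_text())
    if header.get("endianness", "little") != "little":
        raise ValueError(f"unsupported endianness {header['endianness']!r}")
    w, h, n = header["width"], header["height"], header["frame_count"]
    data = np.frombuffer(path.read_bytes(), dtype="<u2")
    if data.size != n * h * w:
        raise ValueError(
            f"{path}: expected {n * h * w} samples ({n}x{h}x{w}), found {data.size}"
        )
    stack = data.reshape(n, h, w).astype(np.uint16)
    return DepthSequence.from_array(
        stack, frame_rate=header["frame_rate"], range_mode=header["range_mode"]
    )
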