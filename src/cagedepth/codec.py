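"""Dual-stream depth codec: lossless MSB + configurable-quality LSB.

A 16-bit depth sequence is split per frame into its MSB and LSB byte planes
(:mod:`.depth_model`) and each plane becomes its own 8-bit grayscale video
stream.  The MSB stream is always compressed losslessly -- it carries the
coarse geometry and changes infrequently -- while the LSB stream, which
holds the rapidly varying fine detail, is compressed at a configurable
rung of a documented quality ladder::

    lossless  >  high  >  medium  >  low

Because the MSB plane is bit-exact at every setting, the per-pixel
reconstruction error is confined to the LSB byte and can never exceed 255
depth units; with ``lsb_quality="lossless"`` the full 16-bit round trip is
bit-exact.

Two interchangeable stream backends are provided:

``image`` (default)
    Each stream is a sequence of independently coded frames -- PNG for
    lossless, JPEG at a per-rung quality for lossy -- stored in a simple
    length-prefixed container (``.seq``).  Pure-Python via Pillow, always
    available, deterministic.
``ffmpeg``
    H.264 via an external ``ffmpeg`` binary: x264 ``-qp 0`` (lossless
    grayscale) for the MSB stream and a CRF ladder for the LSB stream,
    written as ``.mp4``.  Selected automatically when ffmpeg is on PATH.

An encoded recording on disk is two stream files per clip plus one JSON
sidecar holding frame geometry, settings, timestamps, experiment metadata
and clip boundaries.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
import math
import shutil
import struct
import subprocess
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .depth_model import (
    BitPlanePair,
    DepthFrame,
    DepthSequence,
    RangeMode,
    merge_planes,
    split_frame,
)
from .quality import QualityReport, sequence_quality

logger = logging.getLogger(__name__)

#: Ordered LSB quality ladder, worst to best.
QUALITY_LADDER = ("low", "medium", "high", "lossless")

#: JPEG quality per lossy rung (image backend).
_JPEG_QUALITY = {"low": 50, "medium": 80, "high": 95}

#: x264 CRF per lossy rung (ffmpeg backend); lossless uses -qp 0.
_X264_CRF = {"low": 35, "medium": 23, "high": 10}


class CodecError(RuntimeError):
    """Raised when an encoded recording is inconsistent or undecodable."""


@dataclasses.dataclass(frozen=True)
class EncoderSettings:
    """Codec configuration.

    The MSB stream mode is fixed lossless and not user-overridable; only
    the LSB rung, frame rate, clip duration and backend are configurable.
    """

    lsb_quality: str = "medium"
    frame_rate: float = 15.0
    clip_duration: float | None = None
    backend: str = "auto"

    def __post_init__(self) -> None:
        if self.lsb_quality not in QUALITY_LADDER:
            raise ValueError(
                f"lsb_quality must be one of {QUALITY_LADDER}, got {self.lsb_quality!r}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.clip_duration is not None and self.clip_duration <= 0:
            raise ValueError("clip_duration must be positive when set")
        if self.backend not in ("auto", "image", "ffmpeg"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def msb_mode(self) -> str:
        return "lossless"


# ---------------------------------------------------------------------------
# Stream backends
# ---------------------------------------------------------------------------

_SEQ_MAGIC = b"CDSQ1\n"


class ImageStreamBackend:
    """Per-frame PNG/JPEG streams in a length-prefixed ``.seq`` container.

    Layout: magic, one JSON header line ``{"codec", "frames", "height",
    "width"}``, then per frame a 4-byte big-endian payload length followed
    by the PNG or JPEG bytes.
    """

    name = "image"
    extension = "seq"

    def encode_stream(
        self, frames: np.ndarray, path: Path, quality: str, frame_rate: float
    ) -> None:
        codec = "png" if quality == "lossless" else "jpeg"
        header = {
            "codec": codec,
            "frames": int(frames.shape[0]),
            "height": int(frames.shape[1]),
            "width": int(frames.shape[2]),
        }
        with open(path, "wb") as fh:
            fh.write(_SEQ_MAGIC)
            fh.write((json.dumps(header) + "\n").encode())
            for plane in frames:
                buf = io.BytesIO()
                img = Image.fromarray(plane, mode="L")
                if codec == "png":
                    img.save(buf, format="PNG", optimize=True)
                else:
                    img.save(buf, format="JPEG", quality=_JPEG_QUALITY[quality])
                payload = buf.getvalue()
                fh.write(struct.pack(">I", len(payload)))
                fh.write(payload)

    def decode_stream(self, path: Path) -> np.ndarray:
        with open(path, "rb") as fh:
            magic = fh.read(len(_SEQ_MAGIC))
            if magic != _SEQ_MAGIC:
                raise CodecError(f"{path}: not a cagedepth stream container")
            header = json.loads(fh.readline())
            n, h, w = header["frames"], header["height"], header["width"]
            out = np.empty((n, h, w), dtype=np.uint8)
            for i in range(n):
                raw = fh.read(4)
                if len(raw) != 4:
                    raise CodecError(f"{path}: truncated at frame {i}")
                (size,) = struct.unpack(">I", raw)
                payload = fh.read(size)
                if len(payload) != size:
                    raise CodecError(f"{path}: truncated payload at frame {i}")
                img = Image.open(io.BytesIO(payload))
                arr = np.asarray(img.convert("L"), dtype=np.uint8)
                if arr.shape != (h, w):
                    raise CodecError(
                        f"{path}: frame {i} has shape {arr.shape}, expected {(h, w)}"
                    )
                out[i] = arr
        return out


def build_ffmpeg_encode_args(
    path: Path | str, width: int, height: int, frame_rate: float, quality: str
) -> list[str]:
    """Construct the ffmpeg command line for one 8-bit grayscale H.264 stream.

    Lossless uses x264 ``-qp 0``; lossy rungs use the CRF ladder.  Frames
    are piped in as raw grayscale to keep chroma out of the depth bits.
    """
    args = [
        "ffmpeg", "-hide_banner", "-loglevel", "error", "-y",
        "-f", "rawvideo", "-pix_fmt", "gray",
        "-s", f"{width}x{height}", "-r", f"{frame_rate}",
        "-i", "-",
        "-c:v", "libx264", "-preset", "veryfast", "-pix_fmt", "gray",
    ]
    if quality == "lossless":
        args += ["-qp", "0"]
    else:
        args += ["-crf", str(_X264_CRF[quality])]
    args.append(str(path))
    return args


class FfmpegStreamBackend:
    """H.264 streams through an external ffmpeg/libx264 binary."""

    name = "ffmpeg"
    extension = "mp4"

    @staticmethod
    def available() -> bool:
        return shutil.which("ffmpeg") is not None

    def _require(self) -> None:
        if not self.available():
            raise CodecError(
                "ffmpeg binary not found on PATH; install ffmpeg with libx264 "
                "or use the default 'image' backend"
            )

    def encode_stream(
        self, frames: np.ndarray, path: Path, quality: str, frame_rate: float
    ) -> None:
        self._require()
        args = build_ffmpeg_encode_args(
            path, frames.shape[2], frames.shape[1], frame_rate, quality
        )
        proc = subprocess.run(args, input=frames.tobytes(), capture_output=True)
        if proc.returncode != 0:
            raise CodecError(f"ffmpeg encode failed for {path}: {proc.stderr.decode()}")

    def decode_stream(self, path: Path) -> np.ndarray:
        self._require()
        probe = subprocess.run(
            ["ffprobe", "-v", "error", "-select_streams", "v:0",
             "-show_entries", "stream=width,height", "-of", "json", str(path)],
            capture_output=True,
        )
        if probe.returncode != 0:
            raise CodecError(f"ffprobe failed for {path}: {probe.stderr.decode()}")
        st = json.loads(probe.stdout)["streams"][0]
        w, h = st["width"], st["height"]
        proc = subprocess.run(
            ["ffmpeg", "-hide_banner", "-loglevel", "error",
             "-i", str(path), "-f", "rawvideo", "-pix_fmt", "gray", "-"],
            capture_output=True,
        )
        if proc.returncode != 0:
            raise CodecError(f"ffmpeg decode failed for {path}: {proc.stderr.decode()}")
        data = np.frombuffer(proc.stdout, dtype=np.uint8)
        if data.size % (w * h) != 0:
            raise CodecError(f"{path}: decoded byte count not a multiple of frame size")
        return data.reshape(-1, h, w)


_BACKENDS = {"image": ImageStreamBackend, "ffmpeg": FfmpegStreamBackend}


def get_backend(name: str = "auto"):
    """Resolve a backend name; ``auto`` prefers ffmpeg when installed."""
    if name == "auto":
        name = "ffmpeg" if FfmpegStreamBackend.available() else "image"
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown backend {name!r}") from None


# ---------------------------------------------------------------------------
# Clip segmentation
# ---------------------------------------------------------------------------

def segment_into_clips(
    frame_count: int, fps: float, clip_duration: float | None
) -> list[tuple[int, int]]:
    """Partition ``[0, frame_count)`` into contiguous half-open clip ranges.

    Each clip spans at most ``clip_duration`` seconds; the final clip may be
    shorter.  ``clip_duration=None`` yields a single clip.
    """
    if frame_count <= 0:
        raise ValueError("frame_count must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if clip_duration is None:
        return [(0, frame_count)]
    if clip_duration <= 0:
        raise ValueError("clip_duration must be positive")
    per_clip = max(1, math.floor(clip_duration * fps + 1e-9))
    return [
        (start, min(start + per_clip, frame_count))
        for start in range(0, frame_count, per_clip)
    ]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EncodedRecording:
    """Two compressed plane streams (per clip) plus a JSON sidecar on disk."""

    directory: Path
    sidecar: dict

    @property
    def sidecar_path(self) -> Path:
        return self.directory / f"{self.sidecar['name']}.json"

    @property
    def raw_bytes(self) -> int:
        return int(self.sidecar["raw_bytes"])

    @property
    def encoded_bytes(self) -> int:
        return int(self.sidecar["encoded_bytes"])

    @property
    def clips(self) -> list[dict]:
        return self.sidecar["clips"]

    def stream_paths(self) -> list[Path]:
        return [
            self.directory / clip[plane]
            for clip in self.clips
            for plane in ("msb", "lsb")
        ]

    @classmethod
    def load(cls, sidecar_path: str | Path) -> "EncodedRecording":
        sidecar_path = Path(sidecar_path)
        if not sidecar_path.exists():
            raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
        return cls(directory=sidecar_path.parent, sidecar=json.loads(sidecar_path.read_text()))


def compression_ratio(raw_bytes: int, encoded_bytes: int) -> float:
    """Storage saving factor: uncompressed bytes over encoded bytes.

    ``raw_bytes`` is frames x width x height x 2 for 16-bit depth.
    """
    if raw_bytes <= 0 or encoded_bytes <= 0:
        raise ValueError(
            f"byte counts must be positive, got raw={raw_bytes} encoded={encoded_bytes}"
        )
    return raw_bytes / encoded_bytes


def encode_sequence(
    seq: DepthSequence,
    settings: EncoderSettings,
    out_dir: str | Path,
    name: str = "recording",
    metadata: dict | None = None,
) -> EncodedRecording:
    """Encode a depth sequence into MSB/LSB streams plus a JSON sidecar.

    When ``settings.clip_duration`` is set the streams are segmented into
    clips of at most that duration (``<name>.clip0000.msb.<ext>`` etc.);
    otherwise a single pair ``<name>.msb.<ext>`` / ``<name>.lsb.<ext>`` is
    written.  Experiment metadata is carried verbatim into the sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    backend = get_backend(settings.backend)
    n = len(seq)
    stack = seq.to_array()
    msb_all = (stack >> 8).astype(np.uint8)
    lsb_all = (stack & 0xFF).astype(np.uint8)

    ranges = segment_into_clips(n, settings.frame_rate, settings.clip_duration)
    clips = []
    for ci, (start, end) in enumerate(ranges):
        if len(ranges) == 1:
            stem = name
        else:
            stem = f"{name}.clip{ci:04d}"
        clip = {
            "index": ci,
            "start_frame": start,
            "end_frame": end,
            "msb": f"{stem}.msb.{backend.extension}",
            "lsb": f"{stem}.lsb.{backend.extension}",
        }
        backend.encode_stream(
            msb_all[start:end], out_dir / clip["msb"], "lossless", settings.frame_rate
        )
        backend.encode_stream(
            lsb_all[start:end], out_dir / clip["lsb"], settings.lsb_quality,
            settings.frame_rate,
        )
        clips.append(clip)

    encoded_bytes = sum(
        (out_dir / clip[p]).stat().st_size for clip in clips for p in ("msb", "lsb")
    )
    sidecar = {
        "format": "cagedepth-recording",
        "version": 1,
        "name": name,
        "width": seq.width,
        "height": seq.height,
        "frame_count": n,
        "frame_rate": seq.frame_rate,
        "range_mode": seq.range_mode,
        "settings": {
            "msb_mode": settings.msb_mode,
            "lsb_quality": settings.lsb_quality,
            "clip_duration": settings.clip_duration,
            "backend": backend.name,
        },
        "timestamps": [f.timestamp for f in seq.frames],
        "metadata": metadata or {},
        "clips": clips,
        "raw_bytes": seq.raw_bytes,
        "encoded_bytes": encoded_bytes,
    }
    rec = EncodedRecording(directory=out_dir, sidecar=sidecar)
    rec.sidecar_path.write_text(json.dumps(sidecar, indent=2))
    logger.info(
        "encode name=%s frames=%d raw_bytes=%d encoded_bytes=%d ratio=%.2f",
        name, n, seq.raw_bytes, encoded_bytes, seq.raw_bytes / encoded_bytes,
    )
    return rec


def decode_recording(rec: EncodedRecording | str | Path) -> DepthSequence:
    """Decode both streams of a recording and recombine to 16-bit depth.

    Accepts an :class:`EncodedRecording` or a sidecar path.  Frame counts
    are checked against the sidecar per clip and per plane; a mismatch or a
    missing stream file is reported with the stream's identity.
    """
    if not isinstance(rec, EncodedRecording):
        rec = EncodedRecording.load(rec)
    sc = rec.sidecar
    backend = get_backend(sc["settings"]["backend"])
    n, h, w = sc["frame_count"], sc["height"], sc["width"]
    stack = np.empty((n, h, w), dtype=np.uint16)
    for clip in sc["clips"]:
        start, end = clip["start_frame"], clip["end_frame"]
        planes = {}
        for plane in ("msb", "lsb"):
            path = rec.directory / clip[plane]
            if not path.exists():
                raise FileNotFoundError(f"missing {plane} stream file: {path}")
            decoded = backend.decode_stream(path)
            expected = end - start
            if decoded.shape[0] != expected:
                raise CodecError(
                    f"{plane} stream {path.name}: decoded {decoded.shape[0]} frames, "
                    f"sidecar declares {expected}"
                )
            if decoded.shape[1:] != (h, w):
                raise CodecError(
                    f"{plane} stream {path.name}: frame shape {decoded.shape[1:]}, "
                    f"sidecar declares {(h, w)}"
                )
            planes[plane] = decoded
        stack[start:end] = (planes["msb"].astype(np.uint16) << 8) | planes["lsb"]

    timestamps = sc.get("timestamps") or [i / sc["frame_rate"] for i in range(n)]
    frames = [
        DepthFrame(stack[i], timestamp=timestamps[i], frame_index=i) for i in range(n)
    ]
    # Lossy LSB decode may exceed 4096 on aligned input (JPEG overshoot of
    # the low byte); the decoded sequence is tagged "full" in that case so
    # the container invariant stays honest.
    range_mode: RangeMode = sc["range_mode"]
    if range_mode == "aligned" and int(stack.max()) > 4096:
        range_mode = "full"
    return DepthSequence(frames, frame_rate=sc["frame_rate"], range_mode=range_mode)


def verify_recording(seq: DepthSequence, rec: EncodedRecording | str | Path) -> QualityReport:
    """Decode a recording and score it against the original sequence.

    Returns pooled MSE/PSNR, the compression ratio, and an ``exact`` flag
    (true iff the reconstruction is bit-identical).
    """
    if not isinstance(rec, EncodedRecording):
        rec = EncodedRecording.load(rec)
    decoded = decode_recording(rec)
    report = sequence_quality(
        seq, decoded, raw_bytes=rec.raw_bytes, encoded_bytes=rec.encoded_bytes
    )
    logger.info("verify name=%s %s", rec.sidecar["name"], report.summary())
    return report
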