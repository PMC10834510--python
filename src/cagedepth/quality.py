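"""Reconstruction-quality metrics: MSE, PSNR and compression ratio.

PSNR for 16-bit depth uses the full-scale peak unconditionally:

    MSE  = (1 / (m n)) sum_xy (I_orig(x, y) - I_comp(x, y))^2
    PSNR = 10 log10(65535^2 / MSE)      [dB]

Even in aligned mode (samples <= 4096) the peak stays 65535, so reported
PSNR values are comparable across range modes.  A sequence is scored by
pooling the squared errors of all pixels of all frames into one global MSE
and taking one PSNR -- not by averaging per-frame PSNRs.

Zero-valued (invalid) pixels are included in the comparison by default;
pass ``mask_invalid=True`` to exclude pixels that are 0 in either frame.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .depth_model import DepthFrame, DepthSequence, FULL_MAX

#: Sentinel PSNR for an exact (MSE = 0) reconstruction.
PSNR_INFINITE = math.inf


@dataclasses.dataclass(frozen=True)
class QualityReport:
    """MSE, PSNR and compression ratio for an original/reconstruction pair."""

    mse: float
    psnr_db: float
    compression_ratio: float | None
    n_frames: int
    exact: bool

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if math.isinf(d["psnr_db"]):
            d["psnr_db"] = "inf"
        return d

    def summary(self) -> str:
        psnr = "inf" if math.isinf(self.psnr_db) else f"{self.psnr_db:.2f}"
        ratio = "n/a" if self.compression_ratio is None else f"{self.compression_ratio:.2f}x"
        return (
            f"frames={self.n_frames} mse={self.mse:.6g} psnr_db={psnr} "
            f"ratio={ratio} exact={self.exact}"
        )


def _squared_error(orig: np.ndarray, comp: np.ndarray, mask_invalid: bool):
    """Return (sum of squared differences, number of compared samples)."""
    diff = orig.astype(np.int64) - comp.astype(np.int64)
    if mask_invalid:
        valid = (orig != 0) & (comp != 0)
        diff = diff[valid]
        n = int(valid.sum())
    else:
        n = diff.size
    return float(np.sum(diff * diff, dtype=np.float64)), n


def frame_mse(orig: DepthFrame, comp: DepthFrame, mask_invalid: bool = False) -> float:
    """Mean squared error between two equally sized depth frames."""
    if orig.values.shape != comp.values.shape:
        raise ValueError(
            f"dimension mismatch: {orig.values.shape} vs {comp.values.shape}"
        )
    sse, n = _squared_error(orig.values, comp.values, mask_invalid)
    if n == 0:
        raise ValueError("no valid pixels to compare (all masked)")
    return sse / n


def psnr(mse: float, peak: int = FULL_MAX) -> float:
    """Peak signal-to-noise ratio in dB; infinite sentinel when MSE is 0."""
    if mse < 0:
        raise ValueError(f"MSE must be non-negative, got {mse}")
    if mse == 0:
        return PSNR_INFINITE
    return 10.0 * math.log10(peak * peak / mse)


def sequence_quality(
    orig: DepthSequence,
    comp: DepthSequence,
    raw_bytes: int | None = None,
    encoded_bytes: int | None = None,
    mask_invalid: bool = False,
) -> QualityReport:
    """Pooled MSE/PSNR over all pixels of all frames, plus compression ratio.

    The global MSE is the pixel-count-weighted mean of the per-frame MSEs,
    i.e. total squared error over total compared pixels, giving one PSNR for
    the whole recording.
    """
    if len(orig) != len(comp):
        raise ValueError(f"frame-count mismatch: {len(orig)} vs {len(comp)}")
    if (orig.height, orig.width) != (comp.height, comp.width):
        raise ValueError(
            f"dimension mismatch: {(orig.height, orig.width)} vs "
            f"{(comp.height, comp.width)}"
        )
    total_sse = 0.0
    total_n = 0
    for fo, fc in zip(orig.frames, comp.frames):
        sse, n = _squared_error(fo.values, fc.values, mask_invalid)
        total_sse += sse
        total_n += n
    if total_n == 0:
        raise ValueError("no valid pixels to compare (all masked)")
    mse = total_sse / total_n
    ratio = None
    if raw_bytes is not None and encoded_bytes is not None:
        from .codec import compression_ratio  # local import: avoid cycle

        ratio = compression_ratio(raw_bytes, encoded_bytes)
    return QualityReport(
        mse=mse,
        psnr_db=psnr(mse),
        compression_ratio=ratio,
        n_frames=len(orig),
        exact=(mse == 0.0),
    )
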