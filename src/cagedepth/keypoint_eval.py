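"""Keypoint-evaluation machinery: annotation transfer, splits, sigmas, OKS.

Pose annotation on colorized depth images is hard, so keypoints (nose,
left ear, right ear, tail base) are annotated on the simultaneously
recorded RGB stream and transferred to the depth stream through the fixed
spatial alignment between the two cameras (1920x1080 RGB onto 1280x720
depth, a uniform x2/3 scaling).

Detection accuracy is scored with object keypoint similarity (OKS):

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

where d_i is the Euclidean prediction-truth distance for keypoint i, v_i
the ground-truth visibility, s the object scale (square root of the
keypoint bounding-box area, floored at 1 px), and k_i a per-keypoint
falloff constant.  Rather than borrowing COCO's human-body constants, the
k_i are calibrated from a dually annotated image subset: for each bodypart
k_i is the sample standard deviation across frames of the inter-annotator
distance normalized by the object scale.

Also here: the dataset partitioning used for model development -- per coat
color, a fixed-size held-out test set (default 25 of 100) with the
remainder split into training and validation (default 95% / 5% of 75,
giving 71 / 4 with half-up rounding).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_scene import BODYPARTS

logger = logging.getLogger(__name__)

#: A keypoint record: bodypart -> (x, y, visible).
Record = dict[str, tuple[float, float, int]]

_CSV_COLUMNS = [
    "frame_id", "annotator_id", "bodypart", "x", "y", "coordinate_space", "visible",
]

#: Floor applied to degenerate falloff constants (identical annotators).
MIN_SIGMA = 1e-9


class AnnotationSet:
    """Keypoint annotations keyed by (frame_id, annotator_id, bodypart).

    Thin validated wrapper over a tidy table with columns ``frame_id,
    annotator_id, bodypart, x, y, coordinate_space, visible``.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _CSV_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        table = table[_CSV_COLUMNS].copy()
        dup = table.duplicated(
            subset=["frame_id", "annotator_id", "bodypart", "coordinate_space"]
        )
        if dup.any():
            raise ValueError(
                f"duplicate annotation records: {table[dup].head().to_dict('records')}"
            )
        bad_space = set(table["coordinate_space"]) - {"rgb", "depth"}
        if bad_space:
            raise ValueError(f"unknown coordinate_space values {sorted(bad_space)}")
        self.table = table

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def frame_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["frame_id"]))

    @property
    def annotators(self) -> list[str]:
        return sorted(set(self.table["annotator_id"]))

    def select(
        self,
        annotator_id: str | None = None,
        coordinate_space: str | None = None,
    ) -> "AnnotationSet":
        t = self.table
        if annotator_id is not None:
            t = t[t["annotator_id"] == annotator_id]
        if coordinate_space is not None:
            t = t[t["coordinate_space"] == coordinate_space]
        return AnnotationSet(t.reset_index(drop=True))

    def record(self, frame_id: str, annotator_id: str, coordinate_space: str = "depth") -> Record:
        """One (frame, annotator) record as ``{bodypart: (x, y, visible)}``."""
        t = self.table
        t = t[
            (t["frame_id"] == frame_id)
            & (t["annotator_id"] == annotator_id)
            & (t["coordinate_space"] == coordinate_space)
        ]
        return {
            row.bodypart: (float(row.x), float(row.y), int(row.visible))
            for row in t.itertuples()
        }


def _records_by_frame(
    ann: AnnotationSet, annotator_id: str, coordinate_space: str
) -> dict[str, Record]:
    """All of one annotator's records in one pass over the table."""
    t = ann.table
    t = t[(t["annotator_id"] == annotator_id) & (t["coordinate_space"] == coordinate_space)]
    out: dict[str, Record] = {}
    for row in t.itertuples():
        out.setdefault(row.frame_id, {})[row.bodypart] = (
            float(row.x), float(row.y), int(row.visible),
        )
    return out


# ---------------------------------------------------------------------------
# RGB -> depth annotation transfer
# ---------------------------------------------------------------------------

def rgb_to_depth(
    point: tuple[float, float],
    rgb_dims: tuple[int, int],
    depth_dims: tuple[int, int],
    aspect_rtol: float = 1e-6,
) -> tuple[float, float]:
    """Map an RGB-space point onto the depth frame by uniform scaling.

    The two frames must share their aspect ratio (for the real system
    1920x1080 -> 1280x720, a uniform x2/3); anisotropic dimension pairs are
    rejected because they would silently distort keypoint distances.
    """
    sx = depth_dims[0] / rgb_dims[0]
    sy = depth_dims[1] / rgb_dims[1]
    if not math.isclose(sx, sy, rel_tol=aspect_rtol):
        raise ValueError(
            f"aspect-ratio mismatch: {rgb_dims} vs {depth_dims} "
            f"(x scale {sx:.6g}, y scale {sy:.6g})"
        )
    return (point[0] * sx, point[1] * sy)


def transfer_annotations(
    ann: AnnotationSet, rgb_dims: tuple[int, int], depth_dims: tuple[int, int]
) -> AnnotationSet:
    """Re-express all RGB-space records in depth coordinates."""
    t = ann.select(coordinate_space="rgb").table.copy()
    xy = np.array([
        rgb_to_depth((x, y), rgb_dims, depth_dims)
        for x, y in zip(t["x"], t["y"])
    ])
    t["x"], t["y"] = xy[:, 0], xy[:, 1]
    t["coordinate_space"] = "depth"
    return AnnotationSet(t)


# ---------------------------------------------------------------------------
# Dataset partitioning
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DataSplit:
    """Per-color train/validation/test frame-id partition."""

    splits: dict[str, dict[str, list[str]]]

    def sizes(self) -> dict[str, dict[str, int]]:
        return {
            color: {part: len(ids) for part, ids in parts.items()}
            for color, parts in self.splits.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.splits, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSplit":
        return cls(json.loads(Path(path).read_text()))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def split_dataset(
    ids_by_color: Mapping[str, Sequence[str]],
    seed: int = 0,
    n_test: int = 25,
    val_frac: float = 0.05,
) -> DataSplit:
    """Randomly partition each color's frame ids into train/val/test.

    Defaults follow the development protocol: of 100 ids per color, 25 are
    held out for testing and the remaining 75 are split 95% training / 5%
    validation.  5% of 75 is 3.75 images, rounded half-up to 4, leaving 71
    for training.  The same seed always produces the same partition.
    """
    rng = np.random.default_rng(seed)
    splits: dict[str, dict[str, list[str]]] = {}
    for color, ids in ids_by_color.items():
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate frame ids for color {color!r}")
        if len(ids) <= n_test:
            raise ValueError(
                f"color {color!r} has {len(ids)} ids; need more than n_test={n_test}"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        test = sorted(perm[:n_test])
        rest = perm[n_test:]
        n_val = min(len(rest) - 1, max(0, _round_half_up(val_frac * len(rest))))
        val = sorted(rest[:n_val])
        train = sorted(rest[n_val:])
        splits[color] = {"train": train, "val": val, "test": test}
    return DataSplit(splits)


# ---------------------------------------------------------------------------
# Object scale and sigma estimation
# ---------------------------------------------------------------------------

def object_scale(record: Record) -> float:
    """Scale normalizer for OKS: sqrt of the visible-keypoint bounding box.

    Floored at 1 px so coincident keypoints cannot blow up the OKS kernel.
    Requires at least two visible keypoints.
    """
    pts = [(x, y) for x, y, v in record.values() if v > 0]
    if len(pts) < 2:
        raise ValueError(f"object_scale needs >= 2 visible keypoints, got {len(pts)}")
    xs, ys = zip(*pts)
    area = (max(xs) - min(xs)) * (max(ys) - min(ys))
    return max(1.0, math.sqrt(area))


@dataclasses.dataclass(frozen=True)
class SigmaSet:
    """Per-bodypart OKS falloff constants, calibrated from dual annotation."""

    k: dict[str, float]
    n_pairs_used: int

    def __post_init__(self) -> None:
        for part, val in self.k.items():
            if val <= 0:
                raise ValueError(f"sigma for {part!r} must be positive, got {val}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"k": self.k, "n_pairs_used": self.n_pairs_used}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SigmaSet":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], n_pairs_used=d["n_pairs_used"])


def estimate_sigmas(
    dual: AnnotationSet,
    annotators: tuple[str, str] | None = None,
    coordinate_space: str = "depth",
    bodyparts: Sequence[str] = BODYPARTS,
) -> SigmaSet:
    """Calibrate per-keypoint falloff constants from dual annotations.

    For each bodypart i, over every frame annotated by both annotators,
    k_i is the sample standard deviation (ddof=1) of d_i / s, where d_i is
    the inter-annotator distance and s the object scale of the first
    annotator's record.  Frames missing either annotation for a part are
    skipped for that part.  A part with identical annotations everywhere is
    degenerate; its k_i is floored at a tiny positive value and a warning
    is issued.
    """
    if annotators is None:
        found = [a for a in dual.annotators if a != "gt"]
        if len(found) != 2:
            raise ValueError(
                f"expected exactly two annotators, found {found}; pass `annotators`"
            )
        annotators = (found[0], found[1])
    a, b = annotators
    cols = ["frame_id", "bodypart", "x", "y", "visible"]
    t = dual.table[dual.table["coordinate_space"] == coordinate_space]
    ta = t[t["annotator_id"] == a][cols]
    tb = t[t["annotator_id"] == b][cols]

    # Object scale per frame from the first annotator's visible keypoints:
    # sqrt of the bounding-box area, floored at 1 px, >= 2 keypoints needed.
    vis_a = ta[ta["visible"] > 0]
    per_frame = vis_a.groupby("frame_id").agg(
        xmin=("x", "min"), xmax=("x", "max"),
        ymin=("y", "min"), ymax=("y", "max"), n=("x", "size"),
    )
    per_frame = per_frame[per_frame["n"] >= 2]
    scale = np.sqrt(
        (per_frame["xmax"] - per_frame["xmin"]) * (per_frame["ymax"] - per_frame["ymin"])
    ).clip(lower=1.0)

    pairs = ta.merge(tb, on=["frame_id", "bodypart"], suffixes=("_a", "_b"))
    pairs = pairs[(pairs["visible_a"] > 0) & (pairs["visible_b"] > 0)]
    pairs = pairs[pairs["frame_id"].isin(scale.index)]
    n_pairs = pairs["frame_id"].nunique()
    if n_pairs < 2:
        raise ValueError(f"need >= 2 dually annotated frames, found {n_pairs}")
    d = np.hypot(pairs["x_a"] - pairs["x_b"], pairs["y_a"] - pairs["y_b"])
    ratio = d / pairs["frame_id"].map(scale).to_numpy()

    k: dict[str, float] = {}
    grouped = ratio.groupby(pairs["bodypart"].to_numpy())
    for part in bodyparts:
        if part not in grouped.groups or len(grouped.get_group(part)) < 2:
            raise ValueError(f"no usable dual-annotation pairs for bodypart {part!r}")
        est = float(grouped.get_group(part).std(ddof=1))
        if est < MIN_SIGMA:
            warnings.warn(
                f"degenerate sigma for {part!r} (annotators agree exactly); "
                f"floored at {MIN_SIGMA}",
                stacklevel=2,
            )
            est = MIN_SIGMA
        k[part] = est
    return SigmaSet(k=k, n_pairs_used=n_pairs)


# ---------------------------------------------------------------------------
# OKS
# ---------------------------------------------------------------------------

def oks(pred: Record, truth: Record, sigmas: SigmaSet) -> float:
    """Object keypoint similarity between one prediction and its truth.

    Gaussian kernel per truth-visible keypoint, normalized by the truth
    object scale; predictions for invisible parts are ignored.  A visible
    truth keypoint with no prediction contributes 0 (a miss).
    """
    visible = [part for part, (_, _, v) in truth.items() if v > 0]
    if not visible:
        raise ValueError("OKS requires at least one visible truth keypoint")
    s = object_scale(truth) if len(visible) >= 2 else 1.0
    total = 0.0
    for part in visible:
        if part not in pred:
            continue
        px, py, _ = pred[part]
        tx, ty, _ = truth[part]
        d2 = (px - tx) ** 2 + (py - ty) ** 2
        ki = sigmas.k[part]
        total += math.exp(-d2 / (2.0 * s * s * ki * ki))
    return total / len(visible)


@dataclasses.dataclass(frozen=True)
class OksSummary:
    """Per-group and pooled mean OKS."""

    overall: float
    per_group: dict[str, float]
    n_pairs: int

    def rounded(self, ndigits: int = 3) -> dict:
        return {
            "overall": round(self.overall, ndigits),
            "per_group": {g: round(v, ndigits) for g, v in self.per_group.items()},
            "n_pairs": self.n_pairs,
        }


def mean_oks(
    pred: AnnotationSet,
    truth: AnnotationSet,
    sigmas: SigmaSet,
    groups: Mapping[str, str] | None = None,
    coordinate_space: str = "depth",
    pred_annotator: str | None = None,
    truth_annotator: str | None = None,
) -> OksSummary:
    """Mean OKS over all frames present in both sets, optionally grouped.

    ``groups`` maps frame_id to a group label (e.g. coat color); ungrouped
    frames fall into ``"ungrouped"``.  Groups that end up empty are omitted
    with a warning.  Means are reported raw; round for display with
    :meth:`OksSummary.rounded` (3 decimals by convention).
    """
    if pred_annotator is None:
        pred_annotator = pred.annotators[0]
    if truth_annotator is None:
        truth_annotator = truth.annotators[0]
    pred_records = _records_by_frame(pred, pred_annotator, coordinate_space)
    truth_records = _records_by_frame(truth, truth_annotator, coordinate_space)
    scores: dict[str, list[float]] = {}
    n = 0
    for frame_id in truth.frame_ids:
        t = truth_records.get(frame_id)
        p = pred_records.get(frame_id)
        if not t or not p:
            continue
        score = oks(p, t, sigmas)
        group = groups.get(frame_id, "ungrouped") if groups is not None else "all"
        scores.setdefault(group, []).append(score)
        n += 1
    if n == 0:
        raise ValueError("no overlapping frames between prediction and truth sets")
    if groups is not None:
        for group in set(groups.values()) - set(scores):
            warnings.warn(f"group {group!r} has no scored frames; omitted", stacklevel=2)
    per_group = {g: float(np.mean(v)) for g, v in sorted(scores.items())}
    overall = float(np.mean([s for v in scores.values() for s in v]))
    return OksSummary(overall=overall, per_group=per_group, n_pairs=n)
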