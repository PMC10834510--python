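"""Synthetic top-down home-cage depth scenes with ground-truth keypoints.

Real recordings from the target system are not publicly deposited, so the
codec and evaluation modules are exercised on a generator that emulates the
statistical structure of a top-down depth view of a singly housed mouse:

* a flat cage floor 298 mm below the camera (the camera's minimum working
  distance dictates the 29.8 cm mount height);
* static raised fixtures -- a food-hopper grate edge along the front of the
  view and a mezzanine block in one corner -- at fixed depth offsets;
* a mouse rendered as a smooth elongated elevation hump that performs a
  bounded random walk over the floor (closer to the camera means *smaller*
  depth values);
* i.i.d. Gaussian sensor noise, rounded to integer millimetres, plus
  zero-valued dropout pixels;
* per-frame ground-truth keypoints (nose, left ear, right ear, tail base)
  and a paired pseudo-RGB frame at exactly 1.5x the depth resolution
  (full scale 1920x1080 RGB vs 1280x720 depth).

Default dimensions are test-scale 320x240 depth / 480x360 RGB, preserving
the exact 1.5x ratio so the coordinate-transfer logic stays honest.  All
rendered samples lie in the aligned depth range [0, 4096] by construction.

The generator is a model of scene *structure*, not of any particular
sensor: noise level and dropout rate are declared defaults, not fitted
values, and the body hump is not an articulated mouse.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .depth_model import ALIGNED_MAX, DepthFrame, DepthSequence

BODYPARTS = ("nose", "left_ear", "right_ear", "tail_base")
COAT_COLORS = ("black", "white", "tan")

#: RGB resolution is exactly 1.5x the depth resolution on both axes.
RGB_SCALE = 1.5

#: Flat body shade per coat color (pseudo-RGB), against a ~120-gray floor.
_COAT_RGB = {
    "black": (45, 40, 38),
    "white": (230, 228, 225),
    "tan": (200, 160, 110),
}


@dataclasses.dataclass(frozen=True)
class CageScene:
    """Static scene geometry and sensor model.

    ``fixture_regions`` are ``((x0, y0, x1, y1), elevation_mm)`` pairs:
    axis-aligned boxes raised above the floor by a fixed height, so their
    depth reads ``camera_height_mm - elevation_mm``.
    """

    depth_dims: tuple[int, int] = (320, 240)  # (width, height)
    camera_height_mm: float = 298.0
    noise_sd: float = 2.0
    dropout_prob: float = 0.01
    # Walkable inset as a fraction of each axis; large enough that the body
    # (nose reaches 0.45 * body_length past the centroid) stays in frame.
    floor_margin: float = 0.15
    fixture_regions: tuple[tuple[tuple[float, float, float, float], float], ...] | None = None

    def __post_init__(self) -> None:
        w, h = self.depth_dims
        if w < 16 or h < 16:
            raise ValueError(f"depth_dims too small: {self.depth_dims}")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.camera_height_mm <= 0 or self.camera_height_mm > ALIGNED_MAX:
            raise ValueError("camera_height_mm must be in (0, 4096]")
        if self.fixture_regions is None:
            # Hopper grate edge along the top of the view; mezzanine block
            # in the lower-right corner.  Elevations in mm above the floor.
            object.__setattr__(
                self,
                "fixture_regions",
                (
                    ((0.0, 0.0, w, 0.08 * h), 60.0),
                    ((0.72 * w, 0.70 * h, w, h), 40.0),
                ),
            )

    @property
    def rgb_dims(self) -> tuple[int, int]:
        w, h = self.depth_dims
        rw, rh = w * RGB_SCALE, h * RGB_SCALE
        if rw != int(rw) or rh != int(rh):
            raise ValueError(
                f"depth_dims {self.depth_dims} do not scale to integer RGB dims"
            )
        return (int(rw), int(rh))

    @property
    def floor_region(self) -> tuple[float, float, float, float]:
        """Walkable rectangle ``(x0, y0, x1, y1)`` clear of fixtures."""
        w, h = self.depth_dims
        mx, my = self.floor_margin * w, self.floor_margin * h
        return (mx, 0.10 * h + my, w - mx, 0.70 * h - my)


@dataclasses.dataclass(frozen=True)
class MouseState:
    """Mouse pose at one instant, in depth-pixel coordinates.

    Body axes: ``heading`` points from tail to nose; body dimensions are in
    depth pixels (the test-scale scene uses ~1 px per mm).
    """

    centroid: tuple[float, float]
    heading: float
    body_length: float = 80.0
    body_width: float = 30.0
    body_height: float = 30.0
    coat_color: str = "black"

    def __post_init__(self) -> None:
        if self.coat_color not in _COAT_RGB:
            raise ValueError(f"coat_color must be one of {COAT_COLORS}")
        if min(self.body_length, self.body_width, self.body_height) <= 0:
            raise ValueError("body dimensions must be positive")

    @property
    def keypoints(self) -> dict[str, tuple[float, float]]:
        """Ground-truth keypoints derived from the pose (depth coords).

        Nose and tail base sit on opposite ends of the heading axis; the
        ears flank the head.  All four lie inside the rendered body mask.
        """
        cx, cy = self.centroid
        c, s = math.cos(self.heading), math.sin(self.heading)
        half = self.body_length / 2.0

        def at(u: float, v: float) -> tuple[float, float]:
            return (cx + u * c - v * s, cy + u * s + v * c)

        return {
            "nose": at(0.45 * self.body_length, 0.0),
            "left_ear": at(0.25 * self.body_length, -0.30 * self.body_width),
            "right_ear": at(0.25 * self.body_length, 0.30 * self.body_width),
            "tail_base": at(-0.45 * self.body_length, 0.0),
        }


def initial_state(
    scene: CageScene, coat_color: str = "black", rng: np.random.Generator | None = None
) -> MouseState:
    """Place a mouse at a random pose inside the walkable floor region."""
    rng = rng or np.random.default_rng()
    x0, y0, x1, y1 = scene.floor_region
    return MouseState(
        centroid=(float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1))),
        heading=float(rng.uniform(-math.pi, math.pi)),
        coat_color=coat_color,
    )


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a coordinate back into [lo, hi] (single bounce suffices for
    per-frame step sizes much smaller than the region)."""
    if value < lo:
        value = lo + (lo - value)
    if value > hi:
        value = hi - (value - hi)
    return min(max(value, lo), hi)


def step_mouse(
    state: MouseState,
    scene: CageScene,
    rng: np.random.Generator,
    turn_sd: float = 0.35,
    speed_sd: float = 4.0,
) -> MouseState:
    """Advance the bounded random walk by one frame.

    The heading receives wrapped-normal noise (sd ``turn_sd`` rad), the step
    length is half-normal (sd ``speed_sd`` px/frame), and the centroid is
    reflected at the floor-region boundary so the mouse never leaves the
    walkable floor.
    """
    heading = float(
        math.remainder(state.heading + rng.normal(0.0, turn_sd), 2.0 * math.pi)
    )
    speed = abs(float(rng.normal(0.0, speed_sd)))
    x = state.centroid[0] + speed * math.cos(heading)
    y = state.centroid[1] + speed * math.sin(heading)
    x0, y0, x1, y1 = scene.floor_region
    return dataclasses.replace(
        state,
        centroid=(_reflect(x, x0, x1), _reflect(y, y0, y1)),
        heading=heading,
    )


def _body_elevation(
    scene_dims: tuple[int, int], state: MouseState, scale: float = 1.0
) -> np.ndarray:
    """Smooth elongated Gaussian elevation hump (mm above floor).

    ``scale`` maps depth coordinates into the target grid (1.5 for RGB).
    """
    w, h = scene_dims
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = state.centroid[0] * scale, state.centroid[1] * scale
    c, s = math.cos(state.heading), math.sin(state.heading)
    dx, dy = xx - cx, yy - cy
    u = (dx * c + dy * s) / scale
    v = (-dx * s + dy * c) / scale
    su = 0.35 * state.body_length
    sv = 0.35 * state.body_width
    return state.body_height * np.exp(-0.5 * ((u / su) ** 2 + (v / sv) ** 2))


#: Elevation (mm) above which a pixel counts as mouse body.
BODY_MASK_THRESHOLD = 2.0


def body_mask(scene: CageScene, state: MouseState, scale: float = 1.0) -> np.ndarray:
    """Boolean body mask on the depth (scale=1) or RGB (scale=1.5) grid."""
    dims = scene.depth_dims if scale == 1.0 else scene.rgb_dims
    return _body_elevation(dims, state, scale) >= BODY_MASK_THRESHOLD


def render_depth(
    scene: CageScene,
    state: MouseState | None,
    rng: np.random.Generator,
    timestamp: float = 0.0,
    frame_index: int = 0,
) -> DepthFrame:
    """Render one 16-bit depth frame.

    Background pixels read ~``camera_height_mm``; the mouse and fixtures
    are closer to the camera, hence *smaller* depth.  Gaussian noise is
    added, rounded to integer mm, clamped to [1, 4096]; dropout pixels are
    then zeroed.  All samples respect the aligned range by construction.
    """
    w, h = scene.depth_dims
    depth = np.full((h, w), scene.camera_height_mm, dtype=np.float64)
    for (x0, y0, x1, y1), elev in scene.fixture_regions:
        depth[int(y0):int(math.ceil(y1)), int(x0):int(math.ceil(x1))] = (
            scene.camera_height_mm - elev
        )
    if state is not None:
        elev = _body_elevation(scene.depth_dims, state)
        body = elev >= BODY_MASK_THRESHOLD
        depth[body] = scene.camera_height_mm - elev[body]
    if scene.noise_sd > 0:
        depth += rng.normal(0.0, scene.noise_sd, size=depth.shape)
    values = np.clip(np.rint(depth), 1, ALIGNED_MAX).astype(np.uint16)
    if scene.dropout_prob > 0:
        values[rng.random(size=values.shape) < scene.dropout_prob] = 0
    return DepthFrame(values, timestamp=timestamp, frame_index=frame_index)


def render_rgb(
    scene: CageScene, state: MouseState | None, rng: np.random.Generator
) -> np.ndarray:
    """Render the paired pseudo-RGB frame at ``scene.rgb_dims``.

    Flat-shaded body with coat-color-dependent intensity over a textured
    gray background, geometrically consistent with the depth frame under
    the 1.5x coordinate mapping.  Returns ``(h, w, 3)`` uint8.
    """
    w, h = scene.rgb_dims
    base = 120.0 + 12.0 * rng.standard_normal((h // 4 + 1, w // 4 + 1))
    texture = np.repeat(np.repeat(base, 4, axis=0), 4, axis=1)[:h, :w]
    img = np.repeat(texture[:, :, None], 3, axis=2)
    for (x0, y0, x1, y1), _ in scene.fixture_regions:
        sx0, sy0 = int(x0 * RGB_SCALE), int(y0 * RGB_SCALE)
        sx1, sy1 = int(math.ceil(x1 * RGB_SCALE)), int(math.ceil(y1 * RGB_SCALE))
        img[sy0:sy1, sx0:sx1] = img[sy0:sy1, sx0:sx1] * 0.6 + 40.0
    if state is not None:
        mask = body_mask(scene, state, scale=RGB_SCALE)
        img[mask] = np.asarray(_COAT_RGB[state.coat_color], dtype=np.float64)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    """Frames plus annotation table from one generator run.

    ``annotations`` follows the package-wide CSV schema: ``frame_id,
    annotator_id, bodypart, x, y, coordinate_space, visible`` with ground
    truth under annotator id ``gt`` and (in dual mode) jittered annotators
    ``a1`` and ``a2``.
    """

    depth: dict[str, DepthSequence] | None
    rgb: dict[str, list[np.ndarray]] | None
    annotations: pd.DataFrame
    states: dict[str, list[MouseState]]


def _annotation_rows(
    frame_id: str, annotator: str, keypoints: dict[str, tuple[float, float]],
    space: str, scale: float,
) -> Iterable[dict]:
    for part, (x, y) in keypoints.items():
        yield {
            "frame_id": frame_id,
            "annotator_id": annotator,
            "bodypart": part,
            "x": x * scale,
            "y": y * scale,
            "coordinate_space": space,
            "visible": 1,
        }


def generate_dataset(
    n_frames_per_color: int = 100,
    colors: Sequence[str] = COAT_COLORS,
    seed: int = 0,
    scene: CageScene | None = None,
    frame_rate: float = 15.0,
    dual_annotator_jitter_sd: float | None = None,
    render: bool = True,
    render_rgb_frames: bool = False,
    stride: int = 10,
) -> SyntheticDataset:
    """Generate an annotated multi-mouse-color dataset.

    One independent trajectory per coat color; annotated frames are taken
    every ``stride`` walk steps so consecutive records show distinct
    postures (mirroring frame selection for posture variety).  Ground-truth
    keypoints are emitted in both depth and RGB coordinate spaces.  With
    ``dual_annotator_jitter_sd`` set, two synthetic annotators ``a1``/``a2``
    are added, each displacing every keypoint by independent isotropic
    Gaussian jitter of that sd (depth pixels).

    Identical seeds yield bit-identical datasets.
    """
    if n_frames_per_color < 1:
        raise ValueError("n_frames_per_color must be >= 1")
    scene = scene or CageScene()
    root = np.random.SeedSequence(seed)
    color_seeds = root.spawn(len(colors))
    depth: dict[str, DepthSequence] | None = {} if render else None
    rgb: dict[str, list[np.ndarray]] | None = {} if (render and render_rgb_frames) else None
    states: dict[str, list[MouseState]] = {}
    rows: list[dict] = []

    for color, cseed in zip(colors, color_seeds):
        walk_rng, sensor_rng, jitter_rng = (
            np.random.default_rng(s) for s in cseed.spawn(3)
        )
        state = initial_state(scene, coat_color=color, rng=walk_rng)
        frames: list[DepthFrame] = []
        rgb_frames: list[np.ndarray] = []
        states[color] = []
        for i in range(n_frames_per_color):
            for _ in range(stride):
                state = step_mouse(state, scene, walk_rng)
            states[color].append(state)
            frame_id = f"{color}_{i:04d}"
            kps = state.keypoints
            rows.extend(_annotation_rows(frame_id, "gt", kps, "depth", 1.0))
            rows.extend(_annotation_rows(frame_id, "gt", kps, "rgb", RGB_SCALE))
            if dual_annotator_jitter_sd is not None:
                for annotator in ("a1", "a2"):
                    jittered = {
                        part: (
                            x + jitter_rng.normal(0.0, dual_annotator_jitter_sd),
                            y + jitter_rng.normal(0.0, dual_annotator_jitter_sd),
                        )
                        for part, (x, y) in kps.items()
                    }
                    rows.extend(
                        _annotation_rows(frame_id, annotator, jittered, "depth", 1.0)
                    )
                    rows.extend(
                        _annotation_rows(frame_id, annotator, jittered, "rgb", RGB_SCALE)
                    )
            if render:
                frames.append(
                    render_depth(
                        scene, state, sensor_rng,
                        timestamp=i / frame_rate, frame_index=i,
                    )
                )
                if render_rgb_frames:
                    rgb_frames.append(render_rgb(scene, state, sensor_rng))
        if render:
            depth[color] = DepthSequence(
                frames, frame_rate=frame_rate, range_mode="aligned"
            )
            if render_rgb_frames:
                rgb[color] = rgb_frames

    annotations = pd.DataFrame(
        rows,
        columns=[
            "frame_id", "annotator_id", "bodypart", "x", "y",
            "coordinate_space", "visible",
        ],
    )
    return SyntheticDataset(depth=depth, rgb=rgb, annotations=annotations, states=states)


def simulate_sequence(
    n_frames: int,
    scene: CageScene | None = None,
    coat_color: str = "black",
    seed: int = 0,
    frame_rate: float = 15.0,
) -> DepthSequence:
    """Simulate one continuous depth recording (every walk step rendered)."""
    scene = scene or CageScene()
    root = np.random.SeedSequence(seed)
    walk_rng, sensor_rng = (np.random.default_rng(s) for s in root.spawn(2))
    state = initial_state(scene, coat_color=coat_color, rng=walk_rng)
    frames = []
    for i in range(n_frames):
        state = step_mouse(state, scene, walk_rng)
        frames.append(
            render_depth(scene, state, sensor_rng, timestamp=i / frame_rate, frame_index=i)
        )
    return DepthSequence(frames, frame_rate=frame_rate, range_mode="aligned")
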