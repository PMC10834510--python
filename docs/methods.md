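# Methods

This note records the models, parameter choices and numerical conventions
behind `cagedepth`, and what the synthetic test bed does and does not show
about real recordings.

## Depth model and conventions

Depth frames are unsigned 16-bit, nominally millimetres from the camera
(the physical unit is carried symbolically; nothing in the code depends on
it being mm). Sample value 0 is reserved for invalid pixels (sensor
dropout / no return). Pixel coordinates are 0-based, x rightward, y
downward; raw `.d16` dumps are little-endian, row-major from the top-left,
with a JSON header. Aligned-mode sequences (depth re-projected into the
RGB camera's coordinates) are restricted to [0, 4096]; out-of-range
samples are clamped to 4096 with a logged count rather than rejected,
since isolated sensor glitches should not abort a long recording.

## Codec

The contribution-bearing transform is exact byte-plane splitting:
`msb = v >> 8`, `lsb = v & 0xFF`, inverse `v = (msb << 8) | lsb`. Both
planes are encoded as independent 8-bit grayscale streams; the MSB stream
is always lossless, so reconstruction error is structurally confined to
the low byte (per-pixel |error| ≤ 255 at any setting, 0 with a lossless
LSB).

Two stream backends implement the same interface:

* **image** (default): every frame is independently coded — PNG for the
  lossless rung, JPEG for the lossy rungs — and stored length-prefixed in
  a small container file (`.seq`). This backend is pure Python (Pillow),
  deterministic, and used by the test suite. The JPEG quality ladder is
  `high=95, medium=80, low=50`, a conventional wide spread chosen up
  front; on the packaged fixture it yields monotonically increasing size
  and PSNR up the ladder, with the medium rung landing near 10× / 84 dB.
* **ffmpeg**: H.264 through an external `ffmpeg` binary — x264 `-qp 0`
  (grayscale) for lossless streams, CRF `high=10, medium=23, low=35` for
  lossy ones, `.mp4` files. Selected automatically when the binary is on
  PATH. Frames are piped as raw grayscale so no chroma plane can touch
  depth bits. Encoder nondeterminism across ffmpeg builds is tolerated on
  the lossy path only; every exactness guarantee lives on the
  lossless/MSB path, which is bit-exact by construction on both backends.

One caveat inherent to byte splitting: where the scene crosses a multiple
of 256 mm, the LSB plane wraps 255→0 and forms sharp artificial edges;
lossy LSB coding rings at those edges, which is why worst-case lossy error
(~100 depth units on the fixture) is far above the RMS error but still
bounded by 255.

Recordings are two stream files per clip plus one JSON sidecar (geometry,
settings, timestamps, experiment metadata, clip boundaries, byte counts).
Timestamps live in the sidecar, not in stream timing metadata, because
stream timebases are encoder-dependent. Clip segmentation partitions
`[0, n_frames)` into half-open ranges of at most `clip_duration` seconds
(`⌊duration·fps⌋` frames per clip, final clip possibly shorter); decoding
concatenates clips and is frame-for-frame identical to an unsegmented
decode.

## Quality metrics

MSE is computed in signed 64-bit arithmetic (differences reach ±65535).
PSNR uses the fixed peak 65535 regardless of range mode, so values are
comparable across aligned and full-range recordings; `PSNR(MSE=1)` =
20·log10(65535) ≈ 96.33 dB, and MSE = 0 is reported as an infinite
sentinel with `exact=true`. A sequence is scored by pooling squared error
over all pixels of all frames into one global MSE (the pixel-weighted mean
of per-frame MSEs), giving a single PSNR per recording; per-frame
averaging of PSNRs is deliberately not the default. Invalid (zero) pixels
are included by default — the literal metric definition — with a
`mask_invalid` option to exclude pixels that are zero in either frame.

## Synthetic scene generator

The generator emulates the *structure* of a top-down cage view so the
codec and evaluation stages can be exercised end-to-end:

* floor at `camera_height_mm = 298` (the camera sits 29.8 cm above the
  cage floor, set by its minimum working distance);
* static fixtures (hopper-grate strip, mezzanine block) raised 60 and
  40 mm above the floor;
* the mouse as an elongated Gaussian elevation hump (default length 80,
  width 30, height 30 in depth pixels; the test-scale scene is ~1 px/mm),
  not an articulated body — sufficient for codec statistics and keypoint
  geometry;
* keypoints placed analytically on the body axes (nose at +0.45 L along
  the heading, ears at +0.25 L, ±0.30 W, tail base at −0.45 L); they
  provably lie inside the rendered body mask;
* motion as a bounded random walk (heading noise sd 0.35 rad/frame,
  half-normal speed sd 4 px/frame, reflection at the walkable-floor
  boundary, which is inset far enough that keypoints stay in frame);
* sensor noise i.i.d. Gaussian, sd 2 mm — a typical RMS figure for
  short-range stereo depth at ~30 cm — rounded to integers and clamped to
  [1, 4096]; dropout zeroes each pixel independently with probability
  0.01. Both are declared defaults, not values fitted to any real sensor.
* paired pseudo-RGB at exactly 1.5× the depth resolution (default
  320×240 depth / 480×360 RGB; full scale 1280×720 / 1920×1080), with
  coat-color-dependent flat shading (black/white/tan) over a textured
  floor, geometrically consistent with depth under the ×1.5 mapping.

Annotator jitter (dual-annotation mode) is isotropic Gaussian per
keypoint, independent across annotators and keypoints, sd configurable.
Annotated dataset frames are taken every 10 walk steps so consecutive
records show distinct postures.

What passing tests therefore show: the codec's guarantees, the metric
closed forms, and the evaluation pipeline's correctness on data with
realistic value ranges, spatial smoothness, noise and dropout. What they
do not show: performance on real fur/bedding reflectance, real sensor
noise spectra, multi-animal occlusion, or any trained pose model's
accuracy.

## Keypoint evaluation choices

* **Annotation transfer** is uniform scaling (depth/RGB dimension ratio),
  rejected if the two aspect ratios differ — anisotropic scaling would
  silently distort distances. OKS is invariant under this transfer because
  a joint uniform rescaling of prediction and truth cancels through the
  object scale.
* **Object scale** is `sqrt(bounding-box area)` of the visible keypoints,
  floored at 1 px. Segment area (the usual choice when masks exist) is
  unavailable from keypoint-only annotations. The floor prevents division
  blow-ups for degenerate records; exact scale invariance consequently
  holds only above the floor.
* **Sigma calibration**: for each bodypart, `k` is the sample standard
  deviation (ddof = 1) across dually annotated frames of inter-annotator
  distance divided by the first annotator's object scale. Constants come
  from the dual annotations rather than generic human-body defaults —
  that is the point of collecting a dually annotated subset. A part on
  which the annotators agree exactly is degenerate; its `k` is floored at
  1e-9 with a warning rather than rejected.
* **OKS** uses the standard Gaussian kernel over truth-visible keypoints;
  predictions for invisible parts are ignored, and a visible truth
  keypoint with no prediction counts as a miss (contributes 0). With one
  visible keypoint the scale falls back to 1.
* **Partitioning**: per color, `n_test` ids (default 25) are held out
  uniformly at random; 5% of the remainder — 3.75 for 75 ids — is rounded
  half-up to 4 validation images, leaving 71 for training. Splits are
  deterministic in the seed.

The acceptance script's `mean_oks_annotator_vs_truth_test_set` is the mean
OKS of one synthetic jittered annotator against ground truth on the pooled
75-frame test split, scored with the calibrated sigmas. It is a
self-consistency number for the pipeline (annotator-level agreement under
the calibrated kernel), not a pose-model accuracy: no detector is trained
here, so model-dependent OKS levels reported for real systems are outside
what this package can or does reproduce. Likewise the compression
ratio/PSNR pairs reported by the script are properties of the synthetic
fixture under the image backend's pinned ladder, not of any particular
real recording or x264 configuration.

## Problem sizes and tolerances

Tests and the acceptance script use the test-scale scene: a 150-frame
(10 s, 15 fps) 320×240 fixture for codec round trips and ladder
measurements, 10,000 annotation-only frames for sigma recovery (estimate
agrees with an independent Monte-Carlo resimulation within 5%; observed
~2%), and 100 annotated frames per coat color for partition counts. The
exhaustive bit-plane check covers all 65,536 sample values. Floating-point
closed forms are asserted to 0.01 dB (PSNR) and 1e-9 (OKS half-life);
round-trip checks are exact equality.

## Known limitations

* The lossy-rung rate-control mapping (JPEG qualities / CRF values) is
  this package's parameterization of the quality ladder; operating points
  from other implementations are not reconstructions of it.
* Single mouse only; no infrared stream; no photorealism.
* The ffmpeg backend requires an external binary and is exercised only for
  argument construction and its unavailable-error contract in the test
  suite; its guarantees mirror the image backend's by construction
  (lossless MSB path).
* Scheduling gates whole pipeline runs against an injected clock; it does
  not start/stop a live camera (no capture hardware is modeled).
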