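"""Synthetic cage-scene generator: geometry, sensor model, determinism."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import cagedepth as cd
from cagedepth.synthetic_scene import (
    RGB_SCALE,
    body_mask,
    initial_state,
)


@pytest.fixture(scope="module")
def scene():
    return cd.CageScene()


@pytest.fixture(scope="module")
def state(scene):
    return initial_state(scene, coat_color="black", rng=np.random.default_rng(5))


class TestRenderDepth:
    def test_empty_noiseless_scene_is_flat_floor(self):
        scene = cd.CageScene(noise_sd=0.0, dropout_prob=0.0, fixture_regions=())
        frame = cd.render_depth(scene, None, np.random.default_rng(0))
        assert np.all(frame.values == 298)

    def test_mouse_is_closer_than_floor(self, scene, state):
        frame = cd.render_depth(scene, state, np.random.default_rng(0))
        nonzero = frame.values[frame.values > 0]
        assert nonzero.min() < scene.camera_height_mm - 20

    def test_fixtures_raised_above_floor(self, scene):
        quiet = cd.CageScene(noise_sd=0.0, dropout_prob=0.0)
        frame = cd.render_depth(quiet, None, np.random.default_rng(0))
        (x0, y0, x1, y1), elev = quiet.fixture_regions[0]
        assert np.all(frame.values[int(y0):int(y1), int(x0):int(x1)] == 298 - elev)

    def test_dropout_fraction_matches_probability(self):
        # ~10^6 pixels: binomial sd of the zero fraction is ~2.2e-4
        scene = cd.CageScene(depth_dims=(1200, 840), dropout_prob=0.05)
        frame = cd.render_depth(scene, None, np.random.default_rng(7))
        frac = np.mean(frame.values == 0)
        assert frac == pytest.approx(0.05, abs=0.002)

    def test_samples_respect_aligned_range(self, scene, state):
        frame = cd.render_depth(scene, state, np.random.default_rng(1))
        assert frame.values.max() <= cd.ALIGNED_MAX


class TestWalk:
    def test_degenerate_walk_is_stationary(self, scene, state):
        out = cd.step_mouse(state, scene, np.random.default_rng(0),
                            turn_sd=0.0, speed_sd=0.0)
        assert out.centroid == state.centroid
        assert out.heading == pytest.approx(state.heading)

    def test_fixed_seed_reproduces_trajectory(self, scene, state):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            s = state
            runs.append([(s := cd.step_mouse(s, scene, rng)).centroid
                         for _ in range(50)])
        assert runs[0] == runs[1]

    def test_long_walk_stays_in_floor_region(self, scene, state):
        rng = np.random.default_rng(9)
        x0, y0, x1, y1 = scene.floor_region
        s = state
        for _ in range(10_000):
            s = cd.step_mouse(s, scene, rng)
            assert x0 <= s.centroid[0] <= x1
            assert y0 <= s.centroid[1] <= y1


class TestKeypoints:
    def test_keypoints_inside_body_mask(self, scene, state):
        mask = body_mask(scene, state)
        for part, (x, y) in state.keypoints.items():
            assert 0 <= x < scene.depth_dims[0] and 0 <= y < scene.depth_dims[1]
            assert mask[int(round(y)), int(round(x))], part

    def test_nose_and_tail_on_opposite_ends(self, state):
        kps = state.keypoints
        cx, cy = state.centroid
        nose = np.array(kps["nose"]) - (cx, cy)
        tail = np.array(kps["tail_base"]) - (cx, cy)
        assert np.dot(nose, tail) < 0
        heading_vec = np.array([math.cos(state.heading), math.sin(state.heading)])
        assert np.dot(nose, heading_vec) > 0 > np.dot(tail, heading_vec)


class TestRgb:
    def test_rgb_dims_exactly_1p5x(self, scene):
        assert scene.rgb_dims == (480, 360)
        with pytest.raises(ValueError, match="integer RGB"):
            cd.CageScene(depth_dims=(321, 240)).rgb_dims

    def test_coat_shading_contract(self, scene, state):
        rng = np.random.default_rng(3)
        mask = body_mask(scene, state, scale=RGB_SCALE)
        means = {}
        for color in ("black", "white"):
            recolored = dataclasses.replace(state, coat_color=color)
            img = cd.render_rgb(scene, recolored, rng)
            means[color] = img[mask].mean()
        background = img[~mask].mean()
        assert means["black"] < background < means["white"]

    def test_same_seed_gives_identical_paired_frames(self, scene, state):
        frames = [
            (
                cd.render_depth(scene, state, np.random.default_rng(11)).values,
                cd.render_rgb(scene, state, np.random.default_rng(11)),
            )
            for _ in range(2)
        ]
        assert np.array_equal(frames[0][0], frames[1][0])
        assert np.array_equal(frames[0][1], frames[1][1])


class TestDataset:
    def test_counts_and_schema(self):
        ds = cd.generate_dataset(n_frames_per_color=5, seed=3, render=False)
        gt = ds.annotations.query("annotator_id == 'gt'")
        # 3 colors x 5 frames x 4 bodyparts x 2 coordinate spaces
        assert len(gt) == 3 * 5 * 4 * 2
        assert set(ds.annotations["bodypart"]) == set(cd.BODYPARTS)
        assert ds.annotations["frame_id"].nunique() == 15

    def test_rgb_coords_are_1p5x_depth_coords(self):
        ds = cd.generate_dataset(n_frames_per_color=3, seed=3, render=False)
        gt = ds.annotations.query("annotator_id == 'gt'")
        depth = gt.query("coordinate_space == 'depth'").set_index(
            ["frame_id", "bodypart"]
        )
        rgb = gt.query("coordinate_space == 'rgb'").set_index(["frame_id", "bodypart"])
        assert np.allclose(rgb["x"], depth["x"] * 1.5)
        assert np.allclose(rgb["y"], depth["y"] * 1.5)

    def test_zero_jitter_annotators_agree_exactly(self):
        ds = cd.generate_dataset(
            n_frames_per_color=4, seed=0, render=False, dual_annotator_jitter_sd=0.0
        )
        a1 = ds.annotations.query("annotator_id == 'a1'").reset_index(drop=True)
        a2 = ds.annotations.query("annotator_id == 'a2'").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            a1.drop(columns="annotator_id"), a2.drop(columns="annotator_id")
        )

    def test_jitter_distance_matches_rayleigh_mean(self):
        """Inter-annotator distance ~ Rayleigh(sd*sqrt(2)), mean sd*sqrt(pi)."""
        sd = 3.0
        ds = cd.generate_dataset(
            n_frames_per_color=1500, colors=("black",), seed=1,
            render=False, dual_annotator_jitter_sd=sd,
        )
        depth = ds.annotations.query("coordinate_space == 'depth'")
        a1 = depth.query("annotator_id == 'a1'").set_index(["frame_id", "bodypart"])
        a2 = depth.query("annotator_id == 'a2'").set_index(["frame_id", "bodypart"])
        d = np.hypot(a1["x"] - a2["x"], a1["y"] - a2["y"])
        expected = sd * math.sqrt(math.pi)
        assert d.mean() == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self):
        a = cd.generate_dataset(n_frames_per_color=3, seed=77)
        b = cd.generate_dataset(n_frames_per_color=3, seed=77)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)
        assert a.depth["black"].equals(b.depth["black"])
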