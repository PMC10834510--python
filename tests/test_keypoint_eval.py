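"""Annotation transfer, dataset partitioning, sigma calibration, and OKS."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cagedepth as cd
from cagedepth.keypoint_eval import MIN_SIGMA, AnnotationSet


def make_record(points, visible=None):
    visible = visible or {p: 1 for p in points}
    return {p: (x, y, visible[p]) for p, (x, y) in points.items()}


SQUARE = make_record(
    {"nose": (10.0, 10.0), "left_ear": (40.0, 10.0),
     "right_ear": (40.0, 22.0), "tail_base": (10.0, 22.0)}
)
UNIT_SIGMAS = cd.SigmaSet(k={p: 0.1 for p in cd.BODYPARTS}, n_pairs_used=10)


class TestRgbToDepth:
    @pytest.mark.parametrize(
        "point,expected",
        [((0, 0), (0, 0)), ((1920, 1080), (1280, 720)), ((960, 540), (640, 360))],
    )
    def test_full_scale_mapping(self, point, expected):
        out = cd.rgb_to_depth(point, (1920, 1080), (1280, 720))
        assert out == pytest.approx(expected)

    def test_aspect_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aspect"):
            cd.rgb_to_depth((1, 1), (1920, 1080), (1280, 640))

    def test_transfer_annotations_matches_depth_ground_truth(self):
        scene = cd.CageScene()
        ds = cd.generate_dataset(n_frames_per_color=3, seed=2, render=False,
                                 scene=scene)
        ann = AnnotationSet(ds.annotations)
        transferred = cd.transfer_annotations(ann, scene.rgb_dims, scene.depth_dims)
        depth_gt = ann.select(coordinate_space="depth").table
        merged = transferred.table.merge(
            depth_gt, on=["frame_id", "annotator_id", "bodypart"], suffixes=("_t", "")
        )
        assert np.abs(merged["x_t"] - merged["x"]).max() < 0.5
        assert np.abs(merged["y_t"] - merged["y"]).max() < 0.5


class TestSplitDataset:
    def test_default_partition_sizes(self):
        ids = {c: [f"{c}_{i:04d}" for i in range(100)] for c in cd.COAT_COLORS}
        split = cd.split_dataset(ids, seed=0)
        for color in cd.COAT_COLORS:
            sizes = split.sizes()[color]
            assert sizes == {"train": 71, "val": 4, "test": 25}
            parts = split.splits[color]
            union = set(parts["train"]) | set(parts["val"]) | set(parts["test"])
            assert union == set(ids[color])
            assert len(parts["train"]) + len(parts["val"]) + len(parts["test"]) == 100

    def test_determinism_and_seed_sensitivity(self):
        ids = {"black": [str(i) for i in range(100)]}
        assert cd.split_dataset(ids, seed=5).splits == cd.split_dataset(ids, seed=5).splits
        assert cd.split_dataset(ids, seed=5).splits != cd.split_dataset(ids, seed=6).splits

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cd.split_dataset({"black": ["a"] * 30}, seed=0)

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError, match="n_test"):
            cd.split_dataset({"black": [str(i) for i in range(20)]}, seed=0)


class TestObjectScale:
    def test_bounding_box_definition(self):
        rec = make_record({"nose": (0.0, 0.0), "tail_base": (30.0, 12.0)})
        assert cd.object_scale(rec) == pytest.approx(math.sqrt(360))

    def test_coincident_keypoints_floored_at_one(self):
        rec = make_record({"nose": (5.0, 5.0), "tail_base": (5.0, 5.0)})
        assert cd.object_scale(rec) == 1.0

    @given(st.floats(min_value=1.1, max_value=100.0))
    def test_homogeneity(self, c):
        base = cd.object_scale(SQUARE)
        scaled = {p: (x * c, y * c, v) for p, (x, y, v) in SQUARE.items()}
        assert cd.object_scale(scaled) == pytest.approx(c * base)

    def test_needs_two_visible(self):
        rec = make_record({"nose": (0.0, 0.0), "tail_base": (3.0, 4.0)},
                          visible={"nose": 1, "tail_base": 0})
        with pytest.raises(ValueError, match="visible"):
            cd.object_scale(rec)


def dual_annotations(n_frames, jitter_sd, seed=0):
    return cd.generate_dataset(
        n_frames_per_color=n_frames, colors=("black",), seed=seed,
        render=False, dual_annotator_jitter_sd=jitter_sd,
    )


class TestEstimateSigmas:
    def test_identical_annotators_flagged_degenerate(self):
        ds = dual_annotations(10, jitter_sd=0.0)
        ann = AnnotationSet(ds.annotations)
        with pytest.warns(UserWarning, match="degenerate"):
            ss = cd.estimate_sigmas(ann, annotators=("a1", "a2"))
        assert all(k == MIN_SIGMA for k in ss.k.values())

    def test_n_pairs_counts_dual_frames(self):
        ds = dual_annotations(200, jitter_sd=1.0)
        ss = cd.estimate_sigmas(AnnotationSet(ds.annotations), annotators=("a1", "a2"))
        assert ss.n_pairs_used == 200

    def test_recovery_against_monte_carlo_oracle(self):
        """Estimated k matches an independent resimulation of the same model."""
        sd = 2.0
        n = 3000
        ds = dual_annotations(n, jitter_sd=sd, seed=4)
        ann = AnnotationSet(ds.annotations)
        ss = cd.estimate_sigmas(ann, annotators=("a1", "a2"))

        # Oracle: fresh jitter draws over the same truth scales, same statistic.
        gt = ann.select(annotator_id="gt", coordinate_space="depth")
        scales = np.array([
            cd.object_scale(gt.record(fid, "gt")) for fid in gt.frame_ids
        ])
        rng = np.random.default_rng(999)
        diffs = rng.normal(0, sd, (len(scales), 2)) - rng.normal(0, sd, (len(scales), 2))
        d = np.hypot(diffs[:, 0], diffs[:, 1])
        k_oracle = float(np.std(d / scales, ddof=1))
        for part, k in ss.k.items():
            assert k == pytest.approx(k_oracle, rel=0.10), part

    def test_missing_part_rejected_by_name(self):
        ds = dual_annotations(10, jitter_sd=1.0)
        table = ds.annotations.query("bodypart != 'nose' or annotator_id == 'gt'")
        with pytest.raises(ValueError, match="nose"):
            cd.estimate_sigmas(AnnotationSet(table), annotators=("a1", "a2"))


class TestOks:
    def test_perfect_prediction_scores_one(self):
        assert cd.oks(SQUARE, SQUARE, UNIT_SIGMAS) == pytest.approx(1.0)

    def test_half_life_distance_scores_half(self):
        """A single visible keypoint displaced by s*k*sqrt(2 ln 2) scores 0.5."""
        truth = make_record(
            {"nose": (10.0, 10.0), "tail_base": (40.0, 30.0)},
            visible={"nose": 1, "tail_base": 0},
        )
        s = 1.0  # only one visible keypoint -> scale falls back to 1
        k = UNIT_SIGMAS.k["nose"]
        d = s * k * math.sqrt(2 * math.log(2))
        pred = make_record({"nose": (10.0 + d, 10.0), "tail_base": (40.0, 30.0)})
        assert cd.oks(pred, truth, UNIT_SIGMAS) == pytest.approx(0.5, abs=1e-9)

    def test_distant_prediction_scores_near_zero(self):
        pred = {p: (x + 1e4, y + 1e4, v) for p, (x, y, v) in SQUARE.items()}
        assert cd.oks(pred, SQUARE, UNIT_SIGMAS) < 1e-12

    def test_strictly_decreasing_in_distance(self):
        scores = []
        for d in np.linspace(0, 30, 10):
            pred = {p: (x + d, y, v) for p, (x, y, v) in SQUARE.items()}
            scores.append(cd.oks(pred, SQUARE, UNIT_SIGMAS))
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_zero_visible_rejected(self):
        truth = {p: (x, y, 0) for p, (x, y, _) in SQUARE.items()}
        with pytest.raises(ValueError, match="visible"):
            cd.oks(SQUARE, truth, UNIT_SIGMAS)

    def test_missing_prediction_counts_as_miss(self):
        pred = {p: v for p, v in SQUARE.items() if p != "nose"}
        score = cd.oks(pred, SQUARE, UNIT_SIGMAS)
        assert score == pytest.approx(3 / 4)

    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(0, 2**32 - 1))
    def test_scale_invariance(self, c, seed):
        """Jointly rescaling prediction and truth leaves OKS unchanged.

        Holds whenever the object scale stays above its 1 px degeneracy
        floor (SQUARE's bbox gives s ~ 19, so c >= 0.1 keeps s >= 1).
        """
        rng = np.random.default_rng(seed)
        truth = {p: (x, y, v) for (p, (x, y, v)) in SQUARE.items()}
        pred = {
            p: (x + rng.normal(0, 3), y + rng.normal(0, 3), v)
            for p, (x, y, v) in SQUARE.items()
        }
        base = cd.oks(pred, truth, UNIT_SIGMAS)
        scaled = cd.oks(
            {p: (x * c, y * c, v) for p, (x, y, v) in pred.items()},
            {p: (x * c, y * c, v) for p, (x, y, v) in truth.items()},
            UNIT_SIGMAS,
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_rgb_vs_transferred_depth_scores_identical(self):
        """OKS computed in RGB space equals OKS after x2/3 transfer of both."""
        rng = np.random.default_rng(8)
        truth_rgb = {p: (x * 6, y * 6, v) for p, (x, y, v) in SQUARE.items()}
        pred_rgb = {
            p: (x + rng.normal(0, 5), y + rng.normal(0, 5), v)
            for p, (x, y, v) in truth_rgb.items()
        }
        to_depth = lambda r: {
            p: (*cd.rgb_to_depth((x, y), (1920, 1080), (1280, 720)), v)
            for p, (x, y, v) in r.items()
        }
        assert cd.oks(pred_rgb, truth_rgb, UNIT_SIGMAS) == pytest.approx(
            cd.oks(to_depth(pred_rgb), to_depth(truth_rgb), UNIT_SIGMAS), rel=1e-12
        )


class TestMeanOks:
    def _sets(self, jitter_sd):
        ds = cd.generate_dataset(
            n_frames_per_color=5, seed=6, render=False,
            dual_annotator_jitter_sd=jitter_sd,
        )
        ann = AnnotationSet(ds.annotations)
        return ann.select(annotator_id="a1"), ann.select(annotator_id="gt")

    def test_perfect_predictions_score_one_everywhere(self):
        pred, truth = self._sets(jitter_sd=0.0)
        groups = {fid: fid.rsplit("_", 1)[0] for fid in truth.frame_ids}
        summary = cd.mean_oks(pred, truth, UNIT_SIGMAS, groups=groups)
        assert summary.overall == pytest.approx(1.0)
        assert set(summary.per_group) == set(cd.COAT_COLORS)
        assert all(v == pytest.approx(1.0) for v in summary.per_group.values())

    def test_pooled_mean_is_mean_of_equal_sized_groups(self):
        pred, truth = self._sets(jitter_sd=2.0)
        groups = {fid: fid.rsplit("_", 1)[0] for fid in truth.frame_ids}
        summary = cd.mean_oks(pred, truth, UNIT_SIGMAS, groups=groups)
        assert summary.overall == pytest.approx(
            np.mean(list(summary.per_group.values()))
        )
        assert summary.n_pairs == 15

    def test_empty_group_warned_and_omitted(self):
        pred, truth = self._sets(jitter_sd=1.0)
        groups = {fid: fid.rsplit("_", 1)[0] for fid in truth.frame_ids}
        groups["missing_frame"] = "agouti"
        with pytest.warns(UserWarning, match="agouti"):
            summary = cd.mean_oks(pred, truth, UNIT_SIGMAS, groups=groups)
        assert "agouti" not in summary.per_group

    def test_no_overlap_rejected(self):
        pred, truth = self._sets(jitter_sd=1.0)
        renamed = AnnotationSet(
            pred.table.assign(frame_id=pred.table["frame_id"] + "_x")
        )
        with pytest.raises(ValueError, match="overlap"):
            cd.mean_oks(renamed, truth, UNIT_SIGMAS)
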