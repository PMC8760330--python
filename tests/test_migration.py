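"""Cell tracking, speed/straightness, inclusion filter and series coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forcekit import (
    CellTrack,
    SubstrateModel,
    SyntheticCell,
    SyntheticScene,
    derivative_correlation,
    free_movement_filter,
    make_migration_scene,
    mean_speed,
    normalise_to_mean,
    render_displacement_map,
    render_mask,
    straightness,
    track_cells,
    volume_series,
)


def track_from(points, frame_interval_s=300.0, contact=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return CellTrack(
        cell_id=1,
        frames=np.arange(n),
        centroids_um=points,
        areas_um2=np.full(n, 100.0),
        labels=np.ones(n, int),
        contact=np.zeros(n, bool) if contact is None else np.asarray(contact, bool),
        frame_interval_s=frame_interval_s,
    )


def disk_mask_stack(centers, radius=6, shape=(64, 64)):
    """Label stacks from circle centres: one frame per list of (x, y, label)."""
    x = (np.arange(shape[1]) + 0.5)
    y = (np.arange(shape[0]) + 0.5)
    X, Y = np.meshgrid(x, y)
    stack = []
    for frame in centers:
        m = np.zeros(shape, np.uint16)
        for cx, cy, label in frame:
            m[np.hypot(X - cx, Y - cy) <= radius] = label
        stack.append(m)
    return np.stack(stack)


class TestTrackCells:
    def test_stationary_cell_single_track_zero_displacement(self):
        stack = disk_mask_stack([[(20.0, 20.0, 1)]] * 10)
        tracks = track_cells(stack, 1.0, 300.0)
        assert len(tracks) == 1
        t = tracks[0]
        assert len(t) == 10
        assert mean_speed(t) == 0.0

    def test_straight_mover_recovered(self):
        centers = [[(10.0 + i, 20.0, 1)] for i in range(15)]
        stack = disk_mask_stack(centers)
        t = track_cells(stack, 1.0, 300.0)[0]
        steps = np.diff(t.centroids_um, axis=0)
        np.testing.assert_allclose(steps[:, 0], 1.0, atol=0.5)  # 0.5 px/frame
        np.testing.assert_allclose(t.centroids_um[:, 0], 10.0 + np.arange(15), atol=0.5)

    def test_two_passing_cells_no_identity_swap(self):
        # cells approach to 14 um (> max_step 3) and pass by
        centers = [
            [(20.0, 20.0 + i, 1), (50.0, 50.0 - i, 2)] for i in range(12)
        ]
        stack = disk_mask_stack(centers, radius=5)
        tracks = track_cells(stack, 1.0, 300.0, max_step_um=3.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert (tr.labels == tr.labels[0]).all()

    def test_contact_flags_set_on_adjacency(self):
        apart = [[(15.0, 20.0, 1), (45.0, 20.0, 2)]]
        touching = [[(25.0, 20.0, 1), (35.0, 20.0, 2)]]  # masks adjacent
        tracks = track_cells(disk_mask_stack(apart + touching, radius=5), 1.0, 300.0)
        for tr in tracks:
            assert not tr.contact[0]
            assert tr.contact[1]

    def test_simulated_scene_speed_and_straightness_recovery(self):
        sub = SubstrateModel(pixel_size_um=1.0)
        scene = make_migration_scene(n_cells=1, field_um=150, n_frames=25, seed=4)
        masks = np.stack([render_mask(scene, sub, f) for f in range(25)])
        t = track_cells(masks, 1.0, 300.0)[0]
        gt = scene.cells[0].trajectory_um
        gt_steps = np.linalg.norm(np.diff(gt, axis=0), axis=1)
        gt_speed = gt_steps.sum() / (24 * 5.0)
        gt_straight = np.linalg.norm(gt[-1] - gt[0]) / gt_steps.sum()
        assert mean_speed(t) == pytest.approx(gt_speed, rel=0.05)
        assert straightness(t) == pytest.approx(gt_straight, abs=0.02)


class TestSpeedAndStraightness:
    def test_one_um_per_5min_frame(self):
        t = track_from([[0, 0], [1, 0], [2, 0]], frame_interval_s=300.0)
        assert mean_speed(t) == pytest.approx(0.2, rel=1e-12)

    def test_stationary_zero(self):
        t = track_from([[3, 3]] * 5)
        assert mean_speed(t) == 0.0

    def test_random_walk_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        t = track_from(pts, frame_interval_s=120.0)
        brute = sum(
            math.hypot(*(pts[i + 1] - pts[i])) for i in range(49)
        ) / (49 * 2.0)
        assert mean_speed(t) == pytest.approx(brute, rel=1e-12)

    def test_single_frame_track_errors(self):
        with pytest.raises(ValueError):
            mean_speed(track_from([[0, 0]]))
        with pytest.raises(ValueError):
            straightness(track_from([[0, 0]]))

    def test_straight_path_is_one(self):
        t = track_from([[0, 0], [1, 1], [2, 2], [5, 5]])
        assert straightness(t) == pytest.approx(1.0, rel=1e-12)

    def test_closed_path_is_zero(self):
        t = track_from([[0, 0], [1, 0], [1, 1], [0, 0]])
        assert straightness(t) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_legs_closed_form(self):
        t = track_from([[0, 0], [10, 0], [10, 10]])
        assert straightness(t) == pytest.approx(math.sqrt(2) / 2, rel=1e-12)

    def test_zero_path_length_reported_missing(self):
        assert math.isnan(straightness(track_from([[1, 1], [1, 1]])))

    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=20,
        ),
        st.floats(-np.pi, np.pi),
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_straightness_bounded_and_speed_rigid_motion_invariant(
        self, pts, angle, shift
    ):
        t = track_from(pts)
        s = straightness(t)
        assert math.isnan(s) or 0.0 <= s <= 1.0 + 1e-9
        rot = np.array(
            [
                [math.cos(angle), -math.sin(angle)],
                [math.sin(angle), math.cos(angle)],
            ]
        )
        moved = track_from(np.asarray(pts, float) @ rot.T + np.asarray(shift))
        assert mean_speed(moved) == pytest.approx(mean_speed(t), abs=1e-7)


class TestFreeMovementFilter:
    def _track_with_contact(self, contact, frame_interval_s=300.0):
        n = len(contact)
        pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        return track_from(pts, frame_interval_s=frame_interval_s, contact=contact)

    def test_three_hours_free_included(self):
        t = self._track_with_contact([False] * 37)  # 36 x 5 min = 3 h
        assert len(free_movement_filter([t], 2.0)) == 1

    def test_always_in_contact_excluded(self):
        t = self._track_with_contact([True] * 37)
        assert free_movement_filter([t], 2.0) == []

    def test_threshold_boundary_90min_window(self):
        contact = [False] * 19 + [True] * 10  # free span (19-1) x 5 min = 1.5 h
        t = self._track_with_contact(contact)
        assert free_movement_filter([t], 2.0) == []
        kept = free_movement_filter([t], 1.0)
        assert len(kept) == 1
        assert len(kept[0]) == 19  # cropped to the free window

    def test_summary_computed_on_free_window_only(self):
        contact = [True] * 5 + [False] * 25 + [True] * 5
        t = self._track_with_contact(contact)
        kept = free_movement_filter([t], 2.0)[0]
        assert kept.frames[0] == 5 and kept.frames[-1] == 29


class TestVolumeSeries:
    def test_delegates_to_indented_volume_per_frame(self):
        sub = SubstrateModel(pixel_size_um=1.0)
        scene = make_migration_scene(
            n_cells=1, field_um=100, n_frames=4, seed=1, noise_sd_nm=0.0,
            body_radius_um=15.0,
        )
        maps = [render_displacement_map(scene, sub, f) for f in range(4)]
        masks = np.stack([render_mask(scene, sub, f) for f in range(4)])
        t = track_cells(masks, 1.0, 300.0)[0]
        vols = volume_series(t, maps, masks)
        assert len(vols) == 4
        from forcekit import indented_volume

        for i in range(4):
            mask = masks[i] == t.labels[i]
            assert vols[i] == pytest.approx(
                indented_volume(maps[i], mask, 20.0), rel=1e-12
            )
        assert (vols > 0).all()

    def test_frame_mismatch_errors(self):
        t = track_from(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="stack"):
            volume_series(t, [], np.zeros((2, 4, 4), np.uint16))


class TestDerivativeCorrelation:
    def test_perfect_anticorrelation(self):
        s = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert derivative_correlation(s, -s) == pytest.approx(-1.0, rel=1e-12)

    def test_perfect_correlation(self):
        s = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert derivative_correlation(s, s) == pytest.approx(1.0, rel=1e-12)

    def test_constant_difference_is_missing(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])  # constant first difference
        r = derivative_correlation(s, np.array([1.0, 3.0, 2.0, 5.0]))
        assert math.isnan(r)

    def test_independent_series_mean_near_zero(self):
        # Monte-Carlo oracle: under independence the expected correlation
        # of the differenced series is 0
        rng = np.random.default_rng(123)
        rs = [
            derivative_correlation(rng.normal(size=200), rng.normal(size=200))
            for _ in range(1000)
        ]
        assert abs(np.mean(rs)) < 0.02


class TestNormaliseToMean:
    def test_constant_series_all_ones(self):
        np.testing.assert_allclose(normalise_to_mean(np.full(7, 3.5)), 1.0)

    def test_scale_invariance(self):
        s = np.array([1.0, 2.0, 5.0, 4.0])
        np.testing.assert_allclose(
            normalise_to_mean(s), normalise_to_mean(7.3 * s), rtol=1e-12
        )

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(1, 10, size=31)
        assert normalise_to_mean(s).mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalise_to_mean(np.array([1.0, -1.0]))
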