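"""Kalman prediction, Hungarian association and multi-slice tracking."""

import itertools

import numpy as np
import pytest

from rootcrown3d.cross_section import label_components
from rootcrown3d.synthetic import generate_slice_fixture
from rootcrown3d.tracking import (RootTrack, TrackingParams, associate,
                                  kalman_predict, track_stack)
from tests.conftest import make_component


def _feed_track(positions, q=0.0, r=1e-9):
    params = TrackingParams(process_noise=q, measurement_noise=r)
    from rootcrown3d.tracking import KalmanState

    t = RootTrack(track_id=0,
                  kalman=KalmanState.from_measurement(positions[0], params))
    t.detections.append((0, make_component(*positions[0])))
    for i, p in enumerate(positions[1:], start=1):
        t.kalman.advance(params.process_noise)
        t.kalman.update(p, params.measurement_noise)
        t.detections.append((i, make_component(*p)))
    return t, params


class TestKalman:
    def test_stationary_prediction(self):
        t, params = _feed_track([(10.0, 20.0)] * 5)
        pred = kalman_predict(t, params)
        assert np.allclose(pred, (10.0, 20.0), atol=1e-6)

    def test_linear_motion(self):
        pts = [(10.0 + 3.0 * i, 5.0) for i in range(8)]
        t, params = _feed_track(pts)
        pred = kalman_predict(t, params)
        assert abs(pred[0] - (pts[-1][0] + 3.0)) < 1e-3
        assert abs(pred[1] - 5.0) < 1e-3

    def test_quadratic_motion_exact_after_burn_in(self):
        # constant-acceleration model represents x(i) = i^2 exactly
        pts = [(float(i * i), 0.0) for i in range(12)]
        t, params = _feed_track(pts)
        pred = kalman_predict(t, params)
        assert abs(pred[0] - 12.0 ** 2) < 1e-2


class TestAssociate:
    def test_permutation_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (6, 2))
        perm = rng.permutation(6)
        matches, up, ud = associate(pts, pts[perm], gate=50.0)
        assert up == [] and ud == []
        for ti, di in matches:
            assert perm[di] == ti

    def test_diagonal_assignment(self):
        preds = np.array([[0.0, 0.0], [10.0, 0.0]])
        dets = np.array([[1.0, 0.0], [11.0, 0.0]])
        matches, _, _ = associate(preds, dets, gate=5.0)
        assert sorted(matches) == [(0, 0), (1, 1)]

    def test_gate_severs_far_pairs(self):
        matches, up, ud = associate(np.array([[0.0, 0.0]]),
                                    np.array([[100.0, 0.0]]), gate=20.0)
        assert matches == [] and up == [0] and ud == [0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        preds = rng.uniform(0, 50, (n, 2))
        dets = rng.uniform(0, 50, (n, 2))
        cost = np.linalg.norm(preds[:, None] - dets[None, :], axis=2)
        best = min(sum(cost[i, p[i]] for i in range(n))
                   for p in itertools.permutations(range(n)))
        matches, _, _ = associate(preds, dets, gate=1e6)
        total = sum(cost[i, j] for i, j in matches)
        assert abs(total - best) < 1e-9


def _stack_components(stack, pixel_mm=1.0):
    return [label_components(img, i, pixel_mm) for i, img in enumerate(stack)]


class TestTrackStack:
    def test_drifting_disks_two_full_tracks(self):
        fix = generate_slice_fixture("drifting_disks", {"n_frames": 50})
        slices = _stack_components(fix["stack"])
        tracks = [t for t in track_stack(slices) if len(t) >= 5]
        assert len(tracks) == 2
        assert all(len(t) == 50 for t in tracks)

    def test_crossing_disks_identity_preserved(self):
        fix = generate_slice_fixture("crossing_disks", {"n_frames": 40})
        slices = _stack_components(fix["stack"])
        tracks = [t for t in track_stack(slices) if len(t) >= 5]
        assert len(tracks) == 2
        traj = fix["trajectories"]
        for t in tracks:
            start_y = t.detections[0][1].centroid[1]
            end_y = t.detections[-1][1].centroid[1]
            # identify which ground-truth disk the track started as
            disk = int(np.argmin(np.abs(traj[0, :, 1] - start_y)))
            expected_end = traj[len(fix["stack"]) - 1, disk, 1]
            assert abs(end_y - expected_end) < 6.0

    @pytest.mark.parametrize("gap,expected_tracks", [(4, 1), (5, 2)])
    def test_gap_bridging_boundary(self, gap, expected_tracks):
        # disk missing for max_skip slices bridges; max_skip+1 splits
        shape = (64, 64)
        frames = []
        for i in range(30):
            img = np.zeros(shape, bool)
            if not (12 <= i < 12 + gap):
                yy, xx = np.mgrid[:shape[0], :shape[1]]
                img = (xx - (10 + i)) ** 2 + (yy - 32) ** 2 <= 36
            frames.append(img)
        slices = _stack_components(np.array(frames))
        tracks = [t for t in track_stack(slices) if len(t) >= 5]
        assert len(tracks) == expected_tracks

    def test_every_component_in_at_most_one_track(self):
        fix = generate_slice_fixture("drifting_disks", {"n_frames": 20})
        slices = _stack_components(fix["stack"])
        tracks = track_stack(slices)
        seen = set()
        for t in tracks:
            for s, comp in t.detections:
                key = (s, comp.label, comp.centroid)
                assert key not in seen
                seen.add(key)

    def test_depth_ordered_detections(self):
        fix = generate_slice_fixture("crossing_disks", {"n_frames": 25})
        tracks = track_stack(_stack_components(fix["stack"]))
        for t in tracks:
            idx = t.slice_indices
            assert (np.diff(idx) > 0).all()
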