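"""Structure-graph assembly: curvature, trace connection, stem, whorls."""

import numpy as np
import pytest

from rootcrown3d.structure import (StructureError, StructureParams, Whorl,
                                   connect_traces, cumulative_nodal_area,
                                   detect_stem, detect_whorls, track_curvature)
from rootcrown3d.levelset import LevelSetStack
from tests.conftest import make_track


class TestTrackCurvature:
    def test_straight_line_zero(self):
        pts = np.column_stack([np.linspace(0, 50, 20), np.zeros(20), np.zeros(20)])
        assert np.allclose(track_curvature(pts), 0.0)

    def test_circle_curvature(self):
        theta = np.linspace(0, np.pi, 40)
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta),
                               np.zeros(40)])
        curv = track_curvature(pts)
        assert np.allclose(curv, 0.02, rtol=0.05)

    def test_helix_curvature(self):
        r, c = 30.0, 8.0
        t = np.linspace(0, 4 * np.pi, 120)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
        curv = track_curvature(pts)
        expected = r / (r * r + c * c)
        assert np.allclose(np.median(curv), expected, rtol=0.05)

    def test_too_short_empty(self):
        assert track_curvature(np.zeros((2, 3))).size == 0


def _track_from_mm(track_id, points_mm, pixel_mm=0.5, thickness=1.0):
    """Build a track whose polyline_mm reproduces the given 3D points."""
    slices = np.round(points_mm[:, 2] / thickness).astype(int)
    px = points_mm[:, 0] / pixel_mm - 0.5
    py = points_mm[:, 1] / pixel_mm - 0.5
    t = make_track(track_id, list(zip(px, py)), start_slice=int(slices[0]))
    # fix slice indices to match depths exactly
    t.detections = [(int(s), c) for s, (_, c) in zip(slices, t.detections)]
    return t


class TestConnectTraces:
    params = StructureParams()

    def test_split_arc_merges(self):
        # gently curved depth-monotone root split with a ~3 mm gap
        z = np.arange(0.0, 60.0, 1.0)
        arc = np.column_stack([0.004 * z ** 2, np.zeros(len(z)), z])
        a = _track_from_mm(0, arc[:29])
        b = _track_from_mm(1, arc[32:])
        merged = connect_traces([a, b], self.params, 0.5, 1.0)
        assert len(merged) == 1

    def test_perpendicular_segments_not_merged(self):
        a_pts = np.column_stack([np.zeros(20), np.zeros(20),
                                 np.linspace(0, 19, 20)])
        b_pts = np.column_stack([np.linspace(3, 22, 20), np.zeros(20),
                                 np.full(20, 22.0)])
        a = _track_from_mm(0, a_pts)
        b = _track_from_mm(1, b_pts)
        b.detections = [(s + 3, c) for s, c in b.detections]  # below a, gap 3mm
        merged = connect_traces([a, b], self.params, 0.5, 1.0)
        assert len(merged) == 2

    def test_distant_segments_not_merged(self):
        a = _track_from_mm(0, np.column_stack(
            [np.zeros(10), np.zeros(10), np.arange(10.0)]))
        b = _track_from_mm(1, np.column_stack(
            [np.full(10, 50.0), np.zeros(10), np.arange(60.0, 70.0)]))
        merged = connect_traces([a, b], self.params, 0.5, 1.0)
        assert len(merged) == 2

    def test_never_increases_track_count(self):
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(5):
            pts = np.column_stack([rng.uniform(0, 80, 12), rng.uniform(0, 80, 12),
                                   np.sort(rng.uniform(0, 60, 12))])
            tracks.append(_track_from_mm(i, pts))
        merged = connect_traces(tracks, self.params, 0.5, 1.0)
        assert len(merged) <= 5


def _stack(n_slices=100, thickness=1.0, pixel_mm=0.5):
    return LevelSetStack(images=np.zeros((n_slices, 8, 8), np.uint8),
                         thickness=thickness, pixel_mm=pixel_mm)


class TestDetectStem:
    def test_synthetic_crown_stem_diameter(self, default_result, default_crown):
        _, gt = default_crown
        g = default_result.graph
        assert abs(g.stem_diameter - gt.stem_diameter) <= 2 * g.pixel_mm

    def test_no_track_in_top_window_errors(self):
        t = make_track(0, [(10, 10)] * 30, start_slice=50)
        with pytest.raises(StructureError):
            detect_stem([t], _stack())

    def test_largest_median_area_wins(self):
        big = make_track(0, [(10, 10)] * 30, areas=[400.0] * 30)
        small = make_track(1, [(30, 30)] * 30, areas=[30.0] * 30)
        stem, _ = detect_stem([big, small], _stack())
        assert stem.track_id == 0


class TestWhorlDetection:
    def test_two_step_staircase(self):
        stack = _stack(60)
        nodal = []
        tid = 0
        for depth, n_roots in ((10, 6), (25, 6)):
            for k in range(n_roots):
                nodal.append(make_track(tid, [(10 + 5 * k, 10 + 5 * k)] * 20,
                                        start_slice=depth))
                tid += 1
        curve = cumulative_nodal_area(nodal, stack)
        steps = np.diff(np.concatenate([[0.0], curve]))
        rises = np.nonzero(steps > 0)[0]
        assert set(rises) == {10, 25}
        # equal whorls give equal step heights
        assert np.isclose(steps[10], steps[25], rtol=0.10)
        whorls = detect_whorls(curve, nodal, stack)
        assert [w.depth for w in whorls] == [10.0, 25.0]
        assert [w.n_members for w in whorls] == [6, 6]

    def test_close_rises_merge_at_resolution_limit(self):
        stack = _stack(40, thickness=1.0)
        nodal = [make_track(i, [(10 + 3 * i, 10)] * 10, start_slice=10)
                 for i in range(4)]
        nodal += [make_track(10 + i, [(30 + 3 * i, 30)] * 10, start_slice=11)
                  for i in range(4)]
        curve = cumulative_nodal_area(nodal, stack)
        whorls = detect_whorls(curve, nodal, stack,
                               StructureParams(min_whorl_separation=2.0))
        assert len(whorls) == 1
        assert whorls[0].n_members == 8

    def test_flat_curve_no_whorls(self):
        stack = _stack(30)
        assert detect_whorls(np.zeros(30), [], stack) == []

    def test_no_nodal_roots_zero_curve(self):
        curve = cumulative_nodal_area([], _stack(20))
        assert np.allclose(curve, 0.0)


class TestGraphInvariants:
    def test_whorl_depths_increase_with_min_separation(self, default_result):
        g = default_result.graph
        depths = [w.depth for w in g.whorls]
        assert all(b - a >= 2.0 - 1e-9 for a, b in zip(depths, depths[1:]))

    def test_member_partition(self, default_result):
        g = default_result.graph
        all_members = [tid for w in g.whorls for tid in w.member_ids]
        assert len(all_members) == len(set(all_members))
        assert len(all_members) == len(g.nodal)

    def test_whorl_indexing_youngest_first(self, default_result):
        g = default_result.graph
        assert [w.index_from_youngest for w in g.whorls] == \
            list(range(1, len(g.whorls) + 1))

    def test_noise_free_crown_whorl_recovery(self, default_result, default_crown):
        _, gt = default_crown
        g = default_result.graph
        assert len(g.whorls) == len(gt.whorl_depths)
        for w, d in zip(g.whorls, gt.whorl_depths):
            assert abs(w.depth - d) <= 1.0 + 1e-9  # one (raw) slice thickness
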