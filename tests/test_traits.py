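"""Architecture traits: geometry primitives and ground-truth recovery."""

import itertools
import math

import numpy as np
import pytest

from rootcrown3d._geometry import min_enclosing_circle
from rootcrown3d.levelset import LevelSetStack
from rootcrown3d.structure import StructureGraph, Whorl
from rootcrown3d.traits import (TraitTable, compute_all_traits, nodal_angle,
                                occupancy_index, rc_density, rc_depth,
                                rc_diameter, rc_eccentricity,
                                rc_projection_radius, rc_volume,
                                spline_arc_length, whorl_distances)
from tests.conftest import make_track


# ---------------------------------------------------------------------------
# minimal enclosing circle vs brute force
# ---------------------------------------------------------------------------

def _mec_bruteforce(pts):
    """Smallest circle through 2 or 3 support points, exhaustive."""
    def covers(c, r):
        return all(math.hypot(p[0] - c[0], p[1] - c[1]) <= r + 1e-9 for p in pts)

    best = None
    for a, b in itertools.combinations(pts, 2):
        c = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
        r = math.hypot(a[0] - b[0], a[1] - b[1]) / 2
        if covers(c, r) and (best is None or r < best):
            best = r
    for a, b, c3 in itertools.combinations(pts, 3):
        ax, ay = a
        bx, by = b
        cx, cy = c3
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        r = math.hypot(ax - ux, ay - uy)
        if covers((ux, uy), r) and (best is None or r < best):
            best = r
    return best


class TestMinEnclosingCircle:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 26)
            pts = rng.uniform(-10, 10, (n, 2))
            _, r = min_enclosing_circle(pts)
            assert abs(r - _mec_bruteforce([tuple(p) for p in pts])) < 1e-7

    def test_three_points_on_unit_circle(self):
        theta = np.array([0.3, 2.2, 4.0])
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        _, r = min_enclosing_circle(pts)
        assert abs(r - 1.0) < 1e-9

    def test_square_corners(self):
        s = 4.0
        pts = np.array([[0, 0], [s, 0], [0, s], [s, s]])
        _, r = min_enclosing_circle(pts)
        assert abs(r - s * math.sqrt(2) / 2) < 1e-9


# ---------------------------------------------------------------------------
# per-root traits
# ---------------------------------------------------------------------------

class TestWhorlDistances:
    def test_three_whorls(self):
        whorls = [Whorl(d, [0], i + 1) for i, d in enumerate((10.0, 25.0, 43.0))]
        assert whorl_distances(whorls) == (15.0, 18.0)

    def test_two_whorls_second_missing(self):
        whorls = [Whorl(10.0, [0], 1), Whorl(25.0, [1], 2)]
        d12, d23 = whorl_distances(whorls)
        assert d12 == 15.0 and math.isnan(d23)

    def test_single_whorl_both_missing(self):
        d12, d23 = whorl_distances([Whorl(10.0, [0], 1)])
        assert math.isnan(d12) and math.isnan(d23)


class TestNodalAngle:
    def test_vertical_root(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 50, 20)])
        assert abs(nodal_angle(pts) - 90.0) < 1e-6

    def test_45_degree_root(self):
        t = np.linspace(0, 50, 30)
        pts = np.column_stack([t, np.zeros(30), t])
        assert abs(nodal_angle(pts) - 45.0) < 1e-6

    def test_generator_recovery(self, default_result, default_crown):
        _, gt = default_crown
        t = default_result.traits
        assert abs(t.nodal_angle_youngest - gt.angle_per_whorl[0]) <= 3.0


class TestSplineLength:
    def test_straight_segment(self):
        pts = np.column_stack([np.linspace(0, 100, 40), np.zeros(40), np.zeros(40)])
        assert abs(spline_arc_length(pts) - 100.0) <= 1.0

    def test_quarter_circle(self):
        theta = np.linspace(0, np.pi / 2, 50)
        pts = np.column_stack([60 * np.cos(theta), 60 * np.sin(theta),
                               np.zeros(50)])
        expected = math.pi * 60 / 2
        assert abs(spline_arc_length(pts) - expected) <= 0.02 * expected


class TestOccupancy:
    def _graph(self, n_roots, raw_diam, stem_diameter):
        # corrected diameters subtract one pixel of raster dilation, so the
        # raw fitted diameter is the target diameter plus 1 px (1 mm here)
        tracks = [make_track(i, [(20 + 4 * i, 20)] * 12, diameter=raw_diam)
                  for i in range(n_roots)]
        stem = make_track(99, [(0, 0)] * 12, areas=[400.0] * 12)
        whorl = Whorl(0.0, [t.track_id for t in tracks], 1)
        return StructureGraph(stem=stem, stem_diameter=stem_diameter,
                              whorls=[whorl], nodal=tracks, laterals=[],
                              pixel_mm=1.0, thickness=1.0)

    def test_full_occupancy(self):
        # 10 vertical roots of pi mm around a 10 mm stem -> index 1.0
        g = self._graph(10, math.pi + 1.0, 10.0)
        occ = occupancy_index(g.whorls[0], g)
        assert abs(occ - 1.0) < 0.05

    def test_zero_stem_diameter_rejected(self):
        g = self._graph(2, 3.0, 10.0)
        g.stem_diameter = 0.0
        with pytest.raises(ValueError):
            occupancy_index(g.whorls[0], g)

    def test_arithmetic(self):
        # 5 roots of 2 mm around a 20 mm stem -> 10 / (pi * 20) = 0.159
        g = self._graph(5, 3.0, 20.0)
        occ = occupancy_index(g.whorls[0], g)
        assert abs(occ - 10.0 / (math.pi * 20.0)) < 0.02


# ---------------------------------------------------------------------------
# whole-crown stack traits
# ---------------------------------------------------------------------------

def _disk_stack(radius_px, n_slices=20, shape=(128, 128), pixel_mm=0.5,
                thickness=1.0, fill=True):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    cx = cy = shape[0] // 2
    images = []
    for _ in range(n_slices):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        images.append(r2 <= radius_px ** 2)
    return LevelSetStack(images=np.array(images, dtype=np.uint8),
                         thickness=thickness, pixel_mm=pixel_mm)


class TestStackTraits:
    def test_rc_diameter_cylinder(self):
        stack = _disk_stack(40, pixel_mm=0.5)  # 40 px radius = 40 mm diameter
        assert abs(rc_diameter(stack) - 40.0) <= 2 * stack.pixel_mm

    def test_rc_diameter_excludes_empty_slices(self):
        stack = _disk_stack(40)
        stack.images[::2] = 0
        assert abs(rc_diameter(stack) - 40.0) <= 2 * stack.pixel_mm

    def test_rc_eccentricity_circle(self):
        assert abs(rc_eccentricity(_disk_stack(30)) - 1.0) <= 0.05

    def test_rc_eccentricity_ellipse(self):
        yy, xx = np.mgrid[:128, :128]
        ell = ((xx - 64) / 40.0) ** 2 + ((yy - 64) / 20.0) ** 2 <= 1.0
        stack = LevelSetStack(images=np.array([ell] * 5, dtype=np.uint8),
                              thickness=1.0, pixel_mm=0.5)
        assert abs(rc_eccentricity(stack) - 0.5) <= 0.05

    def test_rc_eccentricity_single_pixel(self):
        img = np.zeros((16, 16), np.uint8)
        img[8, 8] = 1
        stack = LevelSetStack(images=img[None], thickness=1.0, pixel_mm=0.5)
        assert rc_eccentricity(stack) == 1.0

    def test_rc_density_disk(self):
        assert abs(rc_density(_disk_stack(30)) - 1.0) <= 0.05

    def test_rc_density_skips_collinear(self):
        img = np.zeros((16, 16), np.uint8)
        img[8, 2:14] = 1  # collinear row
        stack = LevelSetStack(images=img[None], thickness=1.0, pixel_mm=0.5)
        assert math.isnan(rc_density(stack))

    def test_rc_depth_closed_form(self):
        assert rc_depth(_disk_stack(10, n_slices=100, thickness=2.5)) == 250.0
        assert rc_depth(_disk_stack(10, n_slices=1, thickness=1.0)) == 1.0

    def test_rc_projection_radius_square(self):
        img = np.zeros((64, 64), np.uint8)
        s = 20  # pixels
        for r, c in ((10, 10), (10, 10 + s), (10 + s, 10), (10 + s, 10 + s)):
            img[r, c] = 1
        stack = LevelSetStack(images=img[None], thickness=1.0, pixel_mm=0.5)
        expected = (s * 0.5) * math.sqrt(2) / 2
        assert abs(rc_projection_radius(stack) - expected) < 1e-6


class TestVolumeAndSchema:
    def test_single_cylinder_volume(self):
        # one vertical root of 4 mm diameter (raw fit 4.5 mm at 0.5 mm/px,
        # one pixel of raster dilation removed) and 100 mm length
        stem = make_track(0, [(10.0, 10.0)] * 101, diameter=4.5)
        g = StructureGraph(stem=stem, stem_diameter=4.0, whorls=[], nodal=[],
                           laterals=[], pixel_mm=0.5, thickness=1.0)
        vol = rc_volume(g)
        expected = math.pi * (4.0 / 2) ** 2 * 100.0
        assert abs(vol - expected) <= 0.05 * expected

    def test_empty_graph_rejected(self):
        stem = make_track(0, [(0, 0)] * 3)
        g = StructureGraph(stem=stem, stem_diameter=1.0, whorls=[], nodal=[],
                           laterals=[], pixel_mm=0.5, thickness=1.0)
        g.stem = None
        with pytest.raises(Exception):
            rc_volume(StructureGraph(stem=None, stem_diameter=1.0, whorls=[],
                                     nodal=[], laterals=[]))

    def test_trait_table_has_18_traits(self):
        assert len(TraitTable.TRAIT_NAMES) == 18

    def test_three_whorl_crown_all_traits_populated(self, default_result):
        t = default_result.traits
        for name in TraitTable.TRAIT_NAMES:
            assert not math.isnan(getattr(t, name)), name

    def test_two_whorl_crown_d23_missing(self, two_whorl_result):
        t = two_whorl_result.traits
        assert math.isnan(t.whorl_distance_2_3)
        assert "whorl_distance_2_3" in t.qc

    def test_bounds_invariants(self, default_result):
        t = default_result.traits
        assert 0.0 <= t.nodal_angle_youngest <= 90.0
        assert 0.0 < t.rc_eccentricity <= 1.0
        assert 0.0 < t.rc_density <= 1.0
        for name in ("nodal_diameter_youngest", "nodal_length_youngest",
                     "rc_diameter", "rc_depth", "rc_projection_radius",
                     "rc_volume", "stem_diameter"):
            assert getattr(t, name) >= 0.0

    def test_noise_free_recovery(self, default_result, default_crown):
        _, gt = default_crown
        t = default_result.traits
        assert t.n_nodal_youngest == gt.n_nodal_youngest
        assert t.n_nodal_occluded == gt.n_nodal_occluded
        assert abs(t.whorl_distance_1_2 - gt.whorl_distance_1_2) <= 1.0
        assert abs(t.nodal_diameter_youngest - gt.diameter_per_whorl[0]) <= 1.0
        assert abs(t.rc_volume - gt.volume) <= 0.15 * gt.volume
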