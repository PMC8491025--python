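"""Parametric maize root-crown generator with exact ground truth.

A synthetic crown is a vertical stem cylinder plus 2-6 whorls at increasing
depths, each whorl a ring of nodal roots with a set insertion angle,
diameter, length and curvature, optionally carrying lateral roots.  Every
root is a tube around an analytic centerline: the initial direction is set
by the insertion angle and the inclination steepens toward vertical at a
constant rate per mm of arc length (maize nodal roots dive as they grow).
Tube surfaces are point-sampled at a set density, perturbed radially by
Gaussian noise and thinned by uniform dropout — emulating the occlusion and
under-sampling of real excavated-crown reconstructions.

Centerlines begin 1.5 mm clear of the stem surface (beyond the raster
resolution, so the emergence cross-section is a separate component at the
true whorl depth): the generator's
definition of the emergence point is where the root becomes visible outside
the stem, which keeps the ground-truth emergence depth exactly the whorl
depth.  Ground truth (whorl depths/counts, per-whorl angles, diameters,
lengths, occupancy, total volume, per-root polylines) is computed from the
noise-free centerlines with the same trait conventions the pipeline uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cloud_io import RootPointCloud
from .traits import nodal_angle


class SpecError(ValueError):
    """Raised for geometrically impossible crown specifications."""


@dataclass
class WhorlSpec:
    depth: float                     # mm below stem top
    n_roots: int
    insertion_angle_deg: float       # from horizontal, 0-90
    diameter: float                  # mm
    length: float                    # mm arc length
    curvature_deg_per_mm: float = 0.25   # steepening toward vertical
    azimuth_jitter_deg: float = 8.0
    azimuth_offset_deg: float | None = None  # None: auto half-spacing stagger


def _default_whorls() -> list[WhorlSpec]:
    # a typical mature field crown: three resolvable whorls, younger
    # (shallower) whorls steeper and thicker, older ones longer
    return [
        WhorlSpec(depth=15.0, n_roots=8, insertion_angle_deg=65.0,
                  diameter=4.0, length=60.0),
        WhorlSpec(depth=40.0, n_roots=10, insertion_angle_deg=55.0,
                  diameter=3.5, length=80.0),
        WhorlSpec(depth=60.0, n_roots=12, insertion_angle_deg=45.0,
                  diameter=3.0, length=95.0),
    ]


@dataclass
class SyntheticCrownSpec:
    stem_diameter: float = 22.0
    stem_depth: float | None = None       # default: deepest whorl + 15 mm
    whorls: list[WhorlSpec] = field(default_factory=_default_whorls)
    laterals_per_root: int = 0
    lateral_diameter: float = 0.8
    lateral_length: float = 15.0
    point_density: float = 10.0           # points per mm^2 of surface
    noise_mm: float = 0.0                 # radial Gaussian sigma
    dropout: float = 0.0                  # fraction of points removed
    seed: int = 0

    def resolved_stem_depth(self) -> float:
        if self.stem_depth is not None:
            return self.stem_depth
        return max(w.depth for w in self.whorls) + 15.0

    def validate(self) -> None:
        if self.stem_diameter <= 0:
            raise SpecError("stem diameter must be positive")
        if not self.whorls:
            raise SpecError("need at least one whorl")
        depths = [w.depth for w in self.whorls]
        if any(d <= 0 for d in depths) or any(
                b <= a for a, b in zip(depths, depths[1:])):
            raise SpecError("whorl depths must be positive and strictly increasing")
        if max(depths) > self.resolved_stem_depth():
            raise SpecError("whorl below the stem end is unrealizable")
        for w in self.whorls:
            if min(w.n_roots, w.diameter, w.length) <= 0:
                raise SpecError("whorl root count, diameter and length must be positive")
            if not 0 < w.insertion_angle_deg <= 90:
                raise SpecError("insertion angle must be in (0, 90] degrees")
        if not 0 <= self.dropout < 1:
            raise SpecError("dropout must be in [0, 1)")
        if self.point_density <= 0 or self.noise_mm < 0:
            raise SpecError("invalid sampling parameters")


@dataclass
class GroundTruth:
    """Exact trait values implied by the generated centerlines."""

    whorl_depths: list[float]
    n_roots_per_whorl: list[int]
    angle_per_whorl: list[float]          # deg, proximal-70% TLS convention
    diameter_per_whorl: list[float]       # mm
    length_per_whorl: list[float]         # mm
    occupancy_per_whorl: list[float]
    stem_diameter: float
    stem_depth: float
    lateral_diameter: float
    n_laterals: int
    total_depth: float                    # mm, deepest point of any root
    volume: float                         # mm^3, incl. stem
    polylines: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_nodal_youngest(self) -> int:
        return self.n_roots_per_whorl[0]

    @property
    def n_nodal_occluded(self) -> int:
        return sum(self.n_roots_per_whorl[1:])

    @property
    def whorl_distance_1_2(self) -> float:
        return (self.whorl_depths[1] - self.whorl_depths[0]
                if len(self.whorl_depths) >= 2 else math.nan)

    @property
    def whorl_distance_2_3(self) -> float:
        return (self.whorl_depths[2] - self.whorl_depths[1]
                if len(self.whorl_depths) >= 3 else math.nan)


# ---------------------------------------------------------------------------
# centerlines and tube sampling
# ---------------------------------------------------------------------------

def _root_centerline(start: np.ndarray, azimuth: float, angle_deg: float,
                     length: float, curv_deg_per_mm: float,
                     ds: float = 0.5) -> np.ndarray:
    """Integrate a steepening centerline; +z is depth (downward)."""
    n = max(2, int(round(length / ds)) + 1)
    s = np.linspace(0.0, length, n)
    gamma = np.radians(np.minimum(angle_deg + curv_deg_per_mm * s, 89.9))
    d = np.column_stack([np.cos(gamma) * math.cos(azimuth),
                         np.cos(gamma) * math.sin(azimuth),
                         np.sin(gamma)])
    steps = 0.5 * (d[1:] + d[:-1]) * np.diff(s)[:, None]
    pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    return pts


def _sample_tube(centerline: np.ndarray, diameter: float, density: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Surface-sample a tube around a polyline; returns (points, normals)."""
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    r = diameter / 2.0
    n_pts = max(8, int(round(density * math.pi * diameter * total)))
    s = rng.uniform(0.0, total, n_pts)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_pts)
    idx = np.clip(np.searchsorted(cum, s) - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.maximum(seg_len[idx], 1e-12)
    centers = centerline[idx] + seg[idx] * frac[:, None]
    d = seg[idx] / np.maximum(seg_len[idx], 1e-12)[:, None]
    ref = np.where(np.abs(d[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (n_pts, 1)),
                   np.tile([1.0, 0.0, 0.0], (n_pts, 1)))
    n1 = np.cross(d, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(d, n1)
    normals = n1 * np.cos(theta)[:, None] + n2 * np.sin(theta)[:, None]
    return centers + r * normals, normals


def _sample_disk(center: np.ndarray, radius: float, density: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_pts = max(4, int(round(density * math.pi * radius ** 2)))
    rr = radius * np.sqrt(rng.uniform(0, 1, n_pts))
    th = rng.uniform(0, 2 * math.pi, n_pts)
    pts = np.column_stack([center[0] + rr * np.cos(th),
                           center[1] + rr * np.sin(th),
                           np.full(n_pts, center[2])])
    normals = np.tile([0.0, 0.0, -1.0], (n_pts, 1))
    return pts, normals


def generate_crown(spec: SyntheticCrownSpec) -> tuple[RootPointCloud, GroundTruth]:
    """Generate a crown point cloud and its exact ground truth.

    Deterministic for a given spec + seed.  Noise is applied radially to
    tube surfaces; dropout removes points uniformly at random.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stem_r = spec.stem_diameter / 2.0
    stem_depth = spec.resolved_stem_depth()

    point_blocks: list[np.ndarray] = []
    normal_blocks: list[np.ndarray] = []

    # stem: surface cylinder + top cap
    stem_line = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, stem_depth]])
    pts, nrm = _sample_tube(stem_line, spec.stem_diameter, spec.point_density, rng)
    point_blocks.append(pts)
    normal_blocks.append(nrm)
    pts, nrm = _sample_disk(np.zeros(3), stem_r, spec.point_density, rng)
    point_blocks.append(pts)
    normal_blocks.append(nrm)

    gt = GroundTruth(whorl_depths=[w.depth for w in spec.whorls],
                     n_roots_per_whorl=[w.n_roots for w in spec.whorls],
                     angle_per_whorl=[], diameter_per_whorl=[],
                     length_per_whorl=[], occupancy_per_whorl=[],
                     stem_diameter=spec.stem_diameter, stem_depth=stem_depth,
                     lateral_diameter=(spec.lateral_diameter
                                       if spec.laterals_per_root else math.nan),
                     n_laterals=0, total_depth=stem_depth,
                     volume=math.pi * stem_r ** 2 * stem_depth)

    for wi, w in enumerate(spec.whorls):
        angles = []
        start_r = stem_r + 1.5 + w.diameter / 2.0
        # successive whorls are rotationally staggered (as in real crowns);
        # half the root spacing per whorl index unless specified
        offset = (math.radians(w.azimuth_offset_deg)
                  if w.azimuth_offset_deg is not None
                  else wi * math.pi / w.n_roots)
        base_azimuths = offset + 2.0 * math.pi * np.arange(w.n_roots) / w.n_roots
        jitter = np.radians(w.azimuth_jitter_deg) * rng.uniform(-1, 1, w.n_roots)
        for az in base_azimuths + jitter:
            start = np.array([start_r * math.cos(az), start_r * math.sin(az),
                              w.depth])
            line = _root_centerline(start, az, w.insertion_angle_deg,
                                    w.length, w.curvature_deg_per_mm)
            gt.polylines.append(line)
            gt.total_depth = max(gt.total_depth, float(line[:, 2].max()))
            gt.volume += math.pi * (w.diameter / 2.0) ** 2 * w.length
            angles.append(nodal_angle(line))
            pts, nrm = _sample_tube(line, w.diameter, spec.point_density, rng)
            point_blocks.append(pts)
            normal_blocks.append(nrm)
            for _ in range(spec.laterals_per_root):
                s_at = rng.uniform(0.4, 0.9) * w.length
                seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
                cum = np.concatenate([[0.0], np.cumsum(seg)])
                i0 = int(np.clip(np.searchsorted(cum, s_at) - 1, 0, len(line) - 2))
                origin = line[i0]
                lat_az = rng.uniform(0, 2 * math.pi)
                lat = _root_centerline(origin, lat_az, 55.0,
                                       spec.lateral_length, 0.5)
                pts, nrm = _sample_tube(lat, spec.lateral_diameter,
                                        spec.point_density, rng)
                point_blocks.append(pts)
                normal_blocks.append(nrm)
                gt.n_laterals += 1
                gt.volume += (math.pi * (spec.lateral_diameter / 2.0) ** 2
                              * spec.lateral_length)
                gt.total_depth = max(gt.total_depth, float(lat[:, 2].max()))
        gt.angle_per_whorl.append(float(np.mean(angles)))
        gt.diameter_per_whorl.append(w.diameter)
        gt.length_per_whorl.append(w.length)
        gt.occupancy_per_whorl.append(
            w.n_roots * w.diameter / (math.pi * spec.stem_diameter))

    points = np.vstack(point_blocks)
    normals = np.vstack(normal_blocks)
    if spec.noise_mm > 0:
        points = points + normals * rng.normal(0.0, spec.noise_mm,
                                               (len(points), 1))
    if spec.dropout > 0:
        keep = rng.uniform(0, 1, len(points)) >= spec.dropout
        points = points[keep]
    return RootPointCloud(points=points), gt


def random_crown_spec(rng: np.random.Generator, noise_max: float = 0.25,
                      dropout_max: float = 0.1) -> SyntheticCrownSpec:
    """Random crown in the tested envelope: 2-4 whorls, 6-14 roots per
    whorl, insertion angles 30-80 degrees, whorl gaps >= 12 mm."""
    n_whorls = int(rng.integers(2, 5))
    depth = float(rng.uniform(12.0, 20.0))
    whorls = []
    for _ in range(n_whorls):
        whorls.append(WhorlSpec(
            depth=depth,
            n_roots=int(rng.integers(6, 15)),
            insertion_angle_deg=float(rng.uniform(30.0, 80.0)),
            diameter=float(rng.uniform(2.5, 4.5)),
            length=float(rng.uniform(45.0, 70.0)),
            curvature_deg_per_mm=float(rng.uniform(0.1, 0.4)),
            azimuth_jitter_deg=6.0))
        depth += float(rng.uniform(12.0, 22.0))
    return SyntheticCrownSpec(
        stem_diameter=float(rng.uniform(18.0, 26.0)),
        whorls=whorls,
        noise_mm=float(rng.uniform(0.0, noise_max)),
        dropout=float(rng.uniform(0.0, dropout_max)),
        seed=int(rng.integers(0, 2 ** 31 - 1)))


# ---------------------------------------------------------------------------
# 2D slice fixtures for segmentation and tracking tests
# ---------------------------------------------------------------------------

def _disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def generate_slice_fixture(kind: str, params: dict | None = None,
                           seed: int = 0) -> dict:
    """Deterministic 2D raster fixtures with analytic ground truth.

    Kinds: ``disks``, ``overlapping_disks``, ``broken_ring``,
    ``drifting_disks``, ``crossing_disks``.  Returns a dict with ``image``
    or ``stack`` plus the analytic truth (centroids, trajectories, counts).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "disks":
        shape = p.get("shape", (96, 96))
        n = p.get("n", 3)
        r = p.get("radius", 8)
        img = np.zeros(shape, bool)
        centers = []
        while len(centers) < n:
            cx = rng.uniform(r + 2, shape[1] - r - 2)
            cy = rng.uniform(r + 2, shape[0] - r - 2)
            if all((cx - a) ** 2 + (cy - b) ** 2 > (2.5 * r) ** 2
                   for a, b in centers):
                centers.append((cx, cy))
                img |= _disk_mask(shape, cx, cy, r)
        return {"image": img, "centers": centers, "n": n, "radius": r}
    if kind == "overlapping_disks":
        shape = p.get("shape", (96, 96))
        r = p.get("radius", 12)
        d = p.get("d_centers", 18)
        n = p.get("n", 2)
        cy = shape[0] / 2
        x0 = shape[1] / 2 - d * (n - 1) / 2
        centers = [(x0 + i * d, cy) for i in range(n)]
        img = np.zeros(shape, bool)
        for cx, cyy in centers:
            img |= _disk_mask(shape, cx, cyy, r)
        return {"image": img, "centers": centers, "n": n, "radius": r}
    if kind == "broken_ring":
        shape = p.get("shape", (96, 96))
        r = p.get("radius", 25)
        width = p.get("width", 3)
        arc_gap = p.get("arc_gap", 0.2)
        gap_center = p.get("gap_center_deg", 0.0)
        cx = cy = shape[0] / 2
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        rad = np.hypot(xx - cx, yy - cy)
        ring = (rad >= r - width / 2) & (rad <= r + width / 2)
        if arc_gap <= 0:
            img = ring
        else:
            ang = np.degrees(np.arctan2(yy - cy, xx - cx))
            half = arc_gap * 360.0 / 2.0
            diff = (ang - gap_center + 180.0) % 360.0 - 180.0
            img = ring & ~(np.abs(diff) <= half)
        return {"image": img, "radius": r, "center": (cx, cy)}
    if kind == "drifting_disks":
        shape = p.get("shape", (128, 128))
        n_frames = p.get("n_frames", 50)
        r = p.get("radius", 9)
        starts = p.get("starts", [(20.0, 30.0), (20.0, 90.0)])
        vels = p.get("velocities", [(1.8, 0.2), (1.8, -0.2)])
        stack, traj = [], []
        for f in range(n_frames):
            img = np.zeros(shape, bool)
            frame_pos = []
            for (x0, y0), (vx, vy) in zip(starts, vels):
                cx, cy = x0 + vx * f, y0 + vy * f
                img |= _disk_mask(shape, cx, cy, r)
                frame_pos.append((cx, cy))
            stack.append(img)
            traj.append(frame_pos)
        return {"stack": np.array(stack), "trajectories": np.array(traj),
                "n": len(starts), "radius": r}
    if kind == "crossing_disks":
        shape = p.get("shape", (128, 128))
        n_frames = p.get("n_frames", 40)
        r = p.get("radius", 8)
        starts = [(20.0, 30.0), (20.0, 98.0)]
        vels = [(2.2, 1.7), (2.2, -1.7)]
        return generate_slice_fixture(
            "drifting_disks", {"shape": shape, "n_frames": n_frames,
                               "radius": r, "starts": starts,
                               "velocities": vels}, seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
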