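"""Shared fixtures: synthetic crowns and one full pipeline run per session."""

import numpy as np
import pytest

from rootcrown3d.config import PipelineConfig
from rootcrown3d.cross_section import CrossSectionComponent
from rootcrown3d.pipeline import process_cloud
from rootcrown3d.synthetic import SyntheticCrownSpec, WhorlSpec, generate_crown


@pytest.fixture(scope="session")
def default_crown():
    """Noise-free 3-whorl maize crown with ground truth."""
    return generate_crown(SyntheticCrownSpec(seed=1))


@pytest.fixture(scope="session")
def default_result(default_crown):
    """Full pipeline result on the default crown (computed once)."""
    cloud, _ = default_crown
    return process_cloud(cloud, PipelineConfig())


@pytest.fixture(scope="session")
def two_whorl_crown():
    spec = SyntheticCrownSpec(
        whorls=[WhorlSpec(depth=15.0, n_roots=8, insertion_angle_deg=60.0,
                          diameter=4.0, length=45.0),
                WhorlSpec(depth=40.0, n_roots=12, insertion_angle_deg=50.0,
                          diameter=3.0, length=55.0)],
        seed=11)
    return generate_crown(spec)


@pytest.fixture(scope="session")
def two_whorl_result(two_whorl_crown):
    cloud, _ = two_whorl_crown
    return process_cloud(cloud, PipelineConfig())


def make_component(cx, cy, slice_index=0, area=30.0, radius_px=3,
                   diameter=None):
    """Minimal synthetic cross-section component at a pixel centroid.

    ``diameter`` defaults to the fitted-circle value for the area at
    1 mm/px, keeping the two fields consistent.
    """
    size = 2 * radius_px + 1
    yy, xx = np.mgrid[:size, :size]
    mask = (xx - radius_px) ** 2 + (yy - radius_px) ** 2 <= radius_px ** 2
    r0 = int(round(cy)) - radius_px
    c0 = int(round(cx)) - radius_px
    if diameter is None:
        diameter = 2.0 * np.sqrt(area / np.pi)
    return CrossSectionComponent(
        slice_index=slice_index, label=1, centroid=(float(cx), float(cy)),
        area=float(area), diameter=float(diameter),
        bbox=(r0, c0, r0 + size, c0 + size), mask=mask)


def make_track(track_id, points_px, start_slice=0, areas=None, diameter=None):
    """RootTrack through (x, y) pixel positions at consecutive slices."""
    from rootcrown3d.tracking import RootTrack

    t = RootTrack(track_id=track_id)
    for i, (x, y) in enumerate(points_px):
        area = areas[i] if areas is not None else 30.0
        t.detections.append((start_slice + i,
                             make_component(x, y, start_slice + i, area=area,
                                            diameter=diameter)))
    return t
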