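"""End-to-end orchestration: point cloud in, traits + descriptor + graph out.

Stages: read -> scale -> align -> level-set slicing -> inter-slice
interpolation -> per-slice detection -> tracking -> structure assembly ->
traits and descriptor.  Each stage failure aborts with the stage name;
partial outputs written so far are preserved.  Outputs are deterministic
for identical input, config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud_io import RootPointCloud, align_vertical, read_point_cloud, scale_to_mm
from .config import PipelineConfig
from .cross_section import clean_mask, detect_components
from .descriptor import WholeRootDescriptor, whole_root_descriptor
from .levelset import LevelSetStack, interpolate_stack, slice_stack
from .structure import StructureGraph, build_structure_graph
from .tracking import track_stack
from .traits import TraitTable, compute_all_traits

logger = logging.getLogger("rootcrown3d")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    traits: TraitTable
    descriptor: WholeRootDescriptor
    graph: StructureGraph
    qc: dict
    raw_stack: LevelSetStack = field(repr=False, default=None)
    nodal_area_curve: np.ndarray = field(repr=False, default=None)


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s: %.2fs", name, timings[name])
    return out


def process_cloud(cloud: RootPointCloud,
                  config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full trait pipeline on an in-memory point cloud."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    if config.scale_mm != 1.0:
        cloud = _stage("scale", timings, scale_to_mm, cloud, config.scale_mm)
    if config.align:
        cloud, _ = _stage("align", timings, align_vertical, cloud)
    raw = _stage("slice", timings, slice_stack, cloud,
                 config.thickness, config.pixel_mm)

    def clean_stack():
        # Solidify tube cross-sections before interpolation: morphing
        # unfilled rings unions their sampling holes and shatters sections.
        # A ring whose wall has a multi-pixel sampling gap cannot be filled
        # from its own slice; the union with the neighboring slices closes
        # such gaps, and only the *enclosed interior* of that union is
        # carried over (never the neighbors' foreground itself, which would
        # smear moving sections).
        from scipy.ndimage import binary_closing, binary_fill_holes

        masks = raw.images.astype(bool)
        cleaned = [clean_mask(img, min_area=config.min_component_area)
                   for img in masks]
        eight = np.ones((3, 3), bool)
        for i in range(len(masks)):
            lo, hi = max(0, i - 1), min(len(masks), i + 2)
            union = np.logical_or.reduce(masks[lo:hi])
            closed_u = binary_closing(union, structure=eight, border_value=0)
            interior = binary_fill_holes(closed_u) & ~closed_u
            if interior.any():
                cleaned[i] = binary_fill_holes(cleaned[i] | interior)
        images = np.stack(cleaned).astype(np.uint8)
        return LevelSetStack(images=images, thickness=raw.thickness,
                             pixel_mm=raw.pixel_mm, origin=raw.origin,
                             depth0=raw.depth0)

    raw = _stage("clean", timings, clean_stack)
    if config.interp_frames > 0 and raw.n_slices >= 2:
        det_stack = _stage("interpolate", timings, interpolate_stack,
                           raw, config.interp_frames)
    else:
        det_stack = raw

    def detect_all():
        return [detect_components(
            img, i, det_stack.pixel_mm,
            min_area=config.min_component_area,
            min_marker_distance=config.watershed_min_distance,
            merge_ridge_ratio=config.merge_ridge_ratio)
            for i, img in enumerate(det_stack.images)]

    slices = _stage("detect", timings, detect_all)
    # max_skip / min_track_length are physical (raw-slice) tolerances; on an
    # interpolated stack the slices are (k+1)x thinner, so scale the counts
    scale = max(1, round(config.thickness / det_stack.thickness))
    track_params = dataclasses.replace(
        config.tracking,
        max_skip=config.tracking.max_skip * scale,
        min_track_length=config.tracking.min_track_length * scale)
    tracks = _stage("track", timings, track_stack, slices, track_params)
    graph, curve = _stage("structure", timings, build_structure_graph,
                          tracks, det_stack, config.structure, track_params)
    traits = _stage("traits", timings, compute_all_traits, graph, raw)
    descriptor = _stage("descriptor", timings, whole_root_descriptor,
                        raw, config.descriptor_grid)
    qc = {"missing_traits": traits.qc,
          "n_tracks": len(tracks),
          "n_nodal": len(graph.nodal),
          "n_lateral": len(graph.laterals),
          "n_unattached": len(graph.unattached),
          "n_whorls": len(graph.whorls),
          "stage_seconds": timings}
    return PipelineResult(traits=traits, descriptor=descriptor, graph=graph,
                          qc=qc, raw_stack=raw, nodal_area_curve=curve)


def run_pipeline(cloud_path: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Read a PLY crown, run the pipeline and (optionally) write artifacts:
    traits CSV with a units header, descriptor CSV, structure JSON and PLY,
    and the QC report JSON."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    cloud = _stage("cloud_io", timings, read_point_cloud, cloud_path)
    result = process_cloud(cloud, config)
    result.qc["stage_seconds"] = {**timings, **result.qc["stage_seconds"]}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        label = Path(cloud_path).stem
        result.traits.to_csv(out / f"{label}_traits.csv", label=label)
        result.descriptor.to_csv(out / f"{label}_descriptor.csv")
        result.graph.save_json(out / f"{label}_structure.json")
        result.graph.save_polyline_ply(out / f"{label}_structure.ply")
        (out / f"{label}_qc.json").write_text(json.dumps(result.qc, indent=1))
    return result


def run_batch(directory: str | Path, config: PipelineConfig | None = None,
              out_dir: str | Path | None = None) -> pd.DataFrame:
    """Process every PLY in a directory; failures are logged and skipped.

    Returns one trait row per successfully processed crown (identical to
    the single-run numbers for the same file).
    """
    directory = Path(directory)
    plys = sorted(directory.glob("*.ply"))
    if not plys:
        raise FileNotFoundError(f"no PLY files in {directory}")
    rows = []
    failures = []
    for path in plys:
        try:
            result = run_pipeline(path, config, out_dir)
        except Exception as exc:
            logger.error("crown %s failed: %s", path.name, exc)
            failures.append({"crown": path.stem, "error": str(exc)})
            continue
        row = {"crown": path.stem}
        row.update(result.traits.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None and rows:
        df.to_csv(Path(out_dir) / "traits_batch.csv", index=False)
        if failures:
            (Path(out_dir) / "failures.json").write_text(json.dumps(failures, indent=1))
    df.attrs["failures"] = failures
    return df
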