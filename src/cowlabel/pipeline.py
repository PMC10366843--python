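"""Convenience wrapper chaining the full labeling pipeline.

segment (Otsu + seeded region growing + union) -> skeletonize -> graph ->
label. Each stage is importable on its own; this wrapper exists for the CLI
``pipeline`` subcommand and for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .labeling import LabeledCenterlines, label_segments
from .segmentation import (
    BinaryMask,
    SeedPoint,
    default_grow_tolerance,
    otsu_threshold,
    region_grow_3d,
    union_masks,
)
from .skeleton import SkeletonGraph, skeleton_to_graph, skeletonize_3d
from .volume_io import IntensityVolume, VesselSegmentSpec

__all__ = ["PipelineResult", "segment_vessels", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    mask: BinaryMask
    skeleton: BinaryMask
    graph: SkeletonGraph
    labeled: LabeledCenterlines


def segment_vessels(
    vol: IntensityVolume,
    seeds: tuple[SeedPoint, ...],
    tolerance: float | None = None,
    connectivity: int = 6,
) -> BinaryMask:
    """Otsu + per-seed 3D region growing + union.

    When ``tolerance`` is None it is derived per seed from the Otsu
    threshold (seed intensity minus threshold, floored at 10% of the seed
    intensity).
    """
    otsu = otsu_threshold(vol)
    masks = []
    for seed in seeds:
        t = tolerance
        if t is None:
            t = default_grow_tolerance(float(vol.data[seed.coordinate]), otsu)
        masks.append(region_grow_3d(vol, seed, max_deviation=t, connectivity=connectivity))
    return union_masks(masks)


def run_pipeline(
    vol: IntensityVolume,
    seeds: tuple[SeedPoint, ...],
    specs: list[VesselSegmentSpec],
    method: str = "dijkstra",
    tolerance: float | None = None,
    connectivity: int = 6,
    snap_radius: float = 3.0,
) -> PipelineResult:
    """Run segmentation, skeletonization, graph build, and labeling."""
    mask = segment_vessels(vol, seeds, tolerance=tolerance, connectivity=connectivity)
    skel = skeletonize_3d(mask)
    graph = skeleton_to_graph(skel)
    labeled = label_segments(graph, skel, specs, method=method, snap_radius=snap_radius)
    return PipelineResult(mask=mask, skeleton=skel, graph=graph, labeled=labeled)
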