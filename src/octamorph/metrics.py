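"""The six per-lesion MNV parameters: area, flow, FD, numN, sumL, avgW.

* area — lesion-mask pixel count × pitch², mm²
* flow — percentage of lesion pixels carrying detectable flow signal
* FD — box-counting fractal dimension of the centerline skeleton
* numN — vessel-fork (junction node) count per mm² of lesion
* sumL — total centerline length, mm
* avgW — length-weighted mean vessel caliber, µm
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .config import RunConfig
from .graph import build_graph, graph_statistics
from .io import EnFaceImage, ScanGeometry, validate_mask
from .vessels import binarize, enhance_vessels, estimate_calibers, skeletonize

__all__ = [
    "MnvMetrics",
    "lesion_area",
    "flow_density",
    "fractal_dimension",
    "compute_all",
]


@dataclass(frozen=True)
class MnvMetrics:
    """The six vascular parameters of one lesion, in reporting units."""

    area_mm2: float
    fd: float
    numN_per_mm2: float
    flow_pct: float
    sumL_mm: float
    avgW_um: float

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("area_mm2 must be > 0")
        if not 0 <= self.flow_pct <= 100:
            raise ValueError(f"flow_pct out of [0, 100]: {self.flow_pct}")
        if not 0 <= self.fd <= 2:
            raise ValueError(f"fd out of [0, 2]: {self.fd}")
        if self.sumL_mm < 0:
            raise ValueError("sumL_mm must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def lesion_area(mask: np.ndarray, geometry: ScanGeometry) -> float:
    """Lesion area in mm²: set-pixel count × pitch² (pixels as area cells)."""
    mask = validate_mask(mask)
    return int(mask.sum()) * geometry.pixel_area_mm2


def flow_density(vessels: np.ndarray, mask: np.ndarray) -> float:
    """Perfused fraction of the lesion, in percent: 100·|vessels| / |mask|.

    The denominator is the lesion mask, not the full frame — flow is a
    per-lesion vascularization proportion.
    """
    mask = validate_mask(mask)
    vessels = np.asarray(vessels, dtype=bool)
    if np.any(vessels & ~mask):
        raise ValueError("vessel map extends outside the lesion mask")
    return 100.0 * int(vessels.sum()) / int(mask.sum())


def fractal_dimension(
    skeleton: np.ndarray,
    field_shape: Optional[tuple[int, int]] = None,
    multi_offset: bool = False,
) -> float:
    """Box-counting dimension of the skeleton.

    Boxes of side s = 2, 4, …, 2^k tile the skeleton's bounding box anchored
    at its top-left corner; k is the largest power with 2^k ≤ short_side / 4,
    and at least three sizes are required.  fd is minus the OLS slope of
    log N(s) against log s, clipped to [0, 2].

    ``field_shape`` overrides the counting field (anchored at the bounding
    box's top-left) for degenerate shapes whose own bounding box is too
    narrow, e.g. a perfectly straight line.  ``multi_offset`` averages N(s)
    over all s² grid offsets instead of using the single anchored grid.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    rows, cols = np.nonzero(skel)
    r0, c0 = rows.min(), cols.min()
    if field_shape is None:
        h = int(rows.max() - r0 + 1)
        w = int(cols.max() - c0 + 1)
    else:
        h, w = int(field_shape[0]), int(field_shape[1])
    crop = np.zeros((h, w), dtype=bool)
    rr, cc = rows - r0, cols - c0
    keep = (rr < h) & (cc < w)
    crop[rr[keep], cc[keep]] = True

    k = int(np.floor(np.log2(min(h, w) / 4))) if min(h, w) >= 8 else 0
    sizes = [2**i for i in range(1, k + 1)]
    if len(sizes) < 3:
        raise ValueError("lesion too small for FD (need 3 box sizes)")

    counts = []
    for s in sizes:
        if multi_offset:
            n = np.mean(
                [_count_boxes(crop, s, dr, dc) for dr in range(s) for dc in range(s)]
            )
        else:
            n = _count_boxes(crop, s, 0, 0)
        counts.append(n)
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(np.clip(-slope, 0.0, 2.0))


def _count_boxes(grid: np.ndarray, s: int, dr: int, dc: int) -> int:
    """Occupied s×s boxes on the grid shifted by (dr, dc), zero-padded."""
    h, w = grid.shape
    ph = int(np.ceil((h + dr) / s)) * s
    pw = int(np.ceil((w + dc) / s)) * s
    padded = np.zeros((ph, pw), dtype=bool)
    padded[dr : dr + h, dc : dc + w] = grid
    blocks = padded.reshape(ph // s, s, pw // s, s)
    return int(blocks.any(axis=(1, 3)).sum())


def compute_all(
    image: EnFaceImage,
    mask: np.ndarray,
    config: Optional[RunConfig] = None,
    return_intermediates: bool = False,
):
    """Run the full per-lesion pipeline and return :class:`MnvMetrics`.

    Stages: tubularity enhancement → in-mask binarization → thinning with
    spur pruning → distance-transform calibers → graph construction → the
    six parameters.  Deterministic given image + config; a failing stage is
    re-raised with the stage name prefixed.
    """
    cfg = config or RunConfig(geometry=image.geometry)
    geometry = image.geometry
    mask = validate_mask(mask, image.shape)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as exc:
            raise ValueError(f"[{name}] {exc}") from exc

    if cfg.binarize_source == "vesselness":
        response = _stage("enhance", enhance_vessels, image, mask, cfg.scales_px)
    elif cfg.binarize_source == "intensity":
        response = np.where(mask, image.pixels.astype(np.float64), 0.0)
    else:
        raise ValueError(f"unknown binarize_source {cfg.binarize_source!r}")
    method = cfg.binarize_method if cfg.binarize_method != "fixed" else cfg.binarize_threshold
    vessels = _stage(
        "binarize", binarize, response, mask, method, cfg.closing_radius_px, cfg.min_object_px, cfg.max_hole_px
    )
    skeleton = _stage("skeletonize", skeletonize, vessels, cfg.prune_spur_px)
    calibers = _stage("calibers", estimate_calibers, vessels, skeleton, geometry)
    graph = _stage("graph", build_graph, skeleton, calibers, geometry,
                   cfg.junction_merge_px)

    area = _stage("area", lesion_area, mask, geometry)
    flow = _stage("flow", flow_density, vessels, mask)
    fd = _stage("fd", fractal_dimension, skeleton, None, cfg.fd_multi_offset)
    num_n, sum_l, avg_w = _stage("graph_stats", graph_statistics, graph, area)

    metrics = MnvMetrics(
        area_mm2=area,
        fd=fd,
        numN_per_mm2=num_n,
        flow_pct=flow,
        sumL_mm=sum_l,
        avgW_um=avg_w,
    )
    if return_intermediates:
        return metrics, {
            "vesselness": response,
            "vessels": vessels,
            "skeleton": skeleton,
            "calibers": calibers,
            "graph": graph,
        }
    return metrics
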