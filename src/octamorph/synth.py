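"""Synthetic data: calibrated metric populations and lesion-image phantoms.

The study's patient images are not deposited, so two generators stand in:

1. A *population* generator producing per-eye metric cohorts whose per-type
   marginal distributions are moment-matched to the published summary table
   (mean/SD per parameter per MNV type, group sizes 39/32/19).  Right-skewed
   parameters (area, sumL, avgW: printed mean well above the median) use a
   log-normal family; fd, numN and flow (mean ≈ median) use a truncated
   normal.  Parameters are sampled independently within type — the published
   table gives marginals only.

2. An *image* generator growing a stochastic branching vessel tree inside an
   elliptical lesion mask, rasterizing it as bright tubes over multiplicative
   speckle, and recording exact ground-truth morphometrics (centerline
   length, bifurcation count, length-weighted caliber, mask area) for
   pipeline recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import EnFaceImage, ScanGeometry

__all__ = [
    "PUBLISHED_SUMMARY_STATS",
    "DistributionSpec",
    "fit_parameter_distributions",
    "sample_cohort",
    "SyntheticLesionSpec",
    "GroundTruth",
    "generate_lesion_image",
    "recovery_report",
    "PARAM_COLUMNS",
]

#: short parameter keys → metrics-CSV column names
PARAM_COLUMNS = {
    "area": "area_mm2",
    "fd": "fd",
    "numN": "numN_per_mm2",
    "flow": "flow_pct",
    "sumL": "sumL_mm",
    "avgW": "avgW_um",
}

#: Published per-type summary statistics of the six vascular parameters
#: (minimum, Q1, median, Q3, maximum, mean, SD), MNV types 1/2/3 plus the
#: pooled row.  These printed numbers are the calibration input of the
#: population generator.
PUBLISHED_SUMMARY_STATS: dict[tuple[str, str], dict[str, float]] = {}


def _t1(param, cls, mn, q1, med, q3, mx, mean, sd):
    PUBLISHED_SUMMARY_STATS[(param, cls)] = {
        "min": mn, "q1": q1, "median": med, "q3": q3, "max": mx, "mean": mean, "sd": sd,
    }


_t1("area", "total", 0.02, 0.26, 0.87, 2.37, 9.51, 1.56, 1.9)
_t1("area", "1", 0.13, 0.53, 1.49, 3.18, 9.51, 2.38, 2.33)
_t1("area", "2", 0.15, 0.36, 1.01, 1.7, 5.37, 1.38, 1.3)
_t1("area", "3", 0.02, 0.06, 0.1, 0.22, 0.86, 0.19, 0.21)
_t1("fd", "total", 0.95, 1.21, 1.29, 1.41, 1.52, 1.29, 0.14)
_t1("fd", "1", 1.04, 1.26, 1.39, 1.45, 1.52, 1.35, 0.12)
_t1("fd", "2", 1.13, 1.26, 1.31, 1.39, 1.48, 1.32, 0.09)
_t1("fd", "3", 0.95, 1.01, 1.08, 1.2, 1.29, 1.1, 0.11)
_t1("numN", "total", 265.31, 437.36, 469.55, 497.59, 712.0, 470.0, 67.82)
_t1("numN", "1", 365.04, 455.96, 475.64, 505.64, 584.17, 480.0, 46.06)
_t1("numN", "2", 309.03, 424.84, 452.67, 470.42, 498.59, 444.0, 40.3)
_t1("numN", "3", 265.31, 427.54, 508.77, 572.97, 712.0, 494.0, 115.7)
_t1("flow", "total", 26.1, 38.76, 40.77, 42.75, 64.03, 40.9, 5.3)
_t1("flow", "1", 31.1, 38.99, 40.31, 41.53, 46.59, 40.0, 2.94)
_t1("flow", "2", 29.53, 39.43, 40.9, 42.6, 50.07, 40.6, 4.04)
_t1("flow", "3", 26.1, 38.03, 41.99, 47.68, 64.03, 43.3, 9.18)
_t1("sumL", "total", 0.2, 2.94, 10.36, 29.32, 107.44, 18.3, 22.55)
_t1("sumL", "1", 1.66, 6.7, 20.0, 34.3, 107.44, 28.3, 27.8)
_t1("sumL", "2", 1.47, 4.38, 11.45, 18.99, 55.76, 15.7, 14.72)
_t1("sumL", "3", 0.2, 0.7, 1.08, 2.61, 10.48, 2.21, 2.57)
_t1("avgW", "total", 11.42, 20.26, 21.88, 24.32, 54.11, 22.8, 5.37)
_t1("avgW", "1", 16.83, 20.07, 21.29, 22.31, 29.05, 21.5, 2.2)
_t1("avgW", "2", 17.69, 21.09, 22.13, 23.92, 29.02, 22.5, 2.72)
_t1("avgW", "3", 11.42, 19.76, 24.96, 29.1, 54.11, 25.8, 10.32)

#: distribution family per parameter, from the printed mean-vs-median skew
FAMILY = {
    "area": "lognormal",
    "sumL": "lognormal",
    "avgW": "lognormal",
    "fd": "normal",
    "numN": "normal",
    "flow": "normal",
}


@dataclass(frozen=True)
class DistributionSpec:
    """A moment-matched marginal distribution for one parameter × MNV type.

    For the log-normal family the underlying normal parameters are obtained
    in closed form from the printed mean m and SD s:

        sigma² = ln(1 + (s/m)²),   mu = ln(m) − sigma²/2

    so the analytic mean and SD reproduce the printed values exactly.  The
    normal family is (m, s) directly, truncated at 0 when sampling.
    """

    parameter: str
    mnv_type: int
    family: str  # "lognormal" | "normal"
    loc: float
    scale: float
    source_mean: float
    source_sd: float
    source_quartiles: tuple = ()

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def analytic_mean(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.loc + 0.5 * self.scale**2)
        return self.loc

    @property
    def analytic_sd(self) -> float:
        if self.family == "lognormal":
            return self.analytic_mean * math.sqrt(math.expm1(self.scale**2))
        return self.scale

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            return rng.lognormal(self.loc, self.scale, size=n)
        # truncated-at-0 normal by resampling (negligible mass below 0 for
        # all published cells, so the moments are effectively unchanged)
        out = rng.normal(self.loc, self.scale, size=n)
        while np.any(out <= 0):
            bad = out <= 0
            out[bad] = rng.normal(self.loc, self.scale, size=int(bad.sum()))
        return out


def fit_parameter_distributions(
    stats: Optional[dict] = None,
) -> dict[tuple[str, int], DistributionSpec]:
    """Moment-match a distribution to every parameter × type cell (18 specs)."""
    stats = stats if stats is not None else PUBLISHED_SUMMARY_STATS
    specs = {}
    for param, family in FAMILY.items():
        for t in (1, 2, 3):
            cell = stats[(param, str(t))]
            mean, sd = cell["mean"], cell["sd"]
            if sd <= 0:
                raise ValueError(f"{param} type {t}: SD must be > 0")
            if family == "lognormal":
                if mean <= 0:
                    raise ValueError(f"{param} type {t}: lognormal needs mean > 0")
                sigma2 = math.log1p((sd / mean) ** 2)
                mu = math.log(mean) - 0.5 * sigma2
                loc, scale = mu, math.sqrt(sigma2)
            else:
                loc, scale = mean, sd
            specs[(param, t)] = DistributionSpec(
                parameter=param, mnv_type=t, family=family, loc=loc, scale=scale,
                source_mean=mean, source_sd=sd,
                source_quartiles=(cell["q1"], cell["median"], cell["q3"]),
            )
    return specs


def sample_cohort(
    specs: Optional[dict] = None,
    n_per_type: tuple[int, int, int] = (39, 32, 19),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw a per-eye cohort table at the study's group sizes (default 90 eyes).

    Draws are independent across parameters and types (marginal calibration
    only), reproducible under ``seed``.  Columns match the metrics CSV plus
    ``mnv_type``.
    """
    specs = specs if specs is not None else fit_parameter_distributions()
    missing = [(p, t) for p in FAMILY for t in (1, 2, 3) if (p, t) not in specs]
    if missing:
        raise ValueError(f"missing distribution specs for cells: {missing}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    frames = []
    for t, n in zip((1, 2, 3), n_per_type):
        data = {"id": [f"t{t}-{i:03d}" for i in range(1, n + 1)], "mnv_type": t}
        frame = pd.DataFrame(data)
        for param in FAMILY:  # fixed draw order for reproducibility
            frame[PARAM_COLUMNS[param]] = specs[(param, t)].sample(n, rng)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# image-level phantom generator
# --------------------------------------------------------------------------


@dataclass
class SyntheticLesionSpec:
    """Parameters of one synthetic branching-lesion phantom.

    Defaults emulate a mid-sized type-1-like lesion at 12 µm/px: ~2.4 mm²
    mask, 30 µm root vessels tapering by 0.85 per branching, one growth step
    of 3 px with ±12° heading jitter, a 12% bifurcation chance per step at a
    ±55° opening angle, on a 0.15 background with 20% multiplicative speckle.
    """

    target_area_mm2: float = 2.4
    root_caliber_um: float = 30.0
    caliber_taper_ratio: float = 0.85
    step_length_px: float = 3.0
    bifurcation_probability: float = 0.12
    branch_angle_deg: float = 55.0
    angle_jitter_deg: float = 12.0
    background_level: float = 0.15
    speckle_sd: float = 0.2
    n_roots: Optional[int] = None  # None → 1-3 at random
    initial_heading_deg: Optional[float] = None  # None → random per root
    min_steps_between_branches: int = 3
    #: grow additional roots until the centerline length per lesion area
    #: reaches this density (mm per mm²); MNV networks are dense webs, not
    #: single trees.  0 disables re-rooting.
    target_length_density: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if min(self.target_area_mm2, self.root_caliber_um, self.step_length_px) <= 0:
            raise ValueError("lesion spec lengths must be positive")
        if not 0 <= self.bifurcation_probability < 1:
            raise ValueError("bifurcation_probability must be in [0, 1)")
        if not 0.5 < self.caliber_taper_ratio <= 1:
            raise ValueError("caliber_taper_ratio must be in (0.5, 1]")


@dataclass
class GroundTruth:
    """Exact morphometrics of a generated phantom, from its geometry."""

    area_mm2: float
    sumL_mm: float
    numN: int
    avgW_um: float
    polylines: list[np.ndarray] = field(default_factory=list)
    node_positions: list[tuple[float, float]] = field(default_factory=list)


def _elliptical_mask(
    shape: tuple[int, int], area_px: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    aspect = rng.uniform(0.65, 1.0)
    theta = rng.uniform(0, math.pi)
    # pi * a * b = area, b = aspect * a
    a = math.sqrt(area_px / (math.pi * aspect))
    b = aspect * a
    cy = h / 2 + rng.uniform(-h * 0.05, h * 0.05)
    cx = w / 2 + rng.uniform(-w * 0.05, w * 0.05)
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy - cy, xx - cx
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stamp_tube(canvas: np.ndarray, p0, p1, radius_px: float) -> None:
    """Rasterize one centerline step as a tube of the given radius."""
    h, w = canvas.shape
    n = max(2, int(math.ceil(np.hypot(p1[0] - p0[0], p1[1] - p0[1]) / 0.5)) + 1)
    r = max(radius_px, 0.5)
    ri = int(math.ceil(r))
    for t in np.linspace(0.0, 1.0, n):
        cy = p0[0] + t * (p1[0] - p0[0])
        cx = p0[1] + t * (p1[1] - p0[1])
        y0, y1 = max(int(cy - ri), 0), min(int(cy + ri) + 2, h)
        x0, x1 = max(int(cx - ri), 0), min(int(cx + ri) + 2, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_lesion_image(
    spec: SyntheticLesionSpec,
    geometry: ScanGeometry = ScanGeometry(),
) -> tuple[EnFaceImage, np.ndarray, GroundTruth]:
    """Grow, rasterize and degrade one synthetic MNV phantom.

    Vessel tips start at 1-3 root points near the lesion center and advance
    in steps of ``step_length_px`` with Gaussian heading jitter; at each step
    a tip may bifurcate into two children at ±branch_angle/2 whose calibers
    shrink by the taper ratio.  Tips stop at the mask boundary or when the
    caliber falls below one pixel.  Each centerline is rasterized as a bright
    tube of its caliber; the frame is then multiplied by gamma speckle of
    unit mean and ``speckle_sd`` and offset by the background level.

    Returns the image, the lesion mask, and exact :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    pitch = geometry.pixel_pitch_um
    n = geometry.grid_px
    area_px = spec.target_area_mm2 / geometry.pixel_area_mm2
    if area_px < 9:
        raise ValueError("target area too small to place a vessel root")
    mask = _elliptical_mask((n, n), area_px, rng)
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()

    n_roots = spec.n_roots if spec.n_roots is not None else int(rng.integers(1, 4))
    root_r_px = spec.root_caliber_um / pitch
    jitter = math.radians(spec.angle_jitter_deg)
    half_branch = math.radians(spec.branch_angle_deg) / 2.0

    tips = []

    def _root_tip(pos, heading):
        # cooldown 0: roots get no collision grace — that exists only for
        # freshly spawned siblings at a bifurcation
        return {"pos": pos, "heading": heading, "caliber_px": root_r_px,
                "cooldown": 0, "polyline": [pos], "event": None,
                "branch_len_px": 0.0}

    for _ in range(n_roots):
        ang = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0, 0.15) * math.sqrt(area_px / math.pi)
        pos = (cy + off * math.sin(ang), cx + off * math.cos(ang))
        heading = (rng.uniform(0, 2 * math.pi)
                   if spec.initial_heading_deg is None
                   else math.radians(spec.initial_heading_deg))
        tips.append(_root_tip(pos, heading))

    vessel = np.zeros((n, n), dtype=bool)
    polylines: list[np.ndarray] = []
    sum_len_px = 0.0
    cal_len_px = 0.0  # Σ length × caliber, for the length-weighted mean
    # a bifurcation only counts as a ground-truth node if both daughter
    # branches draw enough length to survive spur pruning downstream
    events: list[dict] = []  # per bifurcation: position + drawn daughter lengths
    max_tips = 4096

    def _collides(nxt, pos, prev, radius_px, spawn=None, spawn_ignore_px=0.0):
        """True if the step's stamp would touch vasculature that is not the
        tip's own immediate trail — keeps branches spaced apart so junctions
        arise only at recorded bifurcation events.

        The probe is a disk ahead of the tip; pixels behind the step
        direction or hugging the current position are the tip's own stamp
        and are ignored.  Right after a bifurcation, pixels near the spawn
        point (the sibling's early corridor) are ignored as well.
        """
        rc = radius_px + 2.3
        ri = int(math.ceil(rc))
        y0, y1 = max(int(nxt[0]) - ri, 0), min(int(nxt[0]) + ri + 2, n)
        x0, x1 = max(int(nxt[1]) - ri, 0), min(int(nxt[1]) + ri + 2, n)
        if y0 >= y1 or x0 >= x1:
            return False
        win = vessel[y0:y1, x0:x1]
        if not win.any():
            return False
        yy, xx = np.mgrid[y0:y1, x0:x1]
        near_nxt = (yy - nxt[0]) ** 2 + (xx - nxt[1]) ** 2 <= rc * rc
        # the tip's own stamp: a capsule around its previous step
        a = prev if prev is not None else pos
        dy, dx = pos[0] - a[0], pos[1] - a[1]
        seg2 = dy * dy + dx * dx
        if seg2 > 0:
            t = np.clip(((yy - a[0]) * dy + (xx - a[1]) * dx) / seg2, 0.0, 1.0)
        else:
            t = 0.0
        own = ((yy - (a[0] + t * dy)) ** 2 + (xx - (a[1] + t * dx)) ** 2
               <= (radius_px + 1.2) ** 2)
        hits = win & near_nxt & ~own
        if spawn is not None and spawn_ignore_px > 0:
            near_spawn = ((yy - spawn[0]) ** 2 + (xx - spawn[1]) ** 2
                          <= spawn_ignore_px**2)
            hits &= ~near_spawn
        return bool(np.any(hits))

    lesion_area_mm2 = int(mask.sum()) * geometry.pixel_area_mm2
    target_len_px = spec.target_length_density * lesion_area_mm2 * 1000.0 / pitch
    mask_coords = np.argwhere(mask)
    extra_roots = 0
    clear_rad = int(math.ceil(root_r_px / 2 + 3))

    while True:
        if not tips:
            # lesion not yet at the target vascular density: sprout another
            # root at a clear spot, as MNV feeds from multiple ingrowth sites
            if (spec.target_length_density <= 0 or sum_len_px >= target_len_px
                    or extra_roots >= 200):
                break
            placed = False
            for _ in range(60):
                r_, c_ = map(int, mask_coords[rng.integers(len(mask_coords))])
                y0, y1 = max(r_ - clear_rad, 0), min(r_ + clear_rad + 1, n)
                x0, x1 = max(c_ - clear_rad, 0), min(c_ + clear_rad + 1, n)
                if not vessel[y0:y1, x0:x1].any():
                    tips.append(_root_tip((float(r_), float(c_)),
                                          rng.uniform(0, 2 * math.pi)))
                    placed = True
                    extra_roots += 1
                    break
            if not placed:
                break
            continue
        tip = tips.pop(0)
        pos, heading = tip["pos"], tip["heading"]
        caliber = tip["caliber_px"]
        cooldown = tip["cooldown"]
        poly = tip["polyline"]
        event = tip["event"]
        branch_len = tip["branch_len_px"]
        spawn = poly[0]
        prev_pos = poly[-2] if len(poly) > 1 else None
        while True:
            if caliber < 1.0:
                break
            heading = heading + rng.normal(0.0, jitter)
            nxt = (pos[0] + spec.step_length_px * math.sin(heading),
                   pos[1] + spec.step_length_px * math.cos(heading))
            iy, ix = int(round(nxt[0])), int(round(nxt[1]))
            if not (0 <= iy < n and 0 <= ix < n and mask[iy, ix]):
                break
            # right after a bifurcation the sibling branch is legitimately
            # close; exempt the spawn neighbourhood rather than skipping
            # the collision check outright
            ignore_px = (
                branch_len + spec.step_length_px + caliber / 2.0 + 1.5
                if cooldown > 0
                else 0.0
            )
            if _collides(nxt, pos, prev_pos, caliber / 2.0, spawn=spawn,
                         spawn_ignore_px=ignore_px):
                break
            _stamp_tube(vessel, pos, nxt, caliber / 2.0)
            sum_len_px += spec.step_length_px
            cal_len_px += spec.step_length_px * caliber
            branch_len += spec.step_length_px
            prev_pos = pos
            pos = nxt
            poly.append(pos)
            if cooldown > 0:
                cooldown -= 1
            elif (rng.uniform() < spec.bifurcation_probability
                  and caliber * spec.caliber_taper_ratio >= 1.0
                  and len(tips) < max_tips):
                if event is not None:
                    events[event]["lens"].append(branch_len)
                child_cal = caliber * spec.caliber_taper_ratio
                # a daughter's centerline runs inside the parent tube for
                # about r_parent / sin(branch_angle/2) before it emerges;
                # only the emerged part can survive thinning + spur pruning
                buried = (caliber / 2.0) / max(math.sin(half_branch), 1e-6)
                events.append({
                    "pos": pos,
                    "lens": [],
                    "min_visible_px": 1.0 + buried + child_cal / 2.0,
                })
                event = len(events) - 1
                branch_len = 0.0
                tips.append({"pos": pos, "heading": heading + half_branch,
                             "caliber_px": child_cal,
                             "cooldown": spec.min_steps_between_branches,
                             "polyline": [pos], "event": event,
                             "branch_len_px": 0.0})
                # current tip continues as the second child
                heading = heading - half_branch
                caliber = child_cal
                cooldown = spec.min_steps_between_branches
                spawn = pos
        if event is not None:
            events[event]["lens"].append(branch_len)
        if len(poly) > 1:
            polylines.append(np.asarray(poly))

    vessel &= mask
    # visible bifurcations: both daughters drew more than a spur's length
    visible = [e for e in events
               if len(e["lens"]) == 2 and min(e["lens"]) >= e["min_visible_px"]]
    n_bifurcations = len(visible)
    truth = GroundTruth(
        area_mm2=lesion_area_mm2,
        sumL_mm=sum_len_px * pitch / 1000.0,
        numN=n_bifurcations,
        avgW_um=(cal_len_px / sum_len_px * pitch) if sum_len_px > 0 else float("nan"),
        polylines=polylines,
        node_positions=[e["pos"] for e in visible],
    )

    # intensity model: bright tubes over a dark floor, gamma speckle (unit
    # mean, sd = speckle_sd) multiplying everything, as in OCT-type imagery
    base = np.where(vessel, 1.0, spec.background_level).astype(np.float64)
    if spec.speckle_sd > 0:
        shape_k = 1.0 / spec.speckle_sd**2
        speckle = rng.gamma(shape_k, 1.0 / shape_k, size=base.shape)
        base = base * speckle
    base = np.clip(base, 0.0, None)
    image = EnFaceImage(pixels=base, geometry=geometry)
    return image, mask, truth


def recovery_report(
    n_phantoms: int,
    spec_family: str = "type1",
    seed: int = 0,
    geometry: ScanGeometry = ScanGeometry(),
    config=None,
) -> pd.DataFrame:
    """Ground-truth vs pipeline estimates over seeded phantoms.

    ``spec_family`` selects a preset lesion scale ("type1" mid-size lesions,
    "type3" small tufts, "tube" a single unbranched vessel).  Returns one row
    per phantom × metric with truth, estimate and relative error; aggregate
    with pandas as needed.
    """
    from .metrics import compute_all  # local import to avoid module cycle

    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    presets = {
        "type1": {},
        "type3": {"target_area_mm2": 0.3, "root_caliber_um": 50.0,
                  "bifurcation_probability": 0.2, "n_roots": 1},
        # axis-aligned unbranched control: isolates the digitization floor
        # (8-connected path length is exact on axis-aligned lines)
        "tube": {"bifurcation_probability": 0.0, "n_roots": 1,
                 "angle_jitter_deg": 0.0, "initial_heading_deg": 45.0,
                 "target_length_density": 0.0},
    }
    if spec_family not in presets:
        raise ValueError(f"unknown spec_family {spec_family!r}")
    rows = []
    for i in range(n_phantoms):
        spec = SyntheticLesionSpec(seed=seed + i, **presets[spec_family])
        image, mask, truth = generate_lesion_image(spec, geometry)
        est = compute_all(image, mask, config)
        truth_map = {
            "area_mm2": truth.area_mm2,
            "sumL_mm": truth.sumL_mm,
            "numN": float(truth.numN),
            "avgW_um": truth.avgW_um,
        }
        est_area = est.area_mm2
        est_map = {
            "area_mm2": est.area_mm2,
            "sumL_mm": est.sumL_mm,
            "numN": est.numN_per_mm2 * est_area,
            "avgW_um": est.avgW_um,
        }
        for metric, tval in truth_map.items():
            eval_ = est_map[metric]
            rel = (eval_ - tval) / tval if tval != 0 else float("nan")
            rows.append({"phantom": i, "seed": seed + i, "metric": metric,
                         "truth": tval, "estimate": eval_, "rel_error": rel})
        rows.append({"phantom": i, "seed": seed + i, "metric": "fd",
                     "truth": float("nan"), "estimate": est.fd,
                     "rel_error": float("nan")})
        rows.append({"phantom": i, "seed": seed + i, "metric": "flow_pct",
                     "truth": float("nan"), "estimate": est.flow_pct,
                     "rel_error": float("nan")})
    return pd.DataFrame(rows)
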