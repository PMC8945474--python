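"""Vessel extraction: tubularity enhancement, binarization, thinning, calibers.

The pathologic vessel network of a macular neovascularization shows up on the
en-face angiogram as a web of bright curvilinear ridges over speckle.  The
pipeline here is the standard one for such images: a Hessian-eigenvalue
(Frangi-style) multiscale tubularity filter, an in-lesion Otsu threshold, a
topology-preserving morphological thinning to one-pixel centerlines, and a
Euclidean distance transform for per-centerline-pixel vessel diameters.

Everything in this module is deterministic given its inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io import EnFaceImage, ScanGeometry, validate_mask

__all__ = [
    "enhance_vessels",
    "binarize",
    "skeletonize",
    "prune_spurs",
    "estimate_calibers",
    "neighbor_counts",
]

# 8-neighborhood offsets in fixed raster order (ties resolved deterministically)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def enhance_vessels(
    image: EnFaceImage | np.ndarray,
    mask: np.ndarray,
    scales_px: list[float] = (1.0, 2.0),
    beta: float = 0.5,
    return_scales: bool = False,
):
    """Multiscale Hessian tubularity (bright-ridge) response inside the lesion.

    At each scale ``s`` the image is smoothed with a Gaussian of that width,
    the Hessian eigenvalues ``|l1| <= |l2|`` are computed with gamma-normalised
    (``s**2``) derivatives, and the Frangi vesselness

        V_s = exp(-(l1/l2)**2 / (2 beta**2)) * (1 - exp(-S**2 / (2 c**2)))

    is evaluated where ``l2 < 0`` (bright ridge), with ``S = sqrt(l1^2+l2^2)``
    and ``c`` set to half the maximum of ``S`` at that scale.  The output is
    the per-pixel maximum over scales, zeroed outside the lesion mask.

    Parameters
    ----------
    scales_px : list of float
        Gaussian scales in pixels, each >= 0.5; defaults cover calibers of
        roughly 1-2.5 px (12-30 µm at 12 µm/px), where MNV calibers
        concentrate.
    return_scales : bool
        If true, also return the argmax scale per pixel (0 where response 0).
    """
    pixels = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image)
    mask = validate_mask(mask, pixels.shape)
    scales = [float(s) for s in scales_px]
    if len(scales) == 0:
        raise ValueError("scales_px must be nonempty")
    if any(s < 0.5 for s in scales):
        raise ValueError(f"all scales must be >= 0.5 px, got {scales}")

    img = pixels.astype(np.float64)
    best = np.zeros_like(img)
    best_scale = np.zeros_like(img)
    for s in scales:
        h = hessian_matrix(img, sigma=s, order="rc", mode="reflect",
                           use_gaussian_derivatives=True)
        l1, l2 = hessian_matrix_eigvals(h)  # l1 >= l2 by value
        # reorder by magnitude: |l1| <= |l2|
        swap = np.abs(l1) > np.abs(l2)
        l1s = np.where(swap, l2, l1)
        l2s = np.where(swap, l1, l2)
        l1s *= s * s  # gamma-normalisation so responses compare across scales
        l2s *= s * s
        S2 = l1s * l1s + l2s * l2s
        c = 0.5 * np.sqrt(S2.max())
        if c == 0:  # constant image: no second-order structure anywhere
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2s != 0, (l1s / np.where(l2s != 0, l2s, 1)) ** 2, 0.0)
        v = np.exp(-rb2 / (2 * beta * beta)) * (1.0 - np.exp(-S2 / (2 * c * c)))
        v = np.where(l2s < 0, v, 0.0)
        take = v > best
        best_scale = np.where(take, s, best_scale)
        best = np.where(take, v, best)
    best[~mask] = 0.0
    best_scale[~mask] = 0.0
    if return_scales:
        return best, best_scale
    return best


def binarize(
    vesselness: np.ndarray,
    mask: np.ndarray,
    method: str | float = "otsu_in_mask",
    closing_radius: int = 1,
    min_object_px: int = 5,
    max_hole_px: int = 4,
) -> np.ndarray:
    """Threshold a response map into a perfused-pixel (vessel) map.

    The threshold is computed from in-mask pixels only — Otsu over the whole
    frame would be dominated by the empty background.  After thresholding, a
    morphological closing (disk of ``closing_radius`` px) bridges one-pixel
    gaps the ridge filter leaves at vessel crossings, interior holes of at
    most ``max_hole_px`` pixels (dark speckle punched through a vessel) are
    filled, and connected components smaller than ``min_object_px`` are
    dropped as speckle.  Each cleanup can be disabled with 0.  The result is
    always a subset of the mask.
    """
    vesselness = np.asarray(vesselness, dtype=np.float64)
    mask = validate_mask(mask, vesselness.shape)
    if not np.all(np.isfinite(vesselness)):
        raise ValueError("vesselness map contains non-finite values")
    inside = vesselness[mask]
    if isinstance(method, str):
        if method != "otsu_in_mask":
            raise ValueError(f"unknown binarization method {method!r}")
        if np.unique(inside).size < 2:
            raise ValueError("otsu_in_mask needs >= 2 distinct in-mask values")
        thr = threshold_otsu(inside)
    else:
        thr = float(method)
    vessels = (vesselness > thr) & mask
    if closing_radius > 0 and vessels.any():
        r = int(closing_radius)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (yy * yy + xx * xx) <= r * r
        vessels = ndimage.binary_closing(vessels, structure=disk) & mask
    if max_hole_px > 0 and vessels.any():
        holes, n_h = ndimage.label(~vessels, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(holes.ravel())
        small = sizes <= max_hole_px
        # the background (touching the frame border) is never a hole
        border = np.zeros(n_h + 1, dtype=bool)
        border[np.unique(np.concatenate([
            holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))] = True
        fill = small & ~border
        fill[0] = False
        vessels = (vessels | fill[holes]) & mask
    if min_object_px > 0 and vessels.any():
        lab, n = ndimage.label(vessels, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_px
        keep[0] = False
        vessels = keep[lab]
    return vessels


def neighbor_counts(binary: np.ndarray) -> np.ndarray:
    """Number of set 8-neighbors for every pixel of a binary grid."""
    b = np.asarray(binary, dtype=bool)
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(b.astype(int), k, mode="constant", cval=0)


def _crossing_number(patch: np.ndarray) -> int:
    """Connectivity transitions around a 3×3 neighborhood (Hilditch)."""
    ring = [patch[0, 0], patch[0, 1], patch[0, 2], patch[1, 2],
            patch[2, 2], patch[2, 1], patch[2, 0], patch[1, 0]]
    n = 0
    for i in range(8):
        if not ring[i] and ring[(i + 1) % 8]:
            n += 1
    return n


def skeletonize(vessels: np.ndarray, prune_spur_px: int = 3) -> np.ndarray:
    """Thin a vessel map to 8-connected one-pixel-wide centerlines.

    Morphological thinning preserves topology; terminal spurs shorter than
    ``prune_spur_px`` (a thinning artifact at vessel boundaries) are then
    removed iteratively.  Pruning only ever removes branch tips hanging off a
    junction — it cannot split or delete a connected component.  Residual
    fully-set 2×2 blocks (rare thinning leftovers) are cleaned by removing a
    deletable pixel in fixed raster order, so the result is bit-reproducible.
    """
    vessels = np.asarray(vessels, dtype=bool)
    if not vessels.any():
        raise ValueError("empty vessel map")

    def _thin_fixpoint(b):
        # thinning and 2×2 cleanup can each expose corner pixels the other
        # would remove; iterate to a fixpoint so the result is idempotent
        prev = None
        while prev is None or not np.array_equal(prev, b):
            prev = b
            b = _remove_2x2_blocks(_skimage_skeletonize(b))
        return b

    skel = _thin_fixpoint(vessels)
    if prune_spur_px > 0:
        skel = prune_spurs(skel, prune_spur_px)
        if skel.any():
            skel = _thin_fixpoint(skel)
    return skel


def _remove_2x2_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove pixels forming fully-set 2×2 blocks where removal is safe."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        block = (skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:])
        rows, cols = np.nonzero(block)
        for r, c in zip(rows.tolist(), cols.tolist()):
            # try the four block pixels in raster order; delete the first
            # whose removal keeps its neighborhood connected
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not skel[rr, cc]:
                    continue
                patch = np.zeros((3, 3), dtype=bool)
                r0, r1 = max(rr - 1, 0), min(rr + 2, skel.shape[0])
                c0, c1 = max(cc - 1, 0), min(cc + 2, skel.shape[1])
                patch[r0 - rr + 1 : r1 - rr + 1, c0 - cc + 1 : c1 - cc + 1] = skel[r0:r1, c0:c1]
                patch[1, 1] = False
                if _crossing_number(patch) == 1:
                    skel[rr, cc] = False
                    changed = True
                    break
    return skel


def prune_spurs(skel: np.ndarray, max_len_px: int) -> np.ndarray:
    """Iteratively delete terminal branches shorter than ``max_len_px`` pixels.

    A spur is the chain of pixels from an endpoint up to (excluding) the first
    junction pixel.  Chains ending at another endpoint (isolated lines) are
    never removed, so connected components are preserved.
    """
    skel = np.asarray(skel, dtype=bool).copy()

    def _nbrs(p, exclude=None):
        out = []
        for dr, dc in _OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                if q != exclude:
                    out.append(q)
        return out

    changed = True
    while changed:
        changed = False
        counts = neighbor_counts(skel)
        endpoints = sorted(map(tuple, np.argwhere(skel & (counts == 1)).tolist()))
        for start in endpoints:
            if not skel[start]:
                continue
            # walk from the tip until a junction pixel (>= 3 live neighbors)
            path = [start]
            prev, cur = None, start
            hit_junction = False
            while len(path) <= max_len_px:
                if len(_nbrs(cur)) >= 3:
                    hit_junction = True
                    path.pop()  # the junction itself stays
                    break
                nxt = _nbrs(cur, exclude=prev)
                if not nxt:
                    break  # chain ends at another endpoint: keep it
                prev, cur = cur, nxt[0]
                path.append(cur)
            if hit_junction and 0 < len(path) < max_len_px:
                for p in path:
                    skel[p] = False
                changed = True
                counts = neighbor_counts(skel)
    return skel


def estimate_calibers(
    vessels: np.ndarray, skeleton: np.ndarray, geometry: ScanGeometry
) -> np.ndarray:
    """Per-centerline-pixel vessel diameter in µm via the distance transform.

    ``diameter(p) = 2 * EDT(p) * pitch`` where EDT is the Euclidean distance
    from centerline pixel ``p`` to the nearest background pixel of the vessel
    map.  A one-pixel-wide line therefore reads 2 px (24 µm at 12 µm/px) —
    the resolution floor of the estimator.  Returns an array with NaN off the
    skeleton.
    """
    vessels = np.asarray(vessels, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if np.any(skeleton & ~vessels):
        raise ValueError("skeleton pixel outside vessel map")
    edt = ndimage.distance_transform_edt(vessels)
    pitch = geometry.pixel_pitch_um
    calibers = np.full(vessels.shape, np.nan)
    calibers[skeleton] = 2.0 * edt[skeleton] * pitch
    return calibers
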