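"""Raster and table I/O plus scan-geometry bookkeeping.

An en-face OCTA scan is a square raster covering a known field of view on the
retina; all physical quantities downstream (areas in mm², lengths in mm,
calibers in µm) derive from the pixel pitch, so the pitch is computed once,
exactly, from the field of view and grid size and carried alongside the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ScanGeometry",
    "EnFaceImage",
    "load_image",
    "load_mask",
    "write_metrics_csv",
    "read_metrics_csv",
    "METRIC_COLUMNS",
]

#: Column order of a per-lesion metrics table.
METRIC_COLUMNS = [
    "id",
    "mnv_type",
    "area_mm2",
    "fd",
    "numN_per_mm2",
    "flow_pct",
    "sumL_mm",
    "avgW_um",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a square en-face scan.

    Parameters
    ----------
    field_of_view_mm : float
        Side length of the scanned field on the retina, in millimetres.
        The default corresponds to the common 6 × 6 mm macular protocol.
    grid_px : int
        Number of pixels (A-scan positions) along each side.

    Notes
    -----
    The pixel pitch is derived, never stored: ``1000 * field_of_view_mm /
    grid_px`` micrometres per pixel, evaluated as an exact rational before
    conversion to float (6 mm / 500 px → 12 µm/px exactly).
    """

    field_of_view_mm: float = 6.0
    grid_px: int = 500

    def __post_init__(self) -> None:
        if not self.field_of_view_mm > 0:
            raise ValueError(f"field_of_view_mm must be > 0, got {self.field_of_view_mm}")
        if int(self.grid_px) != self.grid_px or self.grid_px < 16:
            raise ValueError(f"grid_px must be an integer >= 16, got {self.grid_px}")

    @property
    def pixel_pitch_um(self) -> float:
        """Micrometres per pixel, exact rational arithmetic before float."""
        return float(Fraction(1000) * Fraction(self.field_of_view_mm) / Fraction(self.grid_px))

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel cell in mm² (pixels are area elements)."""
        pitch_mm = Fraction(self.field_of_view_mm) / Fraction(self.grid_px)
        return float(pitch_mm * pitch_mm)


@dataclass
class EnFaceImage:
    """A single-channel en-face OCTA raster with its scan geometry.

    Intensities are arbitrary linear units (device export; bit depth is not
    normalised).  ``quality_score`` carries the device quality metadata used
    for cohort exclusion upstream; it does not affect any computation here.
    """

    pixels: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    quality_score: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"en-face image must be 2-D single-channel, got shape {px.shape}")
        if not np.all(np.isfinite(px.astype(np.float64))):
            raise ValueError("en-face image contains non-finite intensities")
        if np.any(px.astype(np.float64) < 0):
            raise ValueError("en-face image contains negative intensities")
        expected = (self.geometry.grid_px, self.geometry.grid_px)
        if px.shape != expected:
            raise ValueError(
                f"image shape {px.shape} does not match scan geometry grid {expected}; "
                "pass a ScanGeometry matching the raster"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path: str | Path, geometry: ScanGeometry = ScanGeometry()) -> EnFaceImage:
    """Load a grayscale PNG/TIFF raster as an :class:`EnFaceImage`.

    Intensities are preserved bit-exactly; 16-bit inputs are not rescaled.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    multi-channel raster or a raster whose shape disagrees with *geometry*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    px = iio.imread(path)
    if px.ndim != 2:
        raise ValueError(
            f"{path.name}: expected grayscale single-channel raster, got shape {px.shape}"
        )
    return EnFaceImage(pixels=px, geometry=geometry)


def load_mask(path: str | Path, image: EnFaceImage) -> np.ndarray:
    """Load a lesion (MNV) mask companion to *image*.

    Any nonzero pixel counts as inside the lesion.  Returns a boolean array of
    the image's shape.  An all-zero mask is rejected: every metric downstream
    divides by lesion area.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    px = iio.imread(path)
    if px.ndim != 2:
        raise ValueError(f"{path.name}: mask must be single-channel, got shape {px.shape}")
    if px.shape != image.shape:
        raise ValueError(
            f"mask shape {px.shape} does not match image shape {image.shape}"
        )
    mask = px != 0
    validate_mask(mask, image.shape)
    return mask


def validate_mask(mask: np.ndarray, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Check lesion-mask invariants (boolean, 2-D, nonempty, shape match)."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask != 0
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match expected {tuple(shape)}")
    if not mask.any():
        raise ValueError("empty lesion mask")
    return mask


def write_metrics_csv(rows: Sequence[dict], path: str | Path) -> None:
    """Write per-lesion metrics to CSV with the canonical column order.

    Each row is a mapping with keys ``id, mnv_type, area_mm2, fd,
    numN_per_mm2, flow_pct, sumL_mm, avgW_um``.  Values round-trip losslessly
    (floats are written at full precision, well beyond 6 significant digits).
    Duplicate ids are rejected.
    """
    df = pd.DataFrame(list(rows))
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics rows missing columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
        raise ValueError(f"duplicate lesion ids: {dupes}")
    df[METRIC_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-lesion metrics table written by :func:`write_metrics_csv`."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate lesion ids in metrics CSV")
    return df[METRIC_COLUMNS]
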