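"""Run configuration: every knob of the measurement pipeline, serializable.

A config hash is embedded in every output file so that two runs can be
checked for comparability; equal hashes + equal seeds imply byte-identical
outputs (the pipeline itself is deterministic).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .io import ScanGeometry

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline parameters with their defaults.

    scales_px
        Tubularity-filter scales; the defaults target the 1-2.5 px caliber
        band where the printed caliber quartiles concentrate at 12 µm/px
        (larger scales fatten the response of thin vessels).
    binarize_source
        ``"vesselness"`` thresholds the tubularity response (default);
        ``"intensity"`` thresholds the raw angiogram inside the mask.
    binarize_method / binarize_threshold
        ``"otsu_in_mask"`` (adaptive, default) or ``"fixed"`` with the given
        absolute threshold.
    closing_radius_px / min_object_px
        Post-threshold cleanup: closing bridges 1-px gaps at crossings,
        small-object removal drops speckle islands; 0 disables either.
    prune_spur_px
        Terminal spurs shorter than this are removed after thinning.
    junction_merge_px
        Dilation radius when fusing nearby junction pixels into one node.
    fd_multi_offset
        Average box counts over all grid offsets instead of the anchored grid.
    alpha
        Significance level of the group-comparison branch logic.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    scales_px: tuple = (1.0, 2.0)
    binarize_source: str = "vesselness"
    binarize_method: str = "otsu_in_mask"
    binarize_threshold: float = 0.5
    closing_radius_px: int = 1
    min_object_px: int = 5
    max_hole_px: int = 4
    prune_spur_px: int = 3
    junction_merge_px: int = 1
    fd_multi_offset: bool = False
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = {
            "field_of_view_mm": self.geometry.field_of_view_mm,
            "grid_px": self.geometry.grid_px,
        }
        d["scales_px"] = list(self.scales_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo = d.pop("geometry", {})
        return cls(geometry=ScanGeometry(**geo), **{
            k: (tuple(v) if k == "scales_px" else v) for k, v in d.items()
        })

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def hash(self) -> str:
        """Short sha256 of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
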