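"""Regions of interest: definition, validation, and bit-exact extraction.

All measurements are made inside named, same-size, non-overlapping rectangular
ROIs (the study design uses three 60 × 60 µm squares per section as technical
replicates). Coordinates are 0-based, row-major, half-open:
``[x0, x0+width) × [y0, y0+height)``. ROI placement itself is anatomical
judgment and is supplied by the user (CSV/JSON of centers); this module only
converts physical sizes, validates, and extracts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .image import CalibratedImage


def _round_half_away(x: float) -> int:
    """Round half away from zero (explicit, platform-independent)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Roi:
    """A named half-open pixel rectangle, optionally with intended physical size."""

    name: str
    x0: int
    y0: int
    width: int
    height: int
    intended_size_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"ROI {self.name!r}: width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI {self.name!r}: origin must be non-negative")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def area_px(self) -> int:
        return self.width * self.height

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px() * pixel_size_um**2

    def overlaps(self, other: "Roi") -> bool:
        """Exact overlap test on half-open integer rectangles."""
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    def fits(self, image: CalibratedImage) -> bool:
        h, w = image.shape
        return self.x1 <= w and self.y1 <= h


@dataclass
class RoiSet:
    """Validated collection of same-size, pairwise non-overlapping ROIs."""

    rois: list[Roi]
    placement_note: str = ""
    image_ref: str = ""

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("RoiSet needs at least one ROI")
        sizes = {(r.width, r.height) for r in self.rois}
        if len(sizes) > 1:
            raise ValueError(f"ROIs must share pixel dimensions, got {sorted(sizes)}")
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"ROIs {a.name!r} and {b.name!r} overlap")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)


def make_rois_from_physical(
    image: CalibratedImage,
    centers: list[tuple[float, float]],
    size_um: float = 60.0,
    names: list[str] | None = None,
    placement_note: str = "",
) -> RoiSet:
    """Build square ROIs of a physical edge length centred on pixel points.

    ``size_um`` is the intended physical edge (default 60 µm, the study's ROI
    size); the pixel edge is ``round(size_um / pixel_size)`` with
    round-half-away-from-zero. Bounds and pairwise overlap are validated.
    """
    side = _round_half_away(size_um / image.pixel_size_um)
    if side < 1:
        raise ValueError(f"{size_um} um is below one pixel at this calibration")
    h, w = image.shape
    rois = []
    for i, (cx, cy) in enumerate(centers):
        name = names[i] if names else f"roi{i + 1}"
        x0 = _round_half_away(cx) - side // 2
        y0 = _round_half_away(cy) - side // 2
        if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
            raise ValueError(
                f"ROI {name!r} ({side}x{side} px at ({x0},{y0})) "
                f"falls outside the {h}x{w} image"
            )
        rois.append(Roi(name, x0, y0, side, side, (size_um, size_um)))
    return RoiSet(rois, placement_note=placement_note)


def full_image_roi(image: CalibratedImage, name: str = "full") -> Roi:
    """ROI covering the whole frame (used when each image is one field)."""
    h, w = image.shape
    return Roi(name, 0, 0, w, h)


def extract(image: CalibratedImage, roi: Roi) -> CalibratedImage:
    """Crop the ROI window; never resamples, calibration preserved bit-exactly."""
    if not roi.fits(image):
        raise ValueError(
            f"ROI {roi.name!r} [{roi.x0}:{roi.x1}]x[{roi.y0}:{roi.y1}] "
            f"exceeds image of shape {image.shape}"
        )
    window = image.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1]
    return image.with_pixels(window)


def load_roi_centers(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read ROI centers from CSV (image, cx, cy) or JSON {image: [[cx, cy], ...]}."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return {k: [tuple(map(float, c)) for c in v] for k, v in data.items()}
    df = pd.read_csv(path)
    required = {"image", "cx", "cy"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI CSV needs columns {sorted(required)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image"]), []).append((float(row.cx), float(row.cy)))
    return out
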