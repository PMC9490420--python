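"""Calibrated image container shared by every measurement module.

All pipeline measurements are physical (µm², nuclei/mm², percent area), so a
pixel array travels together with its µm/pixel calibration and acquisition
modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

#: Acquisition modalities the pipeline routes on.
MODALITIES = ("brightfield", "polarized")


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB micrograph with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        RGB pixel data.
    pixel_size_um : float
        Edge length of one pixel in micrometres. Must be positive.
    modality : {"brightfield", "polarized"}
        How the image was acquired; measurement modules validate this.
    """

    pixels: np.ndarray
    pixel_size_um: float
    modality: str = "brightfield"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    @property
    def area_um2(self) -> float:
        """Physical area of the full frame in µm²."""
        h, w = self.shape
        return h * w * self.pixel_size_um**2

    @property
    def area_mm2(self) -> float:
        """Physical area of the full frame in mm²."""
        return self.area_um2 / 1e6

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Copy of this image with new pixel data, calibration preserved."""
        return replace(self, pixels=np.ascontiguousarray(pixels, dtype=np.uint8))

    def save(self, path: str | Path) -> None:
        """Write as 8-bit RGB TIFF or PNG depending on extension."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self.pixels, photometric="rgb")
        else:
            iio.imwrite(path, self.pixels)


def load_image(
    path: str | Path, pixel_size_um: float, modality: str = "brightfield"
) -> CalibratedImage:
    """Read an RGB TIFF/PNG from disk and attach calibration."""
    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    return CalibratedImage(px.astype(np.uint8), pixel_size_um, modality)
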