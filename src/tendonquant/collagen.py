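"""Collagen content and organization as thresholded percentage area fractions.

Content: picrosirius-red (PSR) stained area in brightfield images — the RGB
frame is reduced to an 8-bit "stain strength" image via the PSR optical-
density projection, thresholded, and the positive percentage computed.
Organization: birefringence in polarized-light images — bright, ordered
collagen on a dark background — reduced to 8-bit luminance and thresholded.

One threshold is frozen per metric for an entire batch (all technical and
biological replicates, all stages), so area fractions stay comparable across
the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .image import CalibratedImage
from .roi import Roi, full_image_roi
from .stains import rgb_to_od

#: OD value mapped to gray level 255 in the stain projection; a fixed ceiling
#: (not per-image min-max) keeps one threshold meaningful across a batch.
OD_CEILING = 1.5

#: Unit OD direction of picrosirius red (sirius-red absorbs mostly green/blue;
#: an eosin-like vector). Used only to project OD onto "stain strength".
PSR_VECTOR = np.array([0.104, 0.947, 0.286])
PSR_VECTOR = PSR_VECTOR / np.linalg.norm(PSR_VECTOR)

#: Rec. 601 luma weights for the polarized-signal projection.
_LUMA = np.array([0.299, 0.587, 0.114])

MODES = ("brightfield_stain", "polarized_signal")


@dataclass(frozen=True)
class AreaFractionResult:
    """Exact positive-pixel count within an ROI at a frozen threshold."""

    metric_name: str
    roi_name: str
    threshold_used: int
    polarity: str
    n_pixels_total: int
    n_pixels_positive: int

    @property
    def fraction(self) -> float:
        """Positive area as percent of ROI pixels, exact rational count."""
        return 100.0 * self.n_pixels_positive / self.n_pixels_total

    def as_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "roi": self.roi_name,
            "threshold": self.threshold_used,
            "polarity": self.polarity,
            "n_total": self.n_pixels_total,
            "n_positive": self.n_pixels_positive,
            "fraction_pct": self.fraction,
        }


def od_to_8bit(od: np.ndarray, ceiling: float = OD_CEILING) -> np.ndarray:
    """Scale an OD (or OD-projection) array to uint8 against a fixed ceiling."""
    scaled = np.clip(np.asarray(od, dtype=float) / ceiling, 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def to_8bit_gray(image: CalibratedImage, mode: str) -> np.ndarray:
    """Reduce an RGB frame to the 8-bit gray image that gets thresholded.

    ``brightfield_stain``: project per-pixel OD onto the PSR stain direction
    (unstained white -> 0, strong stain -> high) and scale by the fixed OD
    ceiling. ``polarized_signal``: luminance of the RGB frame (birefringent
    signal bright on dark background).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "brightfield_stain":
        od = rgb_to_od(image)
        strength = np.clip(od @ PSR_VECTOR, 0.0, None)
        return od_to_8bit(strength)
    lum = image.pixels.astype(float) @ _LUMA
    return np.rint(np.clip(lum, 0, 255)).astype(np.uint8)


def area_fraction(
    gray: np.ndarray,
    threshold: int,
    polarity: str = "above",
    metric_name: str = "area_fraction",
    roi: Roi | None = None,
    roi_name: str = "full",
) -> AreaFractionResult:
    """Count pixels strictly above (or below) the threshold within the ROI."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    if polarity not in ("above", "below"):
        raise ValueError("polarity must be 'above' or 'below'")
    g = np.asarray(gray)
    if roi is not None:
        g = g[roi.y0 : roi.y1, roi.x0 : roi.x1]
        roi_name = roi.name
    positive = g > threshold if polarity == "above" else g < threshold
    return AreaFractionResult(
        metric_name, roi_name, int(threshold), polarity, g.size,
        int(np.count_nonzero(positive)),
    )


def batch_threshold(
    images: list[CalibratedImage],
    mode: str,
    strategy: str = "otsu_on_reference",
    fixed_level: int | None = None,
    reference_index: int = 0,
) -> int:
    """Freeze one threshold level for a whole batch of images.

    ``fixed`` returns ``fixed_level`` unchanged; ``otsu_on_reference`` computes
    Otsu's threshold on the designated reference image and freezes it for the
    batch — a deterministic, auditable surrogate for the study's single manual
    threshold per metric.
    """
    if not images:
        raise ValueError("batch_threshold needs a non-empty image list")
    if strategy == "fixed":
        if fixed_level is None:
            raise ValueError("fixed strategy requires fixed_level")
        if not (0 <= fixed_level <= 255):
            raise ValueError("fixed_level must lie in [0, 255]")
        return int(fixed_level)
    if strategy == "otsu_on_reference":
        gray = to_8bit_gray(images[reference_index], mode)
        return int(threshold_otsu(gray))
    raise ValueError(f"unknown strategy {strategy!r}")


def psr_content_fraction(
    image: CalibratedImage, threshold: int, roi: Roi | None = None
) -> AreaFractionResult:
    """PSR-stained (collagen content) percentage area within an ROI."""
    if image.modality != "brightfield":
        raise ValueError("collagen content is measured on brightfield images")
    gray = to_8bit_gray(image, "brightfield_stain")
    return area_fraction(
        gray, threshold, "above", "collagen_content", roi or full_image_roi(image)
    )


def birefringence_fraction(
    image: CalibratedImage, threshold: int, roi: Roi | None = None
) -> AreaFractionResult:
    """Birefringence-positive (collagen organization) percentage area."""
    if image.modality != "polarized":
        raise ValueError("birefringence is measured on polarized-light images")
    gray = to_8bit_gray(image, "polarized_signal")
    return area_fraction(
        gray, threshold, "above", "birefringence", roi or full_image_roi(image)
    )
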