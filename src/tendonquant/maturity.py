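"""Polarized-light collagen fiber-maturity classification.

Under crossed polarizers, picrosirius-red-stained collagen shifts from green
through yellow to red as fibers thicken and pack — read as immature,
intermediate, and mature collagen. The classifier works per pixel on the raw
RGB intensities of the polarized image:

1. mask: a pixel belongs to the collagen-rich region iff
   ``I_R + I_G + I_B >= net_intensity_min`` (default 140);
2. within the mask, the red/green ratio ``I_R / I_G`` decides the class:
   red (mature) iff ratio >= 1.8, green (immature) iff ratio <= 1.1,
   yellow (intermediate) strictly between.

The two ratio limits are calibrated from small sets of expert-labeled pixels
(at least 10 per class) by placing each limit midway between adjacent class
ratio ranges; 1.1 and 1.8 are the published outcome of that procedure and are
the defaults here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .image import CalibratedImage
from .roi import Roi, full_image_roi


class FiberClass(IntEnum):
    """Pixel classes; integer codes are used in class maps and ground truth."""

    EXCLUDED = 0  # below the net-intensity mask: not collagen-rich
    GREEN = 1  # immature
    YELLOW = 2  # intermediate
    RED = 3  # mature


@dataclass(frozen=True)
class MaturityConfig:
    """Thresholds of the maturity classifier.

    net_intensity_min : int
        Minimum of I_R + I_G + I_B (0..765) for a pixel to count as
        collagen-rich; the mask inequality is inclusive (sum == threshold is
        kept).
    green_max_ratio, red_min_ratio : float
        I_R/I_G classification limits; both comparisons are inclusive
        (ratio == limit lands in green / red respectively).
    zero_green_rule : {"red", "excluded"}
        Class of a masked pixel with I_G == 0 and I_R > 0, where the ratio is
        undefined (treated as +inf -> "red" by default: a pure-red pixel is
        maximally red-shifted).
    """

    net_intensity_min: int = 140
    green_max_ratio: float = 1.1
    red_min_ratio: float = 1.8
    zero_green_rule: str = "red"

    def __post_init__(self) -> None:
        if not (0 <= self.net_intensity_min <= 765):
            raise ValueError("net_intensity_min must lie in [0, 765]")
        if not (0 < self.green_max_ratio < self.red_min_ratio):
            raise ValueError("need 0 < green_max_ratio < red_min_ratio")
        if self.zero_green_rule not in ("red", "excluded"):
            raise ValueError("zero_green_rule must be 'red' or 'excluded'")


@dataclass
class MaturityResult:
    """Per-ROI maturity area fractions, both ROI- and mask-relative.

    ROI-relative fractions (percent of all ROI pixels) always sum to 100;
    mask-relative fractions (percent of collagen-rich pixels) sum to 100 when
    the mask is non-empty and are NaN (``mask_empty=True``) otherwise. The
    mask-relative numbers are the headline values: the mask is what defines
    the collagen-rich region the class fractions describe.
    """

    roi_name: str
    n_pixels_total: int
    counts: dict[str, int]  # keys excluded/green/yellow/red
    config: MaturityConfig

    @property
    def n_pixels_mask(self) -> int:
        return self.n_pixels_total - self.counts["excluded"]

    @property
    def mask_empty(self) -> bool:
        return self.n_pixels_mask == 0

    @property
    def roi_fractions(self) -> dict[str, float]:
        """Percent of all ROI pixels per class (sums to 100 exactly)."""
        t = self.n_pixels_total
        return {k: 100.0 * v / t for k, v in self.counts.items()}

    @property
    def mask_fractions(self) -> dict[str, float]:
        """Percent of masked (collagen-rich) pixels per class; NaN if empty."""
        m = self.n_pixels_mask
        if m == 0:
            return {k: math.nan for k in ("green", "yellow", "red")}
        return {k: 100.0 * self.counts[k] / m for k in ("green", "yellow", "red")}

    def as_row(self) -> dict:
        row = {"roi": self.roi_name, "n_pixels_total": self.n_pixels_total,
               "n_pixels_mask": self.n_pixels_mask}
        for k, v in self.roi_fractions.items():
            row[f"{k}_pct_roi"] = v
        for k, v in self.mask_fractions.items():
            row[f"{k}_pct_mask"] = v
        return row


def classify_pixel(
    r: int, g: int, b: int, config: MaturityConfig | None = None
) -> FiberClass:
    """Classify one pixel; the scalar reference the vectorized path must match.

    Total function on 8-bit triplets: every (r, g, b) gets exactly one class.
    """
    cfg = config or MaturityConfig()
    if r + g + b < cfg.net_intensity_min:
        return FiberClass.EXCLUDED
    if g == 0:
        if r == 0:
            return FiberClass.GREEN  # ratio 0/0: no red signal at all
        return FiberClass.RED if cfg.zero_green_rule == "red" else FiberClass.EXCLUDED
    ratio = r / g
    if ratio >= cfg.red_min_ratio:
        return FiberClass.RED
    if ratio <= cfg.green_max_ratio:
        return FiberClass.GREEN
    return FiberClass.YELLOW


def classify_image(
    pixels: np.ndarray, config: MaturityConfig | None = None
) -> np.ndarray:
    """Vectorized classifier: (H, W, 3) uint8 -> (H, W) class-code map.

    Ratio comparisons are done in integer cross-multiplied form
    (``r * denom >= limit_num * g`` for limit = num/denom) wherever the limits
    are exactly representable as short decimal fractions, avoiding any float
    round-off disagreement with the scalar reference; otherwise float division
    is used, which matches the scalar path by construction.
    """
    cfg = config or MaturityConfig()
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected (H, W, 3) RGB array")
    r = px[:, :, 0].astype(np.int64)
    g = px[:, :, 1].astype(np.int64)
    b = px[:, :, 2].astype(np.int64)

    out = np.full(r.shape, FiberClass.EXCLUDED, dtype=np.uint8)
    masked = (r + g + b) >= cfg.net_intensity_min

    gz = masked & (g == 0)
    # g == 0 special cases
    out[gz & (r == 0)] = FiberClass.GREEN
    if cfg.zero_green_rule == "red":
        out[gz & (r > 0)] = FiberClass.RED

    pos = masked & (g > 0)
    # float ratio reproduces the scalar path exactly (same operation order)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = r / g
    out[pos & (ratio >= cfg.red_min_ratio)] = FiberClass.RED
    is_green = pos & (ratio <= cfg.green_max_ratio)
    out[is_green] = FiberClass.GREEN
    out[pos & (ratio > cfg.green_max_ratio) & (ratio < cfg.red_min_ratio)] = (
        FiberClass.YELLOW
    )
    return out


def maturity_fractions(
    image: CalibratedImage,
    roi: Roi | None = None,
    config: MaturityConfig | None = None,
) -> MaturityResult:
    """Classify every ROI pixel and return class area fractions with counts."""
    cfg = config or MaturityConfig()
    if image.modality != "polarized":
        raise ValueError(
            "maturity classification runs on polarized-light images; "
            f"got modality {image.modality!r}"
        )
    roi = roi or full_image_roi(image)
    if not roi.fits(image):
        raise ValueError(f"ROI {roi.name!r} does not fit image {image.shape}")
    window = image.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1]
    codes = classify_image(window, cfg)
    counts = {
        name.lower(): int(np.count_nonzero(codes == cls))
        for name, cls in FiberClass.__members__.items()
    }
    return MaturityResult(roi.name, codes.size, counts, cfg)


def calibrate_limits(
    samples: list[tuple[float, str]] | dict[str, list[float]],
    min_per_class: int = 10,
) -> tuple[float, float]:
    """Derive (green_max_ratio, red_min_ratio) from labeled example pixels.

    ``samples`` is either a list of ``(I_R/I_G ratio, class)`` pairs or a dict
    ``{class: [ratios]}`` with classes green/yellow/red. Each class needs at
    least ``min_per_class`` samples (default 10, the study's minimum). Each
    limit is the midpoint between adjacent class ratio ranges; overlapping
    ranges are an error — the labeled pixels then do not define a consistent
    rule.
    """
    if isinstance(samples, dict):
        by_class = {k: list(map(float, v)) for k, v in samples.items()}
    else:
        by_class = {}
        for ratio, cls in samples:
            by_class.setdefault(cls, []).append(float(ratio))
    missing = [c for c in ("green", "yellow", "red") if c not in by_class]
    if missing:
        raise ValueError(f"no labeled pixels for class(es): {missing}")
    for cls, vals in by_class.items():
        if len(vals) < min_per_class:
            raise ValueError(
                f"class {cls!r} has {len(vals)} samples; need >= {min_per_class}"
            )
    g_hi = max(by_class["green"])
    y_lo, y_hi = min(by_class["yellow"]), max(by_class["yellow"])
    r_lo = min(by_class["red"])
    if g_hi >= y_lo:
        raise ValueError(
            f"green and yellow ratio ranges overlap (green max {g_hi} >= "
            f"yellow min {y_lo})"
        )
    if y_hi >= r_lo:
        raise ValueError(
            f"yellow and red ratio ranges overlap (yellow max {y_hi} >= "
            f"red min {r_lo})"
        )
    return (g_hi + y_lo) / 2.0, (y_hi + r_lo) / 2.0
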