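"""Nuclear segmentation and morphometry on the hematoxylin channel.

Measures the three cell-level quantities of the study: cell density (nuclei
per mm², counted by the centroid-in-ROI rule), nuclear aspect ratio (major /
minor axis of the moment-equivalent ellipse) and nuclear circularity
(4π·area/perimeter²). The study outlined nuclei manually; the automated
default here is Otsu thresholding of the hematoxylin optical-density channel
with smoothing, a physical size filter, and an optional watershed split —
user-provided label maps are accepted as a pass-through for parity with
manual selection.

Perimeter uses a corrected contour-length estimator (marching-squares 0.5
contour with a 5-point circular moving-average smoothing of the polygon):
naive pixel-edge counting overestimates perimeters of smooth shapes by up to
~8%, biasing circularity low by ~15% on circles, while this estimator is
within ~1% on a radius-50 circle and ~2% on a square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label as sk_label, regionprops
from skimage.segmentation import watershed

from .roi import Roi

#: Shapes with fewer pixels than this are counted but excluded from shape
#: metrics — moments and contours are meaningless at that scale.
MIN_SHAPE_PIXELS = 5

#: Vertex window of the contour-smoothing perimeter estimator.
PERIMETER_SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class SegmentationConfig:
    """Automated nucleus segmentation settings.

    od_threshold_mode : {"otsu", "fixed"}
        Threshold on the hematoxylin OD channel. ``fixed`` requires
        ``fixed_threshold`` (an OD value).
    min_area_um2, max_area_um2 : float
        Physical size filter; objects outside the band are removed.
    split_touching : bool
        Distance-transform watershed split of touching nuclei.
    smoothing_sigma : float
        Gaussian smoothing (pixels) applied to the OD channel first.
    """

    od_threshold_mode: str = "otsu"
    fixed_threshold: float | None = None
    min_area_um2: float = 5.0
    max_area_um2: float = 500.0
    split_touching: bool = False
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.od_threshold_mode not in ("otsu", "fixed"):
            raise ValueError("od_threshold_mode must be 'otsu' or 'fixed'")
        if (self.od_threshold_mode == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold required iff mode is 'fixed'")
        if not (self.min_area_um2 < self.max_area_um2):
            raise ValueError("need min_area_um2 < max_area_um2")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass(frozen=True)
class NucleusRecord:
    """Morphometry of one segmented nucleus; lengths in µm, area in µm²."""

    label: int
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    centroid: tuple[float, float]  # (row, col) in pixels
    shape_valid: bool = True

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis

    @property
    def circularity(self) -> float:
        return 4.0 * np.pi * self.area / self.perimeter**2

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "area_um2": self.area,
            "perimeter_um": self.perimeter,
            "major_axis_um": self.major_axis,
            "minor_axis_um": self.minor_axis,
            "aspect_ratio": self.aspect_ratio if self.shape_valid else np.nan,
            "circularity": self.circularity if self.shape_valid else np.nan,
            "centroid_row": self.centroid[0],
            "centroid_col": self.centroid[1],
        }


def segment_nuclei(
    hematoxylin_od: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig | None = None,
    label_map: np.ndarray | None = None,
) -> np.ndarray:
    """Segment nuclei in a hematoxylin OD channel; returns an int label map.

    If ``label_map`` is given it is validated and passed through unchanged
    (the manual-selection parity path). Otherwise: Gaussian smoothing, Otsu
    (or fixed) OD threshold, connected components, physical size filter,
    optional distance-transform watershed split. An empty result is a valid
    zero-label map, not an error.
    """
    cfg = config or SegmentationConfig()
    od = np.asarray(hematoxylin_od, dtype=float)
    if od.ndim != 2:
        raise ValueError("expected a single-channel OD image")

    if label_map is not None:
        lm = np.asarray(label_map)
        if lm.shape != od.shape:
            raise ValueError("label map shape does not match the channel")
        if lm.min() < 0:
            raise ValueError("label map must be non-negative integers")
        return lm.astype(np.int32)

    if cfg.smoothing_sigma > 0:
        od = gaussian(od, sigma=cfg.smoothing_sigma, preserve_range=True)

    if cfg.od_threshold_mode == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if np.ptp(od) < 1e-9:  # blank channel: Otsu undefined, nothing to find
            return np.zeros(od.shape, dtype=np.int32)
        thr = float(threshold_otsu(od))
    mask = od > thr

    labels = sk_label(mask, connectivity=2)
    if cfg.split_touching and labels.max() > 0:
        dist = ndi.distance_transform_edt(mask)
        min_dist = max(2, int(round(np.sqrt(cfg.min_area_um2) / pixel_size_um)))
        peaks = peak_local_max(
            dist, labels=labels, min_distance=min_dist, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() > 0:
            labels = watershed(-dist, markers, mask=mask)

    # physical size filter
    px_area = pixel_size_um**2
    sizes = np.bincount(labels.ravel())
    keep = np.zeros_like(sizes, dtype=bool)
    if len(sizes) > 1:
        areas = sizes * px_area
        keep[1:] = (areas[1:] >= cfg.min_area_um2) & (areas[1:] <= cfg.max_area_um2)
    filtered = np.where(keep[labels], labels, 0)
    out, _, _ = _relabel(filtered)
    return out


def _relabel(labels: np.ndarray):
    """Compact labels to 1..k preserving order; returns (map, old ids, k)."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels], ids, len(ids)


def _smoothed_contour_perimeter(mask: np.ndarray) -> float:
    """Corrected contour length of a binary object, in pixels."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        k = PERIMETER_SMOOTH_WINDOW
        if closed and len(pts) > k:
            pts = ndi.uniform_filter1d(pts, size=k, axis=0, mode="wrap")
        ring = np.vstack([pts, pts[:1]]) if closed else pts
        total += float(np.sum(np.hypot(*np.diff(ring, axis=0).T)))
    return total


def measure_nuclei(
    labels: np.ndarray, pixel_size_um: float
) -> list[NucleusRecord]:
    """Per-nucleus morphometry from a label map.

    Area is pixel count × pixel_size²; axes come from the ellipse with
    matching normalized second central moments; aspect ratio is major/minor
    (so always ≥ 1). Objects below ``MIN_SHAPE_PIXELS`` stay in the list (for
    counting) but are flagged ``shape_valid=False``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    records = []
    for rp in regionprops(np.asarray(labels)):
        area = rp.area * pixel_size_um**2
        if rp.area < MIN_SHAPE_PIXELS:
            records.append(
                NucleusRecord(rp.label, area, np.nan, np.nan, np.nan,
                              tuple(rp.centroid), shape_valid=False)
            )
            continue
        perim = _smoothed_contour_perimeter(rp.image) * pixel_size_um
        major = max(rp.axis_major_length, 1e-12) * pixel_size_um
        minor = max(rp.axis_minor_length, 1e-12) * pixel_size_um
        if minor > major:  # numerically possible only for degenerate shapes
            major, minor = minor, major
        records.append(
            NucleusRecord(rp.label, area, perim, major, minor, tuple(rp.centroid))
        )
    return records


def cell_density(
    labels: np.ndarray,
    roi_area_um2: float | None = None,
    pixel_size_um: float | None = None,
    roi: Roi | None = None,
) -> float:
    """Nuclei per mm², counting labels whose centroid lies inside the ROI.

    The centroid rule makes density additive over a partition of the field
    into ROIs: each nucleus is counted exactly once. With no explicit ROI the
    whole label map is the ROI (``roi_area_um2`` then required unless
    ``pixel_size_um`` is given).
    """
    lab = np.asarray(labels)
    if roi is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with an explicit roi")
        count = 0
        for rp in regionprops(lab):
            r, c = rp.centroid
            if roi.y0 <= r < roi.y1 and roi.x0 <= c < roi.x1:
                count += 1
        area_um2 = roi.area_um2(pixel_size_um)
    else:
        count = int(len(np.unique(lab)) - (1 if (lab == 0).any() else 0))
        if roi_area_um2 is None:
            if pixel_size_um is None:
                raise ValueError("need roi_area_um2 or pixel_size_um")
            area_um2 = lab.size * pixel_size_um**2
        else:
            area_um2 = roi_area_um2
    if area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    return count / (area_um2 / 1e6)
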