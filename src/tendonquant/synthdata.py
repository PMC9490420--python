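"""Synthetic histology phantoms with exact ground truth.

The study's raw slide scans were never deposited, so every downstream
measurement is exercised on seeded phantoms that carry the exact quantity the
measurement estimates:

* H&E-like nuclei fields (non-overlapping ellipses, Beer–Lambert composed)
  -> exact count, per-nucleus axes/orientation, label map;
* PSR-like polarized fiber fields -> exact per-pixel class map whose pixel
  intensities satisfy the maturity rule for their intended class;
* DAB-like IHC fields -> exact positive mask at a requested area fraction.

A stage series arranges phantoms over developmental days d9–d19 with
parameter tables that follow the reported qualitative trends (cell density
peaking mid-series, nuclear elongation rising, collagen maturing from green
to red), producing an on-disk dataset + manifest that drives the end-to-end
pipeline.

Determinism: identical spec + seed give bit-identical outputs; a series
derives one stable sub-seed per image from its IDs.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .image import CalibratedImage
from .maturity import FiberClass, MaturityConfig
from .stains import StainMatrix, default_matrix

#: Rejection-sampling budget: attempts per requested nucleus.
PLACEMENT_RETRY_FACTOR = 100

#: Minimum clearance between nucleus bounding circles, pixels.
PLACEMENT_MARGIN_PX = 2.0


def derive_seed(base_seed: int, *ids) -> int:
    """Stable per-image sub-seed from a base seed and identifying strings."""
    tag = "|".join(str(i) for i in ids)
    return (int(base_seed) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


# --------------------------------------------------------------------------
# nuclei phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleiPhantomSpec:
    """Parameters of an H&E-like nuclei field.

    ``target_density`` is nuclei per mm²; the generated count is exactly
    ``round(target_density × frame area in mm²)`` — placement, shapes and
    orientations are what the seed randomizes. ``ar_mean``/``ar_sd``
    parameterize the nuclear elongation distribution (truncated at 1);
    areas are µm². Stain levels are optical densities fed to the same
    Beer–Lambert forward model the separation module inverts.
    """

    image_size: tuple[int, int] = (512, 512)  # (H, W) pixels
    pixel_size_um: float = 1.0
    target_density: float = 2000.0
    ar_mean: float = 1.5
    ar_sd: float = 0.2
    nucleus_area_mean: float = 40.0
    nucleus_area_sd: float = 8.0
    hematoxylin_intensity: float = 0.8
    eosin_background: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ValueError("target_density must be > 0")
        if self.ar_mean < 1:
            raise ValueError("ar_mean must be >= 1")
        if self.nucleus_area_mean <= 0:
            raise ValueError("nucleus_area_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def area_mm2(self) -> float:
        h, w = self.image_size
        return h * w * self.pixel_size_um**2 / 1e6

    @property
    def n_nuclei(self) -> int:
        return int(round(self.target_density * self.area_mm2))


def generate_nuclei_phantom(
    spec: NucleiPhantomSpec, matrix: StainMatrix | None = None
) -> tuple[CalibratedImage, dict]:
    """Synthesize a nuclei field; returns (image, ground truth).

    Ground truth holds the exact nucleus count, the integer label map, and
    per-nucleus center/semi-axes/orientation. Nuclei are non-overlapping by
    construction (bounding-circle rejection sampling), so the count is
    unambiguous; an unsatisfiable density raises with the achievable maximum.
    """
    matrix = matrix or default_matrix("H&E")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n = spec.n_nuclei
    if n < 1:
        raise ValueError("frame too small to hold one nucleus at this density")

    px = spec.pixel_size_um
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bound radius)
    nuclei = []
    attempts = 0
    budget = PLACEMENT_RETRY_FACTOR * n
    while len(nuclei) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei in a "
                f"{h}x{w} px frame (placed {len(nuclei)}); achievable density "
                f"~{len(nuclei) / spec.area_mm2:.0f}/mm^2"
            )
        attempts += 1
        area = max(spec.nucleus_area_mean * 0.2,
                   rng.normal(spec.nucleus_area_mean, spec.nucleus_area_sd))
        ar = max(1.0, rng.normal(spec.ar_mean, spec.ar_sd))
        area_px = area / px**2
        b = math.sqrt(area_px / (math.pi * ar))  # minor semi-axis, px
        a = ar * b
        theta = rng.uniform(0, math.pi)
        cy = rng.uniform(a + 1, h - a - 1)
        cx = rng.uniform(a + 1, w - a - 1)
        if any(
            math.hypot(cy - py, cx - pxc) < a + pr + PLACEMENT_MARGIN_PX
            for py, pxc, pr in placed
        ):
            continue
        placed.append((cy, cx, a))
        nuclei.append(
            {"center": (cy, cx), "semi_major_px": a, "semi_minor_px": b,
             "orientation_rad": theta, "area_um2": area, "aspect_ratio": ar}
        )

    labels = np.zeros((h, w), dtype=np.int32)
    hema = np.zeros((h, w), dtype=float)
    for i, nuc in enumerate(nuclei, start=1):
        cy, cx = nuc["center"]
        rr, cc = draw_ellipse(
            cy, cx, nuc["semi_major_px"], nuc["semi_minor_px"],
            shape=(h, w), rotation=nuc["orientation_rad"],
        )
        labels[rr, cc] = i
        hema[rr, cc] = spec.hematoxylin_intensity

    conc = np.zeros((h, w, 3), dtype=float)
    conc[:, :, 0] = hema
    conc[:, :, 1] = spec.eosin_background
    od = conc @ matrix.vectors
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, od.shape)
    image = CalibratedImage(
        _od_to_rgb_clipped(od), spec.pixel_size_um, "brightfield"
    )
    truth = {
        "count": n,
        "density_per_mm2": n / spec.area_mm2,
        "label_map": labels,
        "nuclei": nuclei,
        "ar_mean_requested": spec.ar_mean,
    }
    return image, truth


def _od_to_rgb_clipped(od: np.ndarray) -> np.ndarray:
    intensity = 255.0 * np.power(10.0, -od) - 1.0 / 255.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# polarized-light fiber phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberPhantomSpec:
    """Parameters of a polarized-light PSR fiber field.

    The four fractions (green/yellow/red fiber classes plus dark background)
    must sum to 1; realized pixel counts are exact up to largest-remainder
    rounding. ``class_ratio_targets`` are representative I_R/I_G values per
    class and must satisfy the classification rule for their class.
    ``fiber_sum_range`` bounds the net intensity (I_R+I_G+I_B) of fiber
    pixels; background pixels are generated strictly below the mask
    threshold. Orientation parameters shape the cosmetic spatial texture
    only — class is encoded purely in (net intensity, R/G ratio).
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    fraction_green: float = 0.25
    fraction_yellow: float = 0.25
    fraction_red: float = 0.25
    fraction_background: float = 0.25
    class_ratio_targets: dict = field(
        default_factory=lambda: {"green": 0.8, "yellow": 1.4, "red": 2.4}
    )
    fiber_sum_range: tuple[int, int] = (200, 430)
    orientation_mean_deg: float = 0.0
    orientation_dispersion: float = 8.0  # anisotropic smoothing length, px
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(f < 0 or f > 1 for f in fr.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr.values())}")
        cfg = MaturityConfig()
        t = self.class_ratio_targets
        if not t["green"] <= cfg.green_max_ratio:
            raise ValueError("green ratio target violates the green rule (<= 1.1)")
        if not t["red"] >= cfg.red_min_ratio:
            raise ValueError("red ratio target violates the red rule (>= 1.8)")
        if not (cfg.green_max_ratio < t["yellow"] < cfg.red_min_ratio):
            raise ValueError("yellow ratio target must lie strictly in (1.1, 1.8)")
        lo, hi = self.fiber_sum_range
        if not (cfg.net_intensity_min <= lo <= hi <= 765):
            raise ValueError("fiber_sum_range must lie in [mask threshold, 765]")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "background": self.fraction_background,
            "green": self.fraction_green,
            "yellow": self.fraction_yellow,
            "red": self.fraction_red,
        }


def _largest_remainder_counts(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer class counts summing exactly to ``total``."""
    raw = {k: total * f for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _oriented_field(shape, rng, angle_deg: float, length: float) -> np.ndarray:
    """Smooth anisotropic noise field used to lay classes out in fiber-like bands."""
    noise = rng.normal(size=shape)
    smooth = ndi.gaussian_filter(noise, sigma=(max(length, 0.5), 1.0), mode="wrap")
    return ndi.rotate(smooth, angle_deg, reshape=False, order=1, mode="wrap")


_CLASS_CODE = {"background": int(FiberClass.EXCLUDED), "green": int(FiberClass.GREEN),
               "yellow": int(FiberClass.YELLOW), "red": int(FiberClass.RED)}


def generate_fiber_phantom(spec: FiberPhantomSpec) -> tuple[CalibratedImage, dict]:
    """Synthesize a polarized fiber field; returns (image, ground truth).

    Ground truth is the per-pixel class map (codes of
    :class:`~tendonquant.maturity.FiberClass`); each generated pixel's
    intensities satisfy the default maturity rule for its intended class, so
    classifier recovery error is purely the classifier's.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = MaturityConfig()
    h, w = spec.image_size
    total = h * w
    counts = _largest_remainder_counts(total, spec.fractions)

    # lay classes out along a smooth oriented field: rank pixels, slice ranks
    field_vals = _oriented_field(
        (h, w), rng, spec.orientation_mean_deg, spec.orientation_dispersion
    )
    order = np.argsort(field_vals, axis=None, kind="stable")
    class_map = np.empty(total, dtype=np.uint8)
    pos = 0
    for cls in ("background", "green", "yellow", "red"):
        class_map[order[pos : pos + counts[cls]]] = _CLASS_CODE[cls]
        pos += counts[cls]
    class_map = class_map.reshape(h, w)

    rgb = np.zeros((h, w, 3), dtype=np.int64)
    bg_mask = class_map == _CLASS_CODE["background"]
    n_bg = int(bg_mask.sum())
    if n_bg:
        # strictly below the mask threshold: per-channel cap keeps the sum low
        cap = max((cfg.net_intensity_min - 1) // 3, 1)
        rgb[bg_mask] = rng.integers(0, cap + 1, size=(n_bg, 3))

    ratio_jitter = {"green": (0.55, min(1.05, cfg.green_max_ratio)),
                    "yellow": (cfg.green_max_ratio + 0.06, cfg.red_min_ratio - 0.06),
                    "red": (cfg.red_min_ratio + 0.05, 3.2)}
    for cls in ("green", "yellow", "red"):
        m = class_map == _CLASS_CODE[cls]
        k = int(m.sum())
        if k == 0:
            continue
        lo, hi = ratio_jitter[cls]
        center = spec.class_ratio_targets[cls]
        t = np.clip(rng.normal(center, 0.08, size=k), lo, hi)
        s = rng.integers(spec.fiber_sum_range[0], spec.fiber_sum_range[1] + 1, k)
        b = rng.integers(0, 31, size=k)
        g = np.rint((s - b) / (1.0 + t)).astype(np.int64)
        g = np.clip(g, 40, np.floor(250.0 / np.maximum(t, 1.0)).astype(np.int64))
        r = np.rint(t * g).astype(np.int64)
        # integer nudges so the rounded triplet still obeys its class rule
        if cls == "green":
            r = np.minimum(r, np.floor(cfg.green_max_ratio * g).astype(np.int64))
        elif cls == "red":
            r = np.maximum(r, np.ceil(cfg.red_min_ratio * g).astype(np.int64))
        else:
            low = np.floor(cfg.green_max_ratio * g).astype(np.int64) + 1
            high = np.ceil(cfg.red_min_ratio * g).astype(np.int64) - 1
            r = np.clip(r, low, high)
        r = np.clip(r, 0, 255)
        # keep the pixel inside the mask after all nudges
        b = np.maximum(b, cfg.net_intensity_min - r - g)
        b = np.clip(b, 0, 255)
        rgb[m] = np.column_stack([r, g, b])

    image = CalibratedImage(
        rgb.astype(np.uint8), spec.pixel_size_um, "polarized"
    )
    truth = {
        "class_map": class_map,
        "counts": counts,
        "fractions_requested": spec.fractions,
    }
    return image, truth


# --------------------------------------------------------------------------
# DAB IHC phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DabPhantomSpec:
    """Parameters of a DAB IHC field with hematoxylin counterstain.

    ``positive_fraction`` of the pixels carry DAB at optical density
    ``dab_od`` (over ``hematoxylin_od`` everywhere); the positive count is
    exact up to one-pixel rounding. Noise is additive Gaussian in OD space.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    positive_fraction: float = 0.3
    dab_od: float = 0.8
    hematoxylin_od: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dab_od < 0 or self.hematoxylin_od < 0:
            raise ValueError("stain optical densities must be >= 0")


def generate_dab_phantom(
    spec: DabPhantomSpec, matrix: StainMatrix | None = None
) -> tuple[CalibratedImage, dict]:
    """Synthesize a DAB IHC field; returns (image, ground truth mask)."""
    matrix = matrix or default_matrix("H-DAB")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    total = h * w
    k = int(round(spec.positive_fraction * total))

    # coherent blobs: smooth a noise field, take the top-k pixels
    smooth = ndi.gaussian_filter(rng.normal(size=(h, w)), sigma=4.0, mode="wrap")
    order = np.argsort(smooth, axis=None, kind="stable")
    mask = np.zeros(total, dtype=bool)
    if k:
        mask[order[-k:]] = True
    mask = mask.reshape(h, w)

    conc = np.zeros((h, w, 3), dtype=float)
    conc[:, :, 0] = spec.hematoxylin_od
    conc[:, :, 1] = np.where(mask, spec.dab_od, 0.0)
    od = conc @ matrix.vectors
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, od.shape)
    image = CalibratedImage(
        _od_to_rgb_clipped(od), spec.pixel_size_um, "brightfield"
    )
    truth = {
        "positive_mask": mask,
        "n_positive": k,
        "positive_fraction": k / total,
    }
    return image, truth


# --------------------------------------------------------------------------
# stage series
# --------------------------------------------------------------------------

#: Default per-stage parameter table. The study reports per-stage values only
#: graphically; these defaults encode the directions its Results text states
#: — cell density rising to a d13 peak then falling, nuclear aspect ratio
#: rising monotonically, immature (green) collagen falling, intermediate
#: (yellow) peaking at d13, mature (red) absent at d9 then rising, and a
#: COL3-like DAB signal peaking at d13 — with magnitudes chosen as plausible
#: for embryonic tendon.
DEFAULT_STAGE_PARAMS: dict[int, dict] = {
    9:  {"density": 1800, "ar_mean": 1.3, "green": 0.55, "yellow": 0.10,
         "red": 0.00, "dab_positive": 0.10},
    11: {"density": 2200, "ar_mean": 1.5, "green": 0.40, "yellow": 0.20,
         "red": 0.05, "dab_positive": 0.25},
    13: {"density": 2600, "ar_mean": 1.8, "green": 0.20, "yellow": 0.35,
         "red": 0.12, "dab_positive": 0.40},
    15: {"density": 2300, "ar_mean": 2.2, "green": 0.12, "yellow": 0.30,
         "red": 0.25, "dab_positive": 0.25},
    17: {"density": 2000, "ar_mean": 2.6, "green": 0.08, "yellow": 0.22,
         "red": 0.37, "dab_positive": 0.15},
    19: {"density": 1600, "ar_mean": 3.0, "green": 0.05, "yellow": 0.15,
         "red": 0.47, "dab_positive": 0.10},
}

#: Fraction of fiber-phantom pixels kept as dark background at every stage.
_FIBER_BACKGROUND = 0.30

MODALITY_NAMES = ("he", "psr_pol", "dab")


@dataclass(frozen=True)
class StageSeriesSpec:
    """A replicate-structured multi-stage synthetic dataset.

    Defaults mirror the study design: three technical replicates (ROIs) per
    biological replicate and at least three biological replicates per stage.
    Each emitted image is one ROI-sized field.
    """

    stages: tuple[int, ...] = (9, 11, 13, 15, 17, 19)
    n_biological: int = 3
    n_technical: int = 3
    base_seed: int = 0
    tendons: tuple[str, ...] = ("TmAM",)
    image_size: tuple[int, int] = (128, 128)
    pixel_size_um: float = 1.0
    stage_params: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PARAMS))
    modalities: tuple[str, ...] = MODALITY_NAMES
    noise_sd: float = 0.0
    #: inter-embryo variability: per-biological-replicate multiplicative
    #: jitter (coefficient of variation) on density, AR and stain fractions,
    #: so within-stage variance is realistic rather than zero
    biological_cv: float = 0.08

    def __post_init__(self) -> None:
        from .stats import DAY_TO_HH  # local import avoids a cycle

        unknown = [d for d in self.stages if d not in DAY_TO_HH]
        if unknown:
            raise ValueError(f"stages {unknown} not in the d9-d19 study design")
        if self.n_biological < 3:
            raise ValueError("study design requires >= 3 biological replicates")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        missing = [d for d in self.stages if d not in self.stage_params]
        if missing:
            raise ValueError(f"no stage parameters for day(s) {missing}")
        bad = [m for m in self.modalities if m not in MODALITY_NAMES]
        if bad:
            raise ValueError(f"unknown modalities {bad}; expected {MODALITY_NAMES}")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")


def _biological_jitter(series: StageSeriesSpec, tendon: str, day: int,
                       bio: int) -> dict:
    """Per-embryo multiplicative jitter, stable across technical replicates."""
    rng = np.random.default_rng(
        derive_seed(series.base_seed, tendon, day, bio, "bio")
    )
    cv = series.biological_cv
    mult = lambda: float(np.clip(rng.normal(1.0, cv), 0.5, 1.5)) if cv else 1.0
    return {"density": mult(), "ar": mult(), "green": mult(),
            "yellow": mult(), "red": mult(), "dab": mult()}


def _specs_for(series: StageSeriesSpec, day: int, seed: int, jit: dict):
    p = series.stage_params[day]
    nuc = NucleiPhantomSpec(
        image_size=series.image_size, pixel_size_um=series.pixel_size_um,
        target_density=p["density"] * jit["density"],
        ar_mean=max(1.0, p["ar_mean"] * jit["ar"]),
        noise_sd=series.noise_sd, seed=seed,
    )
    fiber_total = 1.0 - _FIBER_BACKGROUND
    g = p["green"] * jit["green"]
    y = p["yellow"] * jit["yellow"]
    r = p["red"] * jit["red"]
    scale = fiber_total / (g + y + r)
    red_frac = max(0.0, fiber_total - g * scale - y * scale)
    fib = FiberPhantomSpec(
        image_size=series.image_size, pixel_size_um=series.pixel_size_um,
        fraction_green=g * scale, fraction_yellow=y * scale,
        fraction_red=red_frac,
        fraction_background=1.0 - g * scale - y * scale - red_frac, seed=seed,
    )
    dab = DabPhantomSpec(
        image_size=series.image_size, pixel_size_um=series.pixel_size_um,
        positive_fraction=min(1.0, p["dab_positive"] * jit["dab"]),
        noise_sd=series.noise_sd, seed=seed,
    )
    return {"he": nuc, "psr_pol": fib, "dab": dab}


def generate_stage_series(
    series: StageSeriesSpec, out_dir: str | Path, overwrite: bool = False,
    image_format: str = "tiff",
) -> pd.DataFrame:
    """Write a phantom dataset + manifest CSV; returns the manifest table.

    Layout: ``images/<id>.tif`` (8-bit RGB), ``ground_truth/<id>.tif``
    (16-bit labels/classes/mask) with a JSON sidecar of scalar truths, and
    ``manifest.csv`` binding every image to its tendon/stage/replicate IDs.
    Refuses to write into an existing non-empty directory unless
    ``overwrite=True``.
    """
    from .stats import DAY_TO_HH

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace"
        )
    ext = {"tiff": ".tif", "png": ".png"}.get(image_format)
    if ext is None:
        raise ValueError("image_format must be 'tiff' or 'png'")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "ground_truth").mkdir(parents=True, exist_ok=True)

    rows = []
    for tendon in series.tendons:
        for day in series.stages:
            for bio in range(1, series.n_biological + 1):
                jit = _biological_jitter(series, tendon, day, bio)
                for tech in range(1, series.n_technical + 1):
                    for modality in series.modalities:
                        seed = derive_seed(
                            series.base_seed, tendon, day, bio, tech, modality
                        )
                        spec = _specs_for(series, day, seed, jit)[modality]
                        stem = f"{tendon}_d{day:02d}_N{bio}_n{tech}_{modality}"
                        img_path = out / "images" / f"{stem}{ext}"
                        gt_path = out / "ground_truth" / f"{stem}_gt.tif"
                        scalars = _write_phantom(
                            modality, spec, img_path, gt_path
                        )
                        rows.append({
                            "image_path": str(img_path.relative_to(out)),
                            "modality": modality,
                            "tendon": tendon,
                            "stage_day": day,
                            "hh_stage": DAY_TO_HH[day],
                            "biological_id": bio,
                            "technical_id": tech,
                            "pixel_size_um": series.pixel_size_um,
                            "ground_truth_path": str(gt_path.relative_to(out)),
                            **{f"true_{k}": v for k, v in scalars.items()},
                        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _write_phantom(modality: str, spec, img_path: Path, gt_path: Path) -> dict:
    """Generate one phantom, write image + ground truth, return scalar truths."""
    if modality == "he":
        image, truth = generate_nuclei_phantom(spec)
        gt_array = truth["label_map"].astype(np.uint16)
        scalars = {"count": truth["count"],
                   "density_per_mm2": truth["density_per_mm2"],
                   "ar_mean": spec.ar_mean}
    elif modality == "psr_pol":
        image, truth = generate_fiber_phantom(spec)
        gt_array = truth["class_map"].astype(np.uint16)
        total = gt_array.size
        mask_n = total - truth["counts"]["background"]
        scalars = {"fiber_fraction": mask_n / total}
        for cls in ("green", "yellow", "red"):
            scalars[f"{cls}_pct_mask"] = (
                100.0 * truth["counts"][cls] / mask_n if mask_n else float("nan")
            )
    elif modality == "dab":
        image, truth = generate_dab_phantom(spec)
        gt_array = truth["positive_mask"].astype(np.uint16)
        scalars = {"dab_positive_pct": 100.0 * truth["positive_fraction"]}
    else:  # pragma: no cover - guarded by StageSeriesSpec validation
        raise ValueError(f"unknown modality {modality!r}")

    image.save(img_path)
    tifffile.imwrite(gt_path, gt_array)
    gt_path.with_suffix(".json").write_text(
        json.dumps({k: float(v) for k, v in scalars.items()}, sort_keys=True)
    )
    return scalars
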