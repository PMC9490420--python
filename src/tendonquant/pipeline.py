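"""End-to-end study runs: manifest -> measurements -> statistics -> report.

Routes every manifest image to its modality's measurements (H&E nuclear
morphometry; polarized PSR birefringence + maturity fractions; DAB area
fraction), freezes one threshold per thresholded metric for the whole run,
aggregates technical into biological replicates, and runs the between-stage
tests. Deterministic given the config: frozen thresholds and seeds are
echoed into a line-oriented run log, and QC images (segmentation label maps,
maturity class maps) are written for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import collagen, ihc, nuclei, stains
from .image import CalibratedImage, load_image
from .maturity import MaturityConfig, maturity_fractions
from .roi import full_image_roi
from .stats import (
    DAY_TO_HH, aggregate_biological, reports_to_frame, run_study_tests,
)

#: manifest modality -> acquisition modality of the image file
_ACQUISITION = {"he": "brightfield", "psr_pol": "polarized", "dab": "brightfield"}


@dataclass
class RunConfig:
    """Everything a full study run needs; all thresholds end up in the log."""

    manifest: str | Path
    out_dir: str | Path
    segmentation: nuclei.SegmentationConfig = field(
        default_factory=nuclei.SegmentationConfig
    )
    maturity: MaturityConfig = field(default_factory=MaturityConfig)
    dab_target: str = "DAB"
    threshold_strategy: str = "otsu_on_reference"
    birefringence_threshold: int | None = None  # fixed level when strategy=fixed
    dab_threshold: int | None = None
    alpha: float = 0.05
    base_seed: int = 0
    overwrite: bool = False
    write_qc: bool = True

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.threshold_strategy == "fixed":
            if self.birefringence_threshold is None or self.dab_threshold is None:
                raise ValueError(
                    "fixed strategy requires birefringence_threshold and "
                    "dab_threshold"
                )


@dataclass
class RunResult:
    study_table: pd.DataFrame
    biological: pd.DataFrame
    reports: list
    frozen_thresholds: dict
    failures: list[dict]
    out_dir: Path


def _load_manifest(path: Path) -> tuple[pd.DataFrame, Path]:
    manifest = pd.read_csv(path)
    required = {"image_path", "modality", "tendon", "stage_day",
                "biological_id", "technical_id", "pixel_size_um"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks column(s) {sorted(missing)}")
    return manifest, path.parent


def _measure_he(image: CalibratedImage, cfg: RunConfig, qc_dir: Path | None,
                stem: str) -> dict[str, float]:
    channels = stains.deconvolve(image, stains.default_matrix("H&E"))
    labels = nuclei.segment_nuclei(
        channels["hematoxylin"], image.pixel_size_um, cfg.segmentation
    )
    records = [r for r in nuclei.measure_nuclei(labels, image.pixel_size_um)]
    density = nuclei.cell_density(labels, pixel_size_um=image.pixel_size_um)
    shaped = [r for r in records if r.shape_valid]
    if qc_dir is not None:
        tifffile.imwrite(qc_dir / f"{stem}_labels.tif", labels.astype(np.uint16))
    return {
        "cell_density_per_mm2": density,
        "nuclear_aspect_ratio": (
            float(np.mean([r.aspect_ratio for r in shaped])) if shaped else np.nan
        ),
        "nuclear_circularity": (
            float(np.mean([r.circularity for r in shaped])) if shaped else np.nan
        ),
    }


def _measure_psr_pol(image: CalibratedImage, cfg: RunConfig, threshold: int,
                     qc_dir: Path | None, stem: str) -> dict[str, float]:
    roi = full_image_roi(image)
    biref = collagen.birefringence_fraction(image, threshold, roi)
    mat = maturity_fractions(image, roi, cfg.maturity)
    if qc_dir is not None:
        from .maturity import classify_image

        tifffile.imwrite(
            qc_dir / f"{stem}_classes.tif",
            classify_image(image.pixels, cfg.maturity),
        )
    frac = mat.mask_fractions
    return {
        "birefringence_pct": biref.fraction,
        "immature_green_pct": frac["green"],
        "intermediate_yellow_pct": frac["yellow"],
        "mature_red_pct": frac["red"],
    }


def _measure_dab(image: CalibratedImage, cfg: RunConfig, threshold: int
                 ) -> dict[str, float]:
    ihc_cfg = ihc.IhcConfig(cfg.dab_target, dab_threshold=threshold)
    res = ihc.dab_area_fraction(image, full_image_roi(image), ihc_cfg)
    return {f"dab_{cfg.dab_target}_pct": res.fraction}


def _freeze_thresholds(manifest: pd.DataFrame, root: Path, cfg: RunConfig) -> dict:
    """One frozen 8-bit level per thresholded metric for the whole run."""
    frozen: dict[str, int] = {}
    for modality, mode, fixed in (
        ("psr_pol", "polarized_signal", cfg.birefringence_threshold),
        ("dab", None, cfg.dab_threshold),
    ):
        rows = manifest[manifest["modality"] == modality]
        if rows.empty:
            continue
        rows = rows.sort_values("image_path")
        first = rows.iloc[0]
        ref = load_image(
            root / first["image_path"], float(first["pixel_size_um"]),
            _ACQUISITION[modality],
        )
        if cfg.threshold_strategy == "fixed":
            frozen[modality] = int(fixed)
        elif modality == "dab":
            # Otsu on the reference image's DAB channel
            from skimage.filters import threshold_otsu

            frozen[modality] = int(threshold_otsu(ihc.dab_gray(ref)))
        else:
            frozen[modality] = collagen.batch_threshold([ref], mode,
                                                        cfg.threshold_strategy)
    return frozen


def run_study(config: RunConfig) -> RunResult:
    """Execute a full study run; returns tables, reports and the audit trail.

    Per-image failures (missing file, bad modality) are collected, the run
    continues, and the failure summary lands in the log and in the result.
    """
    config.validate()
    manifest, root = _load_manifest(Path(config.manifest))
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out} exists and is not empty; set overwrite")
    out.mkdir(parents=True, exist_ok=True)
    qc_dir = out / "qc" if config.write_qc else None
    if qc_dir is not None:
        qc_dir.mkdir(exist_ok=True)

    frozen = _freeze_thresholds(manifest, root, config)

    rows, failures = [], []
    for _, row in manifest.sort_values(
        ["modality", "tendon", "stage_day", "biological_id", "technical_id"]
    ).iterrows():
        modality = row["modality"]
        stem = Path(row["image_path"]).stem
        try:
            if modality not in _ACQUISITION:
                raise ValueError(f"unknown modality {modality!r}")
            image = load_image(
                root / row["image_path"], float(row["pixel_size_um"]),
                _ACQUISITION[modality],
            )
            if modality == "he":
                metrics = _measure_he(image, config, qc_dir, stem)
            elif modality == "psr_pol":
                metrics = _measure_psr_pol(image, config, frozen["psr_pol"],
                                           qc_dir, stem)
            else:
                metrics = _measure_dab(image, config, frozen["dab"])
        except Exception as exc:  # per-row failure: collect and continue
            failures.append({"image_path": row["image_path"], "error": str(exc)})
            continue
        for metric, value in metrics.items():
            rows.append({
                "tendon": row["tendon"],
                "stage_day": int(row["stage_day"]),
                "hh_stage": DAY_TO_HH[int(row["stage_day"])],
                "biological_id": row["biological_id"],
                "technical_id": row["technical_id"],
                "metric": metric,
                "value": value,
            })

    study = pd.DataFrame(rows).sort_values(
        ["metric", "tendon", "stage_day", "biological_id", "technical_id"]
    ).reset_index(drop=True)
    study.to_csv(out / "study_table.csv", index=False)

    biological = aggregate_biological(study)
    biological.to_csv(out / "biological_means.csv", index=False)
    reports = run_study_tests(biological, alpha=config.alpha)
    reports_to_frame(reports).to_csv(out / "test_reports.csv", index=False)
    (out / "test_reports.json").write_text(
        json.dumps([r.as_dict() for r in reports], indent=2, default=str)
    )

    log_lines = [
        f"manifest: {config.manifest}",
        f"alpha: {config.alpha}",
        f"base_seed: {config.base_seed}",
        f"threshold_strategy: {config.threshold_strategy}",
        *(f"frozen_threshold[{k}]: {v}" for k, v in sorted(frozen.items())),
        f"maturity: net>={config.maturity.net_intensity_min} "
        f"green<={config.maturity.green_max_ratio} "
        f"red>={config.maturity.red_min_ratio}",
        f"segmentation: {config.segmentation}",
        f"images_measured: {len(manifest) - len(failures)}",
        f"images_failed: {len(failures)}",
        *(f"failure: {f['image_path']}: {f['error']}" for f in failures),
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return RunResult(study, biological, reports, frozen, failures, out)
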