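"""DAB immunohistochemistry quantification.

HRP immunostains deposit brown DAB chromogen wherever the target protein
(here TNC, COL3, LOX, MMP2 or MMP9) is present, over a hematoxylin
counterstain. Quantification separates the RGB frame with the H-DAB stain
matrix, rescales the DAB concentration channel to 8 bits against a fixed OD
ceiling, thresholds at a level frozen per protein target, and reports the
positive percentage area within each ROI.

The fixed OD ceiling (rather than per-image min-max scaling) is what makes a
single frozen threshold comparable across all replicates and stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .collagen import AreaFractionResult, OD_CEILING, area_fraction, od_to_8bit
from .image import CalibratedImage
from .roi import Roi, full_image_roi
from .stains import StainMatrix, deconvolve, default_matrix


@dataclass(frozen=True)
class IhcConfig:
    """Per-target DAB quantification settings.

    ``dab_threshold`` is the 8-bit level frozen for the whole run of one
    protein target; set it directly (``threshold_strategy='fixed'``) or from
    :func:`tendonquant.collagen.batch_threshold` before measuring.
    """

    target_name: str
    dab_threshold: int | None = None
    threshold_strategy: str = "otsu_on_reference"
    od_ceiling: float = OD_CEILING

    def with_threshold(self, level: int) -> "IhcConfig":
        return replace(self, dab_threshold=int(level))


def dab_gray(
    image: CalibratedImage,
    matrix: StainMatrix | None = None,
    od_ceiling: float = OD_CEILING,
):
    """H-DAB separation -> DAB concentration channel rescaled to uint8."""
    channels = deconvolve(image, matrix or default_matrix("H-DAB"))
    return od_to_8bit(channels["dab"], od_ceiling)


def dab_area_fraction(
    image: CalibratedImage,
    roi: Roi | None = None,
    config: IhcConfig | None = None,
    matrix: StainMatrix | None = None,
) -> AreaFractionResult:
    """DAB-positive percentage area within an ROI at the frozen threshold."""
    cfg = config if config is not None else IhcConfig("unknown")
    if cfg.dab_threshold is None:
        raise ValueError(
            f"no frozen DAB threshold for target {cfg.target_name!r}; "
            "calibrate one first (batch_threshold or IhcConfig.with_threshold)"
        )
    if image.modality != "brightfield":
        raise ValueError("DAB quantification runs on brightfield images")
    gray = dab_gray(image, matrix, cfg.od_ceiling)
    return area_fraction(
        gray,
        cfg.dab_threshold,
        "above",
        f"dab_{cfg.target_name}",
        roi or full_image_roi(image),
    )
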