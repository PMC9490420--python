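"""Colour deconvolution: separate RGB brightfield images into stain channels.

Brightfield histology obeys Beer–Lambert absorption: the optical density (OD)
of a pixel is a non-negative combination of per-stain OD "direction" vectors.
Given the 3×3 matrix of stain vectors, per-pixel stain concentrations are
recovered by matrix inversion — the classical colour-deconvolution scheme of
Ruifrok & Johnston, which is also what the Fiji H&E / H-DAB presets implement.

Default vectors are the published Ruifrok–Johnston values; alternative
matrices can be loaded from a small JSON/YAML config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image import CalibratedImage

#: Guard against log(0) for pure-black pixels; conventional 1/255 offset.
OD_EPSILON = 1.0 / 255.0

# Ruifrok & Johnston stain OD vectors (RGB order), as shipped by Fiji's
# colour-deconvolution presets. Third vector is completed by cross product.
_RUIFROK = {
    "H&E": {
        "channel_names": ("hematoxylin", "eosin", "residual"),
        "vectors": [
            [0.644211, 0.716556, 0.266844],
            [0.092789, 0.954111, 0.283111],
        ],
    },
    "H-DAB": {
        "channel_names": ("hematoxylin", "dab", "residual"),
        "vectors": [
            [0.650, 0.704, 0.286],
            [0.269, 0.570, 0.776],
        ],
    },
}


def _complete_third_vector(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Cross-product completion of the residual stain vector.

    The result is rectified to be non-negative and unit norm, matching the
    convention of the Fiji plugin.
    """
    v3 = np.cross(v1, v2)
    v3 = np.abs(v3)
    n = np.linalg.norm(v3)
    if n < 1e-12:
        raise ValueError("first two stain vectors are collinear")
    return v3 / n


@dataclass(frozen=True)
class StainMatrix:
    """A named set of three unit-norm stain OD direction vectors (RGB order)."""

    name: str
    vectors: np.ndarray  # shape (3, 3); rows are stains
    channel_names: tuple[str, str, str]

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must have unit norm, got norms {norms}")
        if np.any(v < -1e-12):
            raise ValueError("stain vector components must be non-negative")
        if abs(np.linalg.det(v)) < 1e-9:
            raise ValueError("stain vectors are linearly dependent (singular matrix)")
        if len(self.channel_names) != 3:
            raise ValueError("need exactly 3 channel names")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def inverse(self) -> np.ndarray:
        """Inverse mapping OD (RGB) -> stain concentrations."""
        return np.linalg.inv(self.vectors)


@dataclass
class StainChannels:
    """Per-stain concentration maps produced by :func:`deconvolve`."""

    channels: np.ndarray  # shape (H, W, 3), float
    channel_names: tuple[str, str, str]
    pixel_size_um: float
    matrix: StainMatrix = field(repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.channels[:, :, i]

    def save(self, path: str | Path, channel: str) -> None:
        """Export one channel as 32-bit float TIFF."""
        tifffile.imwrite(Path(path), self[channel].astype(np.float32))


def default_matrix(kind: str) -> StainMatrix:
    """Return the standard published stain matrix for ``"H&E"`` or ``"H-DAB"``."""
    if kind not in _RUIFROK:
        raise ValueError(
            f"unknown stain pair {kind!r}; supported kinds: {sorted(_RUIFROK)}"
        )
    entry = _RUIFROK[kind]
    v1, v2 = (np.asarray(v, dtype=float) for v in entry["vectors"])
    v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
    v3 = _complete_third_vector(v1, v2)
    return StainMatrix(kind, np.stack([v1, v2, v3]), entry["channel_names"])


def load_matrix(path: str | Path) -> StainMatrix:
    """Load a stain matrix from a JSON or YAML config file.

    Expected keys: ``name``, ``vectors`` (2 or 3 RGB triplets; a missing third
    is completed by cross product), ``channel_names``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    vecs = [np.asarray(v, dtype=float) for v in cfg["vectors"]]
    vecs = [v / np.linalg.norm(v) for v in vecs]
    if len(vecs) == 2:
        vecs.append(_complete_third_vector(vecs[0], vecs[1]))
    return StainMatrix(cfg["name"], np.stack(vecs), tuple(cfg["channel_names"]))


def rgb_to_od(image: CalibratedImage | np.ndarray) -> np.ndarray:
    """Beer–Lambert transform: 8-bit RGB intensities to optical densities.

    OD = -log10((I + eps) / 255) with eps = 1/255 guarding zeros; monotone
    decreasing in intensity, ~0 for white and finite (~2.4) for black.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError("rgb_to_od expects an (H, W, 3) RGB array")
    return -np.log10((px.astype(float) + OD_EPSILON) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, re-quantized to uint8."""
    intensity = 255.0 * np.power(10.0, -np.asarray(od, dtype=float)) - OD_EPSILON
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def deconvolve_od(
    od: np.ndarray, matrix: StainMatrix, clip_negative: bool = True
) -> np.ndarray:
    """Invert the stain matrix on a float OD array (..., 3) -> concentrations.

    This is the exact linear inversion: on unquantized OD it recovers the
    generating concentrations to machine precision. Going through an 8-bit
    image instead limits agreement to the quantization step (~1e-3 OD).
    """
    conc = np.asarray(od, dtype=float) @ matrix.inverse
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc


def deconvolve(
    image: CalibratedImage,
    matrix: StainMatrix | None = None,
    clip_negative: bool = True,
) -> StainChannels:
    """Separate an RGB brightfield image into per-stain concentration maps.

    Applies the inverse stain matrix to per-pixel OD. Negative concentrations
    (physically impossible; produced by noise) are clipped to zero by default.
    """
    if matrix is None:
        matrix = default_matrix("H&E")
    conc = deconvolve_od(rgb_to_od(image), matrix, clip_negative)
    return StainChannels(conc, matrix.channel_names, image.pixel_size_um, matrix)


def compose(
    concentrations: np.ndarray, matrix: StainMatrix, pixel_size_um: float,
    modality: str = "brightfield",
) -> CalibratedImage:
    """Forward Beer–Lambert model: stain concentration maps -> RGB image.

    This is the synthesis counterpart of :func:`deconvolve`; building phantoms
    through it makes the deconvolution round trip exactly testable.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 3 or conc.shape[2] != 3:
        raise ValueError("expected (H, W, 3) concentration array")
    od = conc @ matrix.vectors
    return CalibratedImage(od_to_rgb(od), pixel_size_um, modality)
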