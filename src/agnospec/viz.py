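"""Reconstruction and visualization helpers.

Three views of the data:

* model feature images reconstructed from PCA score coordinates
  (mean image + score_1 * component_1 + score_2 * component_2), used to
  map the spectral space a classifier operates over;
* RGB rasters of a feature image, with three chosen KMD slices mapped
  to the red, green and blue channels (equal slices blend to gray);
* van Krevelen coordinates (O/C vs H/C atomic ratios) from peak lists
  that carry pre-assigned elemental formulas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .featurize import HistogramConfig

__all__ = [
    "FormulaRecord",
    "parse_formula",
    "reconstruct_image",
    "reconstruct_grid",
    "render_rgb",
    "van_krevelen",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)\s*(\d*)")
_CHNOS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class FormulaRecord:
    """An elemental composition with its associated peak intensity."""

    counts: dict[str, int] = field(default_factory=dict)
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.counts.get("C", 0) < 1:
            raise ValueError("formula must contain at least one carbon")
        if self.counts.get("H", 0) < 0:
            raise ValueError("negative hydrogen count")


def parse_formula(
    text: str, intensity: float = 1.0, allow_extra: bool = False
) -> FormulaRecord:
    """Parse a composition string like ``C16H32O2`` or ``C6 H12 O6``.

    Elements outside the CHNOS alphabet are rejected unless
    ``allow_extra`` is set (extra elements are then carried through but
    ignored by the ratio computations).
    """
    counts: dict[str, int] = {}
    consumed = 0
    for m in _FORMULA_RE.finditer(text.strip()):
        if not m.group(1):
            continue
        consumed += len(m.group(0).strip())
        el, num = m.group(1), int(m.group(2) or 1)
        if el not in _CHNOS and not allow_extra:
            raise ValueError(f"element {el!r} outside CHNOS in {text!r}")
        counts[el] = counts.get(el, 0) + num
    if consumed != len(text.strip().replace(" ", "")) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return FormulaRecord(counts, intensity)


def reconstruct_image(
    model: PCA,
    score_1: float,
    score_2: float,
    shape: tuple[int, int, int] = HistogramConfig().shape,
) -> np.ndarray:
    """Model feature image at a (PC1, PC2) score coordinate.

    Returns ``mean + score_1 * component_1 + score_2 * component_2``
    reshaped to the image shape.  Values are raw linear combinations —
    they may exceed the transform range; clipping happens only at
    render time.
    """
    if getattr(model, "components_", None) is None or model.n_components_ < 2:
        raise ValueError("model must be fitted with >= 2 components")
    vec = model.mean_ + score_1 * model.components_[0] + score_2 * model.components_[1]
    return vec.reshape(shape)


def reconstruct_grid(
    model: PCA,
    scores: np.ndarray,
    n: int = 8,
    shape: tuple[int, int, int] = HistogramConfig().shape,
) -> np.ndarray:
    """An n x n grid of model images spanning the observed score extremes.

    ``scores`` holds observed (PC1, PC2) score pairs; the grid spans the
    per-component min..max independently.  Returns an array of shape
    (n, n, *image shape): first index is the PC2 row (ascending), second
    the PC1 column.
    """
    scores = np.asarray(scores, dtype=float)
    s1 = np.linspace(scores[:, 0].min(), scores[:, 0].max(), n)
    s2 = np.linspace(scores[:, 1].min(), scores[:, 1].max(), n)
    return np.array(
        [[reconstruct_image(model, a, b, shape) for a in s1] for b in s2]
    )


def render_rgb(
    img: np.ndarray,
    kmd_bins: tuple[int, int, int] = (2, 3, 4),
    cfg: HistogramConfig = HistogramConfig(),
) -> np.ndarray:
    """RGB raster of a feature image from three KMD slices.

    The selected slices (0-based KMD bin indices; the default picks the
    central and high-defect bins) become the red, green and blue
    channels, linearly rescaled from the transform's value range
    [x_min, x_max] to [0, 1] and clipped.  Equal channel values render
    gray/white.
    """
    img = np.asarray(img, dtype=float)
    n_kmd = img.shape[2]
    for b in kmd_bins:
        if not 0 <= b < n_kmd:
            raise ValueError(f"KMD bin index {b} out of range 0..{n_kmd - 1}")
    channels = [img[:, :, b] for b in kmd_bins]
    rgb = np.stack(channels, axis=-1)
    rgb = (rgb - cfg.x_min) / (cfg.x_max - cfg.x_min)
    return np.clip(rgb, 0.0, 1.0)


def van_krevelen(records: list[FormulaRecord]) -> list[tuple[float, float, float]]:
    """Per-formula (O/C, H/C, intensity) triples for a van Krevelen plot."""
    out = []
    for r in records:
        c = r.counts.get("C", 0)
        if c < 1:
            raise ValueError("van Krevelen ratios need C >= 1")
        out.append((r.counts.get("O", 0) / c, r.counts.get("H", 0) / c, r.intensity))
    return out
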