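"""Pixel-wise SPAD inversion: masks, maps, rendering, and leaf statistics.

A fitted model is applied to every leaf pixel of a calibrated reflectance
cube at the selected wavelengths, producing a SPAD distribution map.
Background is removed with an NDVI threshold plus largest-connected-
component cleanup; per-leaf summary statistics (min, max, mean, std) are
computed over leaf pixels only. Predictions are deliberately not clipped to
the chlorophyll-meter range, so model pathologies (e.g. linear models
extrapolating far out of range) stay visible in the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .calibration import Hypercube
from .models import FittedModel
from .selection import SelectionResult

DEFAULT_NDVI_THRESHOLD = 0.3
RED_WL = 670.0
NIR_MIN_WL = 750.0
# Wavelength match tolerance: half of the nominal 3.6 nm band spacing.
WL_MATCH_TOL_NM = 1.8

# Green -> yellow -> red palette stops (low SPAD = red, high = green), as
# (fraction, RGB). Exact stops are a package choice; configurable.
DEFAULT_PALETTE = ((0.0, (200, 30, 30)), (0.5, (235, 220, 60)),
                   (1.0, (30, 150, 40)))


@dataclass
class SPADMap:
    """Per-pixel predicted SPAD with a leaf mask and summary statistics."""

    values: np.ndarray   # rows x cols, NaN on background
    mask: np.ndarray     # boolean leaf mask

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("empty leaf mask")

    @property
    def stats(self) -> dict:
        v = self.values[self.mask]
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "std": float(v.std())}


def leaf_mask(cube: Hypercube, threshold: float = DEFAULT_NDVI_THRESHOLD,
              keep_largest: bool = True) -> np.ndarray:
    """Leaf/background mask from NDVI = (NIR - red) / (NIR + red).

    Uses the band nearest 670 nm as red and the first band above 750 nm as
    NIR; pixels above the threshold, optionally reduced to the largest
    connected component, form the mask.
    """
    wl = cube.wavelengths
    nir_candidates = np.flatnonzero(wl > NIR_MIN_WL)
    if nir_candidates.size == 0:
        raise ValueError("cube has no band above 750 nm; cannot compute NDVI")
    red_band = int(np.argmin(np.abs(wl - RED_WL)))
    nir_band = int(nir_candidates[np.argmin(np.abs(wl[nir_candidates] - 860.0))])
    red = cube.data[:, :, red_band]
    nir = cube.data[:, :, nir_band]
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red == 0, 0.0, (nir - red) / (nir + red))
    mask = ndvi > threshold
    if keep_largest and mask.any():
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def match_wavelengths(grid: np.ndarray, targets: np.ndarray,
                      tol: float = WL_MATCH_TOL_NM) -> np.ndarray:
    """Nearest-neighbour indices of target wavelengths in the cube grid;
    raises if any target is farther than the tolerance."""
    grid = np.asarray(grid, float)
    idx = np.abs(grid[None, :] - np.asarray(targets, float)[:, None]).argmin(axis=1)
    err = np.abs(grid[idx] - targets)
    if np.any(err > tol):
        worst = float(err.max())
        raise ValueError(
            f"selected wavelength off-grid by {worst:.2f} nm (> {tol} nm)")
    return idx


def predict_map(cube: Hypercube, model: FittedModel,
                selection: SelectionResult = None,
                mask: np.ndarray = None,
                ndvi_threshold: float = DEFAULT_NDVI_THRESHOLD) -> SPADMap:
    """Apply the model to every leaf pixel at the selected wavelengths.

    The cube's grid is matched to the model's wavelengths by nearest
    neighbour within half a band spacing. ``selection``, when given, must
    agree with the model's band set. Background pixels stay NaN.
    """
    if selection is not None:
        if not np.allclose(np.sort(selection.wavelengths),
                           np.sort(model.wavelengths)):
            raise ValueError("selection and model band sets disagree")
    if mask is None:
        mask = leaf_mask(cube, threshold=ndvi_threshold)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("leaf mask is empty; nothing to predict")
    band_idx = match_wavelengths(cube.wavelengths, model.wavelengths)
    pixels = cube.data[mask][:, band_idx]
    values = np.full(mask.shape, np.nan)
    values[mask] = model.predict(pixels)
    return SPADMap(values=values, mask=mask)


def _palette_lut(palette=DEFAULT_PALETTE) -> np.ndarray:
    """256 x 3 uint8 lookup table interpolated from the palette stops."""
    fracs = np.array([p[0] for p in palette])
    cols = np.array([p[1] for p in palette], dtype=float)
    x = np.linspace(0, 1, 256)
    lut = np.stack([np.interp(x, fracs, cols[:, c]) for c in range(3)], axis=1)
    return np.clip(np.round(lut), 0, 255).astype(np.uint8)


def render_map(spad_map: SPADMap, out_path, vmin: float = 0.0,
               vmax: float = 80.0, palette=DEFAULT_PALETTE):
    """Write grayscale + colour PNGs of the map on fixed global limits.

    Fixed (vmin, vmax) limits keep different leaves on a shared scale.
    Values at/beyond the limits map to the palette endpoints; background is
    white. Returns (gray_path, color_path); output is deterministic for
    identical inputs.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if vmax <= vmin:
        raise ValueError("vmax must exceed vmin")
    norm = (spad_map.values - vmin) / (vmax - vmin)
    norm = np.clip(np.where(spad_map.mask, norm, 0.0), 0.0, 1.0)
    level = np.round(norm * 255).astype(np.uint8)

    gray = np.where(spad_map.mask, level, 255).astype(np.uint8)
    gray_path = out_path.with_name(out_path.stem + "_gray.png")
    Image.fromarray(gray, mode="L").save(gray_path, format="PNG")

    lut = _palette_lut(palette)
    rgb = lut[level]
    rgb[~spad_map.mask] = (255, 255, 255)
    color_path = out_path.with_name(out_path.stem + "_color.png")
    Image.fromarray(rgb, mode="RGB").save(color_path, format="PNG")
    return gray_path, color_path


def stats_frame(maps: dict) -> pd.DataFrame:
    """Summary-statistics table for named SPAD maps (leaf id -> SPADMap)."""
    rows = []
    for name, m in maps.items():
        rows.append({"leaf": name, **m.stats})
    return pd.DataFrame(rows)
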