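"""Reflectance calibration of raw hypercubes and ROI spectrum extraction.

A hypercube is converted from raw digital numbers (DN) to reflectance with
white/dark reference frames:

    R = (DN_raw - DN_dark) / (DN_white - DN_dark)

Mean spectra are then extracted from rectangular regions of interest and
combined into a single weighted-average spectrum per leaf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

KINDS = ("raw_dn", "white_dn", "dark_dn", "reflectance")

# Reflectance outside this range is kept (not clipped) but counted and
# logged; real leaves can exceed 1 slightly at specular pixels.
REFLECTANCE_WARN_RANGE = (0.0, 1.5)


@dataclass
class Hypercube:
    """3-D spectral image: rows x cols x bands plus a wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands dimension {self.data.shape[2]} != wavelength grid "
                f"length {self.wavelengths.size}"
            )
        if self.kind not in KINDS:
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ROI:
    """Rectangular region of interest; 0-based, half-open pixel intervals."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    weight: float = None  # default: proportional to pixel count

    def __post_init__(self):
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError(f"empty ROI: {self}")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError(f"negative ROI coordinates: {self}")
        if self.weight is not None and self.weight < 0:
            raise ValueError("ROI weight must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)


def _as_reference(frame: Hypercube, target_shape) -> np.ndarray:
    """Broadcast a reference cube to the target shape.

    Accepts a full cube, a single-row frame (1 x cols x bands, broadcast
    along rows), or a single-column frame (rows x 1 x bands).
    """
    d = frame.data
    rows, cols, bands = target_shape
    if d.shape == target_shape:
        return d
    if d.shape == (1, cols, bands) or d.shape == (rows, 1, bands):
        return np.broadcast_to(d, target_shape)
    raise ValueError(
        f"reference frame shape {d.shape} incompatible with cube shape {target_shape}"
    )


def calibrate(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Convert a raw DN cube to reflectance using white/dark references.

    Elements where the denominator (white - dark) is zero are flagged invalid
    as NaN rather than propagating infinities. Raises if the denominator is
    zero everywhere or the wavelength grids disagree.
    """
    for ref in (white, dark):
        if not np.allclose(ref.wavelengths, raw.wavelengths):
            raise ValueError("wavelength grids of cube and references differ")
    w = _as_reference(white, raw.shape)
    d = _as_reference(dark, raw.shape)
    denom = w - d
    bad = denom == 0
    if bad.all():
        raise ValueError("white - dark is zero everywhere; cannot calibrate")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(bad, np.nan, (raw.data - d) / np.where(bad, 1.0, denom))
    lo, hi = REFLECTANCE_WARN_RANGE
    n_out = int(np.sum((refl < lo) | (refl > hi)))
    if n_out:
        log.warning("calibrate: %d reflectance values outside [%g, %g] (kept)",
                    n_out, lo, hi)
    return Hypercube(refl, raw.wavelengths.copy(), kind="reflectance")


def extract_roi_spectra(cube: Hypercube, rois: list):
    """Per-ROI mean spectra and their weighted average.

    Returns ``(per_roi, combined)`` where ``per_roi`` is k x p (one mean
    spectrum per ROI) and ``combined`` is the weighted average across ROIs.
    ROIs without an explicit weight contribute proportionally to their pixel
    count, which makes the combined spectrum equal to the plain per-pixel
    mean over all ROI pixels when no weights are given.
    """
    if cube.kind != "reflectance":
        raise ValueError(f"expected a reflectance cube, got kind {cube.kind!r}")
    if not rois:
        raise ValueError("at least one ROI is required")
    rows, cols, _ = cube.shape
    spectra, weights = [], []
    for roi in rois:
        if roi.row_max > rows or roi.col_max > cols:
            raise ValueError(f"ROI {roi} outside image bounds {rows}x{cols}")
        block = cube.data[roi.row_min:roi.row_max, roi.col_min:roi.col_max, :]
        spectra.append(block.reshape(-1, block.shape[-1]).mean(axis=0))
        weights.append(roi.n_pixels if roi.weight is None else roi.weight)
    per_roi = np.vstack(spectra)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("ROI weights sum to zero")
    combined = (w[:, None] * per_roi).sum(axis=0) / w.sum()
    return per_roi, combined


def parse_roi_block(text: str) -> list:
    """Parse a plain-text ROI block: one rectangle per line as
    ``row_min row_max col_min col_max [weight]``; '#' starts a comment."""
    rois = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"bad ROI line: {line!r}")
        nums = [int(v) for v in parts[:4]]
        weight = float(parts[4]) if len(parts) == 5 else None
        rois.append(ROI(*nums, weight=weight))
    return rois
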