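"""Synthetic leaf spectra, SPAD values, and hypercubes with known ground truth.

Emulates the statistical structure of seedling-stage pepper-leaf imaging data:
400-1000 nm reflectance at ~3.6 nm sampling (176 bands), a vegetation-like
spectral shape (green peak near 550 nm, chlorophyll-absorption trough near
670 nm, red edge, NIR plateau), SPAD values stratified by leaf position
(lower > middle > upper tiers), and a band-localised SPAD -> reflectance
dependency with spectrally correlated additive noise.

The generator is the ground-truth source for every downstream stage: band
selectors should recover the planted informative bands, calibration should
invert the DN encoding exactly, and pixel-wise inversion should recover the
planted SPAD field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import Hypercube
from .dataset import POSITIONS, SpectralDataset

# Default planted wavelengths: visible bands respond negatively to SPAD
# (more chlorophyll -> more absorption), NIR bands positively (denser
# mesophyll -> more scattering).
DEFAULT_INFORMATIVE_WL = (550.0, 560.0, 620.0, 670.0, 700.0, 720.0,
                          850.0, 880.0, 920.0, 960.0)

# 12-bit DN encoding for synthetic cubes: dark current ~2% and white
# reference ~95% of full scale; values are kept unquantised floats so the
# reflectance calibration is an exact algebraic inverse.
DN_FULL_SCALE = 4095.0
DN_DARK_FRACTION = 0.02
DN_WHITE_FRACTION = 0.95
BACKGROUND_REFLECTANCE = 0.04


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated experiment: 150 leaves in three tiers of 50,
    tier SPAD means 66.0 / 61.0 / 48.3 (lower/middle/upper), 176 bands over
    400-1000 nm. Effect sizes and noise are chosen so planted bands carry
    strong (|rho| ~ 0.9) marginal correlations, comparable to the strongest
    bands seen in vegetation spectra.
    """

    n_samples: int = 150
    n_bands: int = 176
    wl_min: float = 400.0
    wl_max: float = 1000.0
    informative_bands: tuple = None  # band indices; default derived from wavelengths
    effect_sizes: tuple = None       # reflectance change per SD of SPAD
    noise_sd: float = 0.004
    spectral_corr_length: float = 5.0  # bands; Gaussian kernel sigma
    position_means: tuple = (66.0, 61.0, 48.3)  # lower, middle, upper
    position_sds: tuple = (3.0, 3.0, 3.0)
    link: str = "linear"  # or "quadratic" (band term depends on z^2)
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be < wl_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.link not in ("linear", "quadratic"):
            raise ValueError(f"unknown link: {self.link!r}")
        if len(self.position_means) != len(self.position_sds):
            raise ValueError("position_means and position_sds must align")
        if self.informative_bands is None:
            wl = self.wavelengths()
            idx = sorted({int(np.argmin(np.abs(wl - w)))
                          for w in DEFAULT_INFORMATIVE_WL})
            self.informative_bands = tuple(idx)
        self.informative_bands = tuple(int(b) for b in self.informative_bands)
        for b in self.informative_bands:
            if not 0 <= b < self.n_bands:
                raise ValueError(f"informative_bands entry {b} outside [0, {self.n_bands})")
        if self.effect_sizes is None:
            wl = self.wavelengths()
            self.effect_sizes = tuple(
                0.01 if wl[b] > 720.0 else -0.01 for b in self.informative_bands
            )
        if len(self.effect_sizes) != len(self.informative_bands):
            raise ValueError("effect_sizes must align with informative_bands")

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)

    def population_moments(self) -> tuple:
        """Mean and SD of the SPAD mixture over tiers (equal tier weights)."""
        means = np.asarray(self.position_means, float)
        sds = np.asarray(self.position_sds, float)
        mu = means.mean()
        var = (sds**2).mean() + means.var()
        return mu, float(np.sqrt(var))


def vegetation_template(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like base reflectance: piecewise-Gaussian bumps.

    Low blue baseline, green peak near 550 nm, chlorophyll trough near
    670 nm, sigmoidal red edge to an NIR plateau near 0.45.
    """
    wl = np.asarray(wavelengths, float)
    base = 0.05 + 0.10 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    base -= 0.02 * np.exp(-0.5 * ((wl - 670.0) / 25.0) ** 2)
    red_edge = 0.40 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    return base + red_edge


def _correlated_noise(rng: np.random.Generator, shape: tuple,
                      sd: float, corr_length: float) -> np.ndarray:
    """Band-correlated Gaussian noise with stationary marginal SD `sd`.

    White noise convolved along the last (spectral) axis with a Gaussian
    kernel of sigma `corr_length` bands, L2-normalised so the marginal SD is
    preserved; circular boundary keeps the process stationary.
    """
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if corr_length <= 0:
        return sd * white
    radius = max(1, int(np.ceil(4 * corr_length)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / corr_length) ** 2)
    kernel /= np.linalg.norm(kernel)
    return sd * ndimage.convolve1d(white, kernel, axis=-1, mode="wrap")


def _spad_to_z(spad: np.ndarray, cfg: SimConfig) -> np.ndarray:
    mu, sigma = cfg.population_moments()
    return (np.asarray(spad, float) - mu) / sigma


def _spectra_from_spad(spad: np.ndarray, cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Reflectance rows for the given SPAD values: template + planted band
    terms + correlated noise."""
    spad = np.atleast_1d(np.asarray(spad, float))
    wl = cfg.wavelengths()
    z = _spad_to_z(spad, cfg)
    # quadratic link adds curvature (z + 0.4 z^2) that a linear model cannot
    # remove by any band combination, while staying mostly monotone
    signal = z + 0.4 * z**2 if cfg.link == "quadratic" else z
    X = np.tile(vegetation_template(wl), (spad.size, 1))
    for b, e in zip(cfg.informative_bands, cfg.effect_sizes):
        X[:, b] += e * signal
    X += _correlated_noise(rng, X.shape, cfg.noise_sd, cfg.spectral_corr_length)
    return X


def generate_dataset(cfg: SimConfig) -> SpectralDataset:
    """Draw a stratified SPAD sample (three leaf tiers) and its spectra.

    Reproducible under ``cfg.seed``. Tier sizes are as equal as possible,
    lower tiers taking the remainder first, matching a balanced collection of
    leaves per position.
    """
    rng = np.random.default_rng(cfg.seed)
    n_tiers = len(cfg.position_means)
    sizes = [cfg.n_samples // n_tiers] * n_tiers
    for i in range(cfg.n_samples % n_tiers):
        sizes[i] += 1
    y_parts, labels = [], []
    for tier, (m, s, k) in enumerate(zip(cfg.position_means, cfg.position_sds, sizes)):
        y_parts.append(rng.normal(m, s, size=k))
        labels += [POSITIONS[tier % len(POSITIONS)]] * k
    y = np.concatenate(y_parts)
    X = _spectra_from_spad(y, cfg, rng)
    return SpectralDataset(X=X, y=y, wavelengths=cfg.wavelengths(),
                           position_labels=labels)


def generate_hypercube(spad_field: np.ndarray, leaf_mask: np.ndarray,
                       cfg: SimConfig):
    """Raw/white/dark DN cubes whose calibration recovers the planted spectra.

    Each leaf pixel gets a spectrum from its SPAD value via the same model as
    :func:`generate_dataset`; background pixels get a flat low-reflectance
    spectrum. DN encoding: ``raw = dark + R * (white - dark)`` with constant
    reference frames, so ``calibrate(raw, white, dark)`` is exact.

    Returns ``(raw, white, dark, truth)`` where truth is the SPAD field with
    NaN outside the mask.
    """
    spad_field = np.asarray(spad_field, float)
    leaf_mask = np.asarray(leaf_mask, bool)
    if spad_field.shape != leaf_mask.shape:
        raise ValueError(
            f"spad_field shape {spad_field.shape} != leaf_mask shape {leaf_mask.shape}"
        )
    rng = np.random.default_rng(cfg.seed)
    rows, cols = spad_field.shape
    wl = cfg.wavelengths()
    R = np.empty((rows, cols, cfg.n_bands))
    flat = np.full(cfg.n_bands, BACKGROUND_REFLECTANCE)
    R[~leaf_mask] = flat
    if cfg.noise_sd > 0:
        R[~leaf_mask] += _correlated_noise(
            rng, ((~leaf_mask).sum(), cfg.n_bands), cfg.noise_sd,
            cfg.spectral_corr_length)
    if leaf_mask.any():
        R[leaf_mask] = _spectra_from_spad(spad_field[leaf_mask], cfg, rng)

    dark_dn = np.full_like(R, DN_DARK_FRACTION * DN_FULL_SCALE)
    white_dn = np.full_like(R, DN_WHITE_FRACTION * DN_FULL_SCALE)
    raw_dn = dark_dn + R * (white_dn - dark_dn)

    truth = np.where(leaf_mask, spad_field, np.nan)
    return (
        Hypercube(raw_dn, wl, kind="raw_dn"),
        Hypercube(white_dn, wl, kind="white_dn"),
        Hypercube(dark_dn, wl, kind="dark_dn"),
        truth,
    )


def elliptical_leaf_mask(rows: int, cols: int, margin: float = 0.12) -> np.ndarray:
    """Convenience leaf silhouette: an ellipse inscribed with the given margin."""
    r = (np.arange(rows) - (rows - 1) / 2) / (rows * (0.5 - margin))
    c = (np.arange(cols) - (cols - 1) / 2) / (cols * (0.5 - margin))
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0
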