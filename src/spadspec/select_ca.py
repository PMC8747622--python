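"""Correlation-based characteristic band screening.

Per band, Spearman's rank correlation between reflectance and SPAD is
computed (product-moment correlation of average-rank-transformed values, with
a two-sided p-value from the large-sample t approximation); bands with
|rho| above a threshold and p below a significance level are retained.

The absolute value is used deliberately: strong visible-band correlations
are negative (chlorophyll absorbs), strong NIR correlations positive, and
both carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import SpectralDataset
from .selection import SelectionResult

DEFAULT_RHO_THRESHOLD = 0.65
DEFAULT_ALPHA = 0.01


@dataclass
class Correlogram:
    """Per-band Spearman rho and p-value over the wavelength grid.

    Bands where the correlation is undefined (constant reflectance or
    constant SPAD) carry NaN, not zero.
    """

    rho: np.ndarray
    pvalue: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, float)
        self.pvalue = np.asarray(self.pvalue, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if not (self.rho.size == self.pvalue.size == self.wavelengths.size):
            raise ValueError("rho, pvalue and wavelengths must align")
        ok = np.isfinite(self.rho)
        if np.any(np.abs(self.rho[ok]) > 1 + 1e-12):
            raise ValueError("rho outside [-1, 1]")


def _spearman_with_p(x: np.ndarray, y_ranks: np.ndarray, n: int):
    if np.ptp(x) == 0:
        return np.nan, np.nan
    rho = np.corrcoef(stats.rankdata(x), y_ranks)[0, 1]
    # large-sample t approximation, df = n - 2
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def spearman_correlogram(ds: SpectralDataset) -> Correlogram:
    """Spearman rho and two-sided p per band against the SPAD vector."""
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for a correlogram")
    if np.ptp(ds.y) == 0:
        rho = np.full(ds.n_bands, np.nan)
        return Correlogram(rho, rho.copy(), ds.wavelengths)
    y_ranks = stats.rankdata(ds.y)
    rho = np.empty(ds.n_bands)
    pval = np.empty(ds.n_bands)
    for j in range(ds.n_bands):
        rho[j], pval[j] = _spearman_with_p(ds.X[:, j], y_ranks, n)
    return Correlogram(rho, pval, ds.wavelengths)


def select_by_correlation(cg: Correlogram,
                          rho_threshold: float = DEFAULT_RHO_THRESHOLD,
                          alpha: float = DEFAULT_ALPHA) -> SelectionResult:
    """Bands with |rho| > threshold and p < alpha (undefined bands excluded).

    No multiple-testing correction is applied: the screening rule is a plain
    per-band significance test, documented as such.
    """
    with np.errstate(invalid="ignore"):
        keep = (np.abs(cg.rho) > rho_threshold) & (cg.pvalue < alpha)
    keep &= np.isfinite(cg.rho)
    return SelectionResult(
        method="ca",
        indices=np.flatnonzero(keep),
        grid=cg.wavelengths,
        diagnostics={"rho": cg.rho, "pvalue": cg.pvalue,
                     "rho_threshold": rho_threshold, "alpha": alpha},
    )
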