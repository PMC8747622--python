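"""Tabular container for leaf reflectance spectra with SPAD labels.

The modelling unit throughout the package is an ``n x p`` reflectance matrix
with a SPAD value per sample, a strictly ascending wavelength grid, and a
leaf-position label (lower / middle / upper) per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIONS = ("lower", "middle", "upper")


@dataclass
class SpectralDataset:
    """Reflectance spectra (rows) with per-sample SPAD values.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Reflectance, nominally in [0, ~1].
    y : ndarray, shape (n,)
        SPAD readings (dimensionless chlorophyll-meter units).
    wavelengths : ndarray, shape (p,)
        Band centres in nm, strictly increasing.
    sample_ids : list of str
    position_labels : list of str
        Leaf tier per sample, one of ``lower``/``middle``/``upper``.
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list = field(default_factory=list)
    position_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if self.wavelengths.shape != (p,):
            raise ValueError(
                f"wavelengths has length {self.wavelengths.size}, expected {p}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite (no missing values)")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        if not self.position_labels:
            self.position_labels = ["lower"] * n
        if len(self.sample_ids) != n or len(self.position_labels) != n:
            raise ValueError("sample_ids / position_labels must have length n")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def band_subset(self, indices) -> "SpectralDataset":
        """Dataset restricted to the given band indices (kept sorted by wavelength)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return SpectralDataset(
            X=self.X[:, idx],
            y=self.y.copy(),
            wavelengths=self.wavelengths[idx],
            sample_ids=list(self.sample_ids),
            position_labels=list(self.position_labels),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{w:.1f}": self.X[:, j] for j, w in enumerate(self.wavelengths)}
        return pd.DataFrame(
            {
                "id": self.sample_ids,
                "position": self.position_labels,
                "spad": self.y,
                **cols,
            }
        )

    def to_csv(self, path) -> None:
        """One row per sample: id, position, SPAD, then one column per wavelength
        (header = wavelength in nm, one decimal)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        df = pd.read_csv(path)
        meta = ["id", "position", "spad"]
        wl_cols = [c for c in df.columns if c not in meta]
        return cls(
            X=df[wl_cols].to_numpy(float),
            y=df["spad"].to_numpy(float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            sample_ids=df["id"].astype(str).tolist(),
            position_labels=df["position"].astype(str).tolist(),
        )
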