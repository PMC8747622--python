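"""Shared container for characteristic-band selection results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionResult:
    """Bands chosen by a selector, with enough context to compare methods.

    ``indices`` index into the full wavelength grid ``grid`` (length p);
    ``wavelengths`` are the selected band centres, sorted ascending.
    ``diagnostics`` carries per-algorithm extras (correlogram, RMSECV path,
    round history) for plotting and serialisation.
    """

    method: str
    indices: np.ndarray
    grid: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= self.grid.size):
            raise ValueError("selection indices outside the wavelength grid")
        # unique + ascending index order == ascending wavelength order
        self.indices = idx

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid[self.indices]

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    @property
    def n_bands(self) -> int:
        return int(self.grid.size)

    @property
    def fraction(self) -> float:
        """Selected share of the full band set."""
        return self.n_selected / self.n_bands

    def to_frame(self) -> pd.DataFrame:
        sel = np.zeros(self.n_bands, dtype=bool)
        sel[self.indices] = True
        df = pd.DataFrame({
            "band": np.arange(self.n_bands),
            "wavelength_nm": self.grid,
            "selected": sel,
        })
        for key in ("rho", "pvalue"):
            if key in self.diagnostics:
                df[key] = self.diagnostics[key]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
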