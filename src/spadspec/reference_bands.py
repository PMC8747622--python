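"""Published characteristic-band selections for pepper-leaf SPAD estimation.

The three selectors (correlation screening, sCARS, IRIV) have published band
lists of 76, 46, and 26 wavelengths out of a 176-band instrument grid. The
sCARS and IRIV lists are printed in full; the correlation-screened list is
printed as 15 explicit wavelengths plus a contiguous 771.1-990.4 nm block of
61 bands. The instrument's exact grid was never published (some listed
wavelengths even fall outside the instrument's nominal 400-1000 nm range),
so this module reconstructs the block and the full grid synthetically: the
block is a uniform 61-point grid whose points are snapped to every published
NIR wavelength it must contain, and the full grid pads the union of all
lists with evenly spaced fillers up to 176 bands. Counts and fractions are
exact; individual filler wavelengths are stand-ins.
"""

from __future__ import annotations

import numpy as np

from .selection import SelectionResult

N_TOTAL_BANDS = 176

CA_EXPLICIT = (
    533.3, 536.7, 540.0, 543.4, 546.7, 550.1, 553.4, 556.8, 560.1,
    697.1, 700.6, 704.1, 707.6, 711.1, 767.6,
)
CA_BLOCK_RANGE = (771.1, 990.4)
CA_BLOCK_COUNT = 61  # 76 published bands minus the 15 explicit ones

SCARS_BANDS = (
    386.6, 392.9, 402.5, 415.4, 431.5, 526.7, 530.0, 590.5, 593.9, 597.3,
    600.7, 610.9, 614.3, 617.7, 624.6, 641.7, 645.1, 676.2, 679.7, 683.2,
    693.6, 711.1, 718.1, 732.2, 832.1, 850.2, 853.8, 868.4, 872.0, 875.7,
    879.3, 890.3, 894.0, 916.0, 919.7, 923.4, 927.1, 930.8, 938.2, 945.6,
    953.0, 960.5, 971.7, 979.2, 982.9, 986.7,
)

IRIV_BANDS = (
    477.1, 490.3, 510.1, 526.7, 597.3, 600.7, 610.9, 614.3, 617.7, 624.6,
    628.0, 638.3, 648.6, 676.2, 725.1, 728.7, 839.3, 853.8, 861.1, 868.4,
    875.7, 879.3, 894.0, 916.0, 945.6, 979.2,
)


def _ca_block() -> np.ndarray:
    """The 61-band 771.1-990.4 nm block: uniform grid snapped to every
    published NIR wavelength that falls inside it (synthetic stand-in for
    the unpublished instrument grid)."""
    lo, hi = CA_BLOCK_RANGE
    grid = np.linspace(lo, hi, CA_BLOCK_COUNT)
    known = sorted(w for w in set(SCARS_BANDS) | set(IRIV_BANDS) if lo <= w <= hi)
    taken = np.zeros(grid.size, dtype=bool)
    for w in known:
        j = int(np.argmin(np.abs(grid - w)))
        while taken[j]:  # collision: move to the next free slot
            j += 1
        grid[j] = w
        taken[j] = True
    grid = np.sort(grid)
    assert np.unique(grid).size == CA_BLOCK_COUNT
    return grid


def ca_bands() -> np.ndarray:
    return np.sort(np.concatenate([CA_EXPLICIT, _ca_block()]))


def full_grid() -> np.ndarray:
    """A 176-band grid containing every listed wavelength, padded with
    evenly spaced synthetic fillers in the uncovered visible region."""
    listed = np.unique(np.concatenate(
        [ca_bands(), SCARS_BANDS, IRIV_BANDS]))
    n_fill = N_TOTAL_BANDS - listed.size
    if n_fill < 0:
        raise RuntimeError("listed bands exceed the grid size")
    fillers = []
    candidate = 400.0
    while len(fillers) < n_fill:
        if np.abs(listed - candidate).min() > 1.0:
            fillers.append(round(candidate, 1))
        candidate += 3.6
        if candidate > 1100.0:
            raise RuntimeError("could not place grid fillers")
    grid = np.sort(np.concatenate([listed, fillers]))
    assert grid.size == N_TOTAL_BANDS
    return grid


def reference_selection_results():
    """The three published selections as :class:`SelectionResult` objects on
    a shared 176-band grid. Returns ``{"ca": ..., "scars": ..., "iriv": ...}``."""
    grid = full_grid()

    def to_indices(wavelengths):
        idx = np.array([int(np.argmin(np.abs(grid - w))) for w in wavelengths])
        if not np.allclose(grid[idx], wavelengths, atol=1e-6):
            raise RuntimeError("band list not representable on the grid")
        return idx

    return {
        "ca": SelectionResult("ca", to_indices(ca_bands()), grid),
        "scars": SelectionResult("scars", to_indices(SCARS_BANDS), grid),
        "iriv": SelectionResult("iriv", to_indices(IRIV_BANDS), grid),
    }
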