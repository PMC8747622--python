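"""Stability competitive adaptive reweighted sampling (sCARS).

N Monte-Carlo runs each fit a PLS calibration model on a random fraction of
the samples using the currently retained bands. A band's weight is the
stability of its regression coefficient — mean magnitude divided by standard
deviation over B within-run bootstrap refits (a config switch falls back to
the plain |coefficient| of classic CARS). The number of retained bands
follows an exponentially decreasing schedule from all p bands at run 1 down
to two at run N; which bands fill the schedule is decided competitively: a
deterministic elite (top half of the schedule by weight) plus weighted
sampling without replacement for the remaining slots, so the retained count
matches the schedule exactly. Each run's subset is scored by k-fold RMSECV
on the full sample and the subset with the global minimum wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pls import kfold_indices, pls1_fit, rmsecv, select_n_components
from .dataset import SpectralDataset
from .selection import SelectionResult


@dataclass
class ScarsConfig:
    n_runs: int = 500
    sample_ratio: float = 0.8
    max_pls_components: int = 10
    cv_folds: int = 10
    n_bootstrap: int = 20      # within-run refits for the stability index
    stability: bool = True     # False: classic CARS |coefficient| weights
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.sample_ratio < 1:
            raise ValueError("sample_ratio must be in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")


@dataclass
class ScarsTrace:
    """Per-run bookkeeping: retained counts, RMSECV path, coefficient record."""

    retained_counts: np.ndarray
    rmsecv_path: np.ndarray
    coef_paths: np.ndarray      # (n_runs, p); zero where a band was inactive
    best_run: int
    selected: np.ndarray
    failed_runs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run": np.arange(1, self.retained_counts.size + 1),
            "retained_count": self.retained_counts,
            "rmsecv": self.rmsecv_path,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def edf_ratio(run_index: int, n_runs: int, n_bands: int) -> float:
    """Exponentially decreasing retention ratio r_i = a * exp(-k * i).

    Boundary conditions pin a and k: all bands kept at run 1 (r_1 = 1) and
    two bands at run N (r_N = 2/p).
    """
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if not 1 <= run_index <= n_runs:
        raise ValueError(f"run_index {run_index} outside [1, {n_runs}]")
    k = math.log(n_bands / 2.0) / (n_runs - 1)
    a = math.exp(k)
    return a * math.exp(-k * run_index)


def _band_weights(X, y, retained, sample_idx, n_components, cfg, rng):
    """Weight per retained band from the run's calibration sample."""
    Xs = X[np.ix_(sample_idx, retained)]
    ys = y[sample_idx]
    if cfg.stability:
        coefs = np.empty((cfg.n_bootstrap, retained.size))
        for b in range(cfg.n_bootstrap):
            boot = rng.integers(0, len(sample_idx), size=len(sample_idx))
            coefs[b], _ = pls1_fit(Xs[boot], ys[boot], n_components)
        sd = coefs.std(axis=0, ddof=1)
        weights = np.abs(coefs.mean(axis=0)) / np.maximum(sd, 1e-12)
        mean_coef = coefs.mean(axis=0)
    else:
        mean_coef, _ = pls1_fit(Xs, ys, n_components)
        weights = np.abs(mean_coef)
    return weights, mean_coef


def _competitive_retain(retained, weights, target, rng):
    """Keep `target` bands: deterministic elite (top half of the schedule by
    weight, ties to the lower band index) plus weighted sampling without
    replacement for the remaining slots."""
    order = np.argsort(-weights, kind="stable")  # stable: ties -> lower index
    if target >= retained.size:
        return retained.copy()
    n_elite = max(1, target // 2)
    elite = order[:n_elite]
    rest = order[n_elite:]
    n_draw = target - n_elite
    if n_draw > 0:
        w = weights[rest] + 1e-12
        drawn = rng.choice(rest, size=n_draw, replace=False, p=w / w.sum())
        keep_local = np.concatenate([elite, drawn])
    else:
        keep_local = elite
    return np.sort(retained[keep_local])


def run_scars(ds: SpectralDataset, cfg: ScarsConfig):
    """Run the full sCARS schedule; returns (SelectionResult, ScarsTrace)."""
    X, y = ds.X, ds.y
    n, p = X.shape
    if n < cfg.cv_folds:
        raise ValueError(f"need at least cv_folds={cfg.cv_folds} samples")
    if p < 2:
        raise ValueError("need at least 2 bands")
    rng = np.random.default_rng(cfg.seed)
    eval_folds = kfold_indices(n, cfg.cv_folds, rng)
    n_sample = max(10, int(round(cfg.sample_ratio * n)))
    inner_folds = kfold_indices(n_sample, 5, rng)

    retained = np.arange(p)
    counts = np.zeros(cfg.n_runs, dtype=int)
    path = np.full(cfg.n_runs, np.nan)
    coef_paths = np.zeros((cfg.n_runs, p))
    subsets = []
    failed = []
    for i in range(1, cfg.n_runs + 1):
        # round-before-ceil guards float error at the r_N * p = 2 boundary
        target = int(np.ceil(round(edf_ratio(i, cfg.n_runs, p) * p, 9)))
        target = min(max(target, 2), retained.size)
        sample_idx = rng.choice(n, size=n_sample, replace=False)
        try:
            n_comp = select_n_components(
                X[np.ix_(sample_idx, retained)], y[sample_idx],
                min(cfg.max_pls_components, retained.size), inner_folds)
            weights, mean_coef = _band_weights(
                X, y, retained, sample_idx, n_comp, cfg, rng)
            if not np.all(np.isfinite(weights)) or weights.sum() == 0:
                raise FloatingPointError("degenerate weights")
        except (FloatingPointError, np.linalg.LinAlgError):
            failed.append(i - 1)
            counts[i - 1] = retained.size
            subsets.append(retained.copy())
            continue
        coef_paths[i - 1, retained] = mean_coef
        retained = _competitive_retain(retained, weights, target, rng)
        counts[i - 1] = retained.size
        subsets.append(retained.copy())
        path[i - 1] = rmsecv(
            X[:, retained], y,
            min(cfg.max_pls_components, retained.size), eval_folds)

    if np.all(np.isnan(path)):
        raise RuntimeError("every sCARS run failed; cannot select a subset")
    best = int(np.nanargmin(path))
    selected = subsets[best]
    trace = ScarsTrace(retained_counts=counts, rmsecv_path=path,
                       coef_paths=coef_paths, best_run=best,
                       selected=selected, failed_runs=failed)
    result = SelectionResult(
        method="scars", indices=selected, grid=ds.wavelengths,
        diagnostics={"rmsecv_path": path, "retained_counts": counts,
                     "best_run": best},
    )
    return result, trace
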