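"""Pipeline orchestration: simulate -> select -> evaluate -> invert.

A single YAML config drives composable stages; every artefact lands in a
run directory with a manifest (config hash, seed, stage outputs) so a run
is reproducible bit-for-bit for its deterministic stages. Also provides the
selection-overlap comparison across methods.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .calibration import calibrate
from .dataset import SpectralDataset
from .envi import write_envi
from .inversion import leaf_mask, predict_map, render_map, stats_frame
from .models import ModelSpec, cross_validate, fit
from .select_ca import select_by_correlation, spearman_correlogram
from .select_iriv import IrivConfig, run_iriv
from .select_scars import ScarsConfig, run_scars
from .selection import SelectionResult
from .synthetic import (SimConfig, elliptical_leaf_mask, generate_dataset,
                        generate_hypercube)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "select", "evaluate", "invert", "compare")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "runs"
    run_name: str = None
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    simulation: dict = field(default_factory=dict)
    selection: dict = field(default_factory=lambda: {"methods": ["ca"]})
    model: dict = field(default_factory=lambda: {"method": "xgboost"})
    cv: dict = field(default_factory=lambda: {"k": 10})
    inversion: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {ALL_STAGES}")
        for m in self.selection.get("methods", []):
            if m not in ("ca", "scars", "iriv"):
                raise ValueError(f"unknown selection method {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "run_name": self.run_name, "stages": list(self.stages),
            "simulation": dict(self.simulation),
            "selection": dict(self.selection), "model": dict(self.model),
            "cv": dict(self.cv), "inversion": dict(self.inversion),
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SelectionComparison:
    """Overlap report across selection methods on one wavelength grid."""

    methods: list
    counts: dict                 # method -> n selected
    fractions: dict              # method -> share of the full band set
    percents: dict               # method -> 100*fraction rounded to 2 dp
    pairwise: dict               # (m1, m2) -> sorted common wavelengths
    common: np.ndarray           # wavelengths selected by every method
    n_bands: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.methods,
            "n_selected": [self.counts[m] for m in self.methods],
            "fraction": [self.fractions[m] for m in self.methods],
            "percent": [self.percents[m] for m in self.methods],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_selections(results: list) -> SelectionComparison:
    """Counts, fractions, pairwise and global intersections by wavelength."""
    if len(results) < 2:
        raise ValueError("need at least two selections to compare")
    grid = results[0].grid
    for r in results[1:]:
        if r.grid.size != grid.size or not np.allclose(r.grid, grid):
            raise ValueError("selections are on different wavelength grids")
    methods = [r.method for r in results]
    sets = {r.method: set(r.indices.tolist()) for r in results}
    counts = {m: len(sets[m]) for m in methods}
    fractions = {m: counts[m] / grid.size for m in methods}
    percents = {m: round(100.0 * fractions[m], 2) for m in methods}
    pairwise = {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            idx = sorted(sets[m1] & sets[m2])
            pairwise[(m1, m2)] = grid[np.array(idx, int)] if idx else np.array([])
    common_idx = sorted(set.intersection(*sets.values()))
    common = grid[np.array(common_idx, int)] if common_idx else np.array([])
    return SelectionComparison(methods=methods, counts=counts,
                               fractions=fractions, percents=percents,
                               pairwise=pairwise, common=common,
                               n_bands=int(grid.size))


def plot_selection_comparison(cmp: SelectionComparison, results: list,
                              out_path) -> Path:
    """Strip plot of selected wavelengths per method, common bands marked."""
    fig, ax = plt.subplots(figsize=(8, 2 + 0.6 * len(results)))
    for i, r in enumerate(results):
        ax.scatter(r.wavelengths, np.full(r.n_selected, i), s=12,
                   label=f"{r.method} ({r.n_selected})")
    if cmp.common.size:
        for w in cmp.common:
            ax.axvline(w, color="steelblue", alpha=0.3, lw=1)
    ax.set_yticks(range(len(results)))
    ax.set_yticklabels([r.method for r in results])
    ax.set_xlabel("wavelength (nm)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _run_selection(method: str, ds: SpectralDataset, cfg: PipelineConfig):
    params = dict(cfg.selection.get(method, {}))
    if method == "ca":
        cg = spearman_correlogram(ds)
        return select_by_correlation(cg, **params)
    if method == "scars":
        sc = ScarsConfig(seed=cfg.seed, **params)
        return run_scars(ds, sc)[0]
    ic = IrivConfig(seed=cfg.seed, **params)
    return run_iriv(ds, ic)[0]


def _tiered_spad_field(shape, means, rng):
    """Three side-by-side leaf patches, one per tier, with a mild gradient."""
    rows, cols = shape
    field_vals = np.zeros(shape)
    third = cols // len(means)
    for t, m in enumerate(means):
        sl = slice(t * third, cols if t == len(means) - 1 else (t + 1) * third)
        grad = np.linspace(-2, 2, sl.stop - sl.start)
        field_vals[:, sl] = m + grad[None, :] + rng.normal(0, 0.5, (rows, sl.stop - sl.start))
    return field_vals


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    name = cfg.run_name or time.strftime("run_%Y%m%d_%H%M%S")
    run_dir = Path(cfg.output_dir) / name
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "version": __version__, "stages": {}}
    (run_dir / "config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    ds = None
    selections = {}
    try:
        for stage in cfg.stages:
            t0 = time.perf_counter()
            outputs = []
            if stage == "simulate":
                sim = SimConfig(seed=cfg.seed, **cfg.simulation)
                ds = generate_dataset(sim)
                path = run_dir / "dataset.csv"
                ds.to_csv(path)
                outputs.append(str(path))
            elif stage == "select":
                if ds is None:
                    ds = _load_dataset(cfg, run_dir)
                for method in cfg.selection.get("methods", ["ca"]):
                    sel = _run_selection(method, ds, cfg)
                    selections[method] = sel
                    path = run_dir / f"selection_{method}.csv"
                    sel.to_csv(path)
                    outputs.append(str(path))
            elif stage == "evaluate":
                if ds is None:
                    ds = _load_dataset(cfg, run_dir)
                use = cfg.selection.get("use") or next(iter(selections), None)
                bands = selections[use].indices if use in selections else None
                spec = ModelSpec(method=cfg.model.get("method", "xgboost"),
                                 hyperparams=cfg.model.get("hyperparams", {}),
                                 seed=cfg.seed)
                report = cross_validate(ds, bands, spec,
                                        k=cfg.cv.get("k", 10), seed=cfg.seed)
                report.to_csv(run_dir / "cv_report.csv")
                report.predictions.to_csv(run_dir / "cv_predictions.csv",
                                          index=False)
                manifest["cv"] = report.aggregate
                outputs += [str(run_dir / "cv_report.csv"),
                            str(run_dir / "cv_predictions.csv")]
            elif stage == "invert":
                if ds is None:
                    ds = _load_dataset(cfg, run_dir)
                outputs += _invert_stage(cfg, ds, selections, run_dir, manifest)
            elif stage == "compare":
                if len(selections) >= 2:
                    results = list(selections.values())
                    cmp = compare_selections(results)
                    cmp.to_csv(run_dir / "selection_comparison.csv")
                    plot_selection_comparison(
                        cmp, results, run_dir / "selection_comparison.png")
                    outputs += [str(run_dir / "selection_comparison.csv")]
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": outputs,
            }
            log.info("stage %s done in %.2fs", stage,
                     time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def _load_dataset(cfg: PipelineConfig, run_dir: Path) -> SpectralDataset:
    path = cfg.simulation.get("dataset_csv") or run_dir / "dataset.csv"
    if not Path(path).exists():
        raise FileNotFoundError(
            "no dataset available: run the simulate stage or point "
            "simulation.dataset_csv at a CSV")
    return SpectralDataset.from_csv(path)


def _invert_stage(cfg, ds, selections, run_dir, manifest):
    inv = cfg.inversion
    use = cfg.selection.get("use") or next(iter(selections), None)
    bands = selections[use].indices if use in selections else None
    spec = ModelSpec(method=cfg.model.get("method", "xgboost"),
                     hyperparams=cfg.model.get("hyperparams", {}),
                     seed=cfg.seed)
    model = fit(ds, spec, bands=bands)
    sim = SimConfig(seed=cfg.seed, **cfg.simulation)
    shape = tuple(inv.get("shape", (48, 48)))
    rng = np.random.default_rng(cfg.seed + 1)
    maps = {}
    outputs = []
    for tier, mean in zip(("lower", "middle", "upper"), sim.position_means):
        mask_true = elliptical_leaf_mask(*shape)
        spad_field = np.full(shape, mean) + rng.normal(0, 1.0, shape)
        raw, white, dark, truth = generate_hypercube(spad_field, mask_true, sim)
        cube = calibrate(raw, white, dark)
        write_envi(cube, run_dir / f"leaf_{tier}.img")
        smap = predict_map(cube, model)
        maps[tier] = smap
        render_map(smap, run_dir / f"leaf_{tier}.png",
                   vmin=inv.get("vmin", 0.0), vmax=inv.get("vmax", 80.0))
        outputs.append(str(run_dir / f"leaf_{tier}_color.png"))
    stats = stats_frame(maps)
    stats.to_csv(run_dir / "map_stats.csv", index=False)
    manifest["map_stats"] = stats.to_dict(orient="records")
    outputs.append(str(run_dir / "map_stats.csv"))
    return outputs
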