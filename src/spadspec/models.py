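"""Regression models and cross-validated evaluation.

Four model families map selected-band reflectance to SPAD: partial
least-squares regression (PLSR) and three tree ensembles (XGBoost, random
forest, gradient-boosted trees). Fitting is delegated to scikit-learn and
xgboost; this module owns band bookkeeping, the evaluation metrics, and
k-fold cross-validation.

Metric definitions
------------------
R² here is the *squared Pearson correlation* between measured and predicted
values — not the 1 - SSres/SStot form. The two differ for biased
predictors: a model can score a high correlation-R² while being
systematically offset. This choice follows the evaluation convention of the
emulated study and is therefore always in [0, 1]. RMSE and MAE are the
usual root-mean-square and mean-absolute errors. Cross-validated aggregates
(Rcv², RMSEcv, MAEcv) are unweighted means across folds; pooled
out-of-fold metrics are also computed and stored for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from xgboost import XGBRegressor

from ._pls import kfold_indices
from .dataset import SpectralDataset

METHODS = ("plsr", "xgboost", "rfr", "gbdt")

DEFAULT_ENSEMBLE_PARAMS = {"n_trees": 500, "depth": 3, "learning_rate": 0.1}


@dataclass
class ModelSpec:
    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        allowed = ({"n_components"} if self.method == "plsr"
                   else {"n_trees", "depth", "learning_rate"})
        bad = set(self.hyperparams) - allowed
        if bad:
            raise ValueError(f"unsupported hyperparams for {self.method}: {sorted(bad)}")


@dataclass
class FittedModel:
    """A fitted estimator plus the band subset it was trained on."""

    spec: ModelSpec
    estimator: object
    bands: np.ndarray
    wavelengths: np.ndarray

    def predict(self, X_sel: np.ndarray) -> np.ndarray:
        """Predict from a matrix whose columns are the model's bands."""
        X_sel = np.asarray(X_sel, float)
        if X_sel.ndim != 2 or X_sel.shape[1] != self.bands.size:
            raise ValueError(
                f"expected (n, {self.bands.size}) selected-band matrix, "
                f"got {X_sel.shape}")
        return np.asarray(self.estimator.predict(X_sel), float).ravel()

    def predict_full(self, X_full: np.ndarray) -> np.ndarray:
        """Predict from a full-grid matrix; selects the model's bands."""
        return self.predict(np.asarray(X_full, float)[:, self.bands])


@dataclass
class CVReport:
    k: int
    per_fold: pd.DataFrame          # columns fold, r2, rmse, mae, n_test
    aggregate: dict                 # mean-of-folds Rcv2 / RMSEcv / MAEcv
    pooled: dict                    # same metrics on pooled out-of-fold preds
    predictions: pd.DataFrame       # id, y, yhat, fold

    def __post_init__(self):
        rmse = self.per_fold["rmse"].to_numpy()
        mae = self.per_fold["mae"].to_numpy()
        if np.any(rmse < -1e-12) or np.any(mae < -1e-12):
            raise ValueError("negative error metric")
        if np.any(mae > rmse + 1e-9):
            raise ValueError("MAE exceeds RMSE in a fold")

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)


def metrics(y: np.ndarray, yhat: np.ndarray):
    """(R², RMSE, MAE): correlation-squared R², root-mean-square and mean
    absolute error. R² is NaN when either vector is constant."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("y and yhat must have equal nonzero length")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        r2 = float("nan")
    else:
        r = np.corrcoef(y, yhat)[0, 1]
        r2 = float(r**2)
    return r2, rmse, mae


def _pick_pls_components(X, y, cap: int, seed: int) -> int:
    """Inner 5-fold CV over component counts, smallest RMSECV wins."""
    n, p = X.shape
    cap = max(1, min(cap, p, n - 2))
    folds = kfold_indices(n, 5, np.random.default_rng(seed))
    best, best_c = np.inf, 1
    for c in range(1, cap + 1):
        sse = 0.0
        for tr, te in folds:
            m = PLSRegression(n_components=min(c, len(tr) - 1), scale=False)
            m.fit(X[tr], y[tr])
            r = y[te] - m.predict(X[te]).ravel()
            sse += r @ r
        if sse < best - 1e-12:
            best, best_c = sse, c
    return best_c


def _build_estimator(spec: ModelSpec, X, y):
    hp = spec.hyperparams
    if spec.method == "plsr":
        n_comp = hp.get("n_components")
        if n_comp is None:
            n_comp = _pick_pls_components(X, y, cap=10, seed=spec.seed)
        n_comp = max(1, min(n_comp, X.shape[1], X.shape[0] - 1))
        return PLSRegression(n_components=n_comp, scale=False)
    p = {**DEFAULT_ENSEMBLE_PARAMS, **hp}
    if spec.method == "xgboost":
        return XGBRegressor(
            n_estimators=p["n_trees"], max_depth=p["depth"],
            learning_rate=p["learning_rate"], random_state=spec.seed,
            n_jobs=1, verbosity=0, tree_method="hist")
    if spec.method == "rfr":
        return RandomForestRegressor(
            n_estimators=p["n_trees"], max_depth=None if p["depth"] == 0 else p["depth"],
            random_state=spec.seed, n_jobs=1)
    return GradientBoostingRegressor(
        n_estimators=p["n_trees"], max_depth=p["depth"],
        learning_rate=p["learning_rate"], random_state=spec.seed)


def fit(ds_train: SpectralDataset, spec: ModelSpec,
        bands=None) -> FittedModel:
    """Fit a model on the training dataset, optionally restricted to bands.

    ``bands`` are indices into the dataset's wavelength grid; None uses all
    bands. Deterministic under the spec's seed.
    """
    if bands is None:
        bands = np.arange(ds_train.n_bands)
    bands = np.sort(np.asarray(bands, int))
    if bands.size == 0:
        raise ValueError("selected band set is empty")
    X = ds_train.X[:, bands]
    y = ds_train.y
    if spec.method == "plsr" and X.shape[0] <= 1:
        raise ValueError("PLSR needs more than one training sample")
    est = _build_estimator(spec, X, y)
    est.fit(X, y)
    fitted = np.asarray(est.predict(X), float).ravel()
    if not np.all(np.isfinite(fitted)):
        raise RuntimeError(f"{spec.method} produced non-finite fitted values")
    return FittedModel(spec=spec, estimator=est, bands=bands,
                       wavelengths=ds_train.wavelengths[bands])


def _stratified_folds(labels, n, k, seed):
    """Seeded fold assignment, stratified by leaf-position label when the
    labels permit, so every fold sees every tier."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    fold_of = np.empty(n, dtype=int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            fold_of[i] = j % k
    # randomise which fold id gets the remainder samples
    remap = rng.permutation(k)
    fold_of = remap[fold_of]
    return [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
            for f in range(k)]


def cross_validate(ds: SpectralDataset, bands, spec: ModelSpec,
                   k: int = 10, seed: int = 0) -> CVReport:
    """k-fold cross-validation with per-fold and aggregate metrics.

    Folds are seeded and stratified by leaf position. Every fold must hold
    at least 2 samples (per-fold R² is meaningless otherwise), so k = n is
    rejected.
    """
    n = ds.n_samples
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    if n < 2 * k:
        raise ValueError(
            f"k={k} leaves folds with fewer than 2 samples at n={n}")
    folds = _stratified_folds(ds.position_labels, n, k, seed)
    rows = []
    oof = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    for f, (tr, te) in enumerate(folds):
        sub_train = SpectralDataset(
            X=ds.X[tr], y=ds.y[tr], wavelengths=ds.wavelengths,
            sample_ids=[ds.sample_ids[i] for i in tr],
            position_labels=[ds.position_labels[i] for i in tr])
        model = fit(sub_train, spec, bands=bands)
        yhat = model.predict_full(ds.X[te])
        oof[te] = yhat
        fold_id[te] = f
        r2, rmse, mae = metrics(ds.y[te], yhat)
        rows.append({"fold": f, "r2": r2, "rmse": rmse, "mae": mae,
                     "n_test": te.size})
    per_fold = pd.DataFrame(rows)
    agg = {
        "r2_cv": float(per_fold["r2"].mean()),
        "rmse_cv": float(per_fold["rmse"].mean()),
        "mae_cv": float(per_fold["mae"].mean()),
    }
    pr2, prmse, pmae = metrics(ds.y, oof)
    pooled = {"r2": pr2, "rmse": prmse, "mae": pmae}
    preds = pd.DataFrame({"id": ds.sample_ids, "y": ds.y, "yhat": oof,
                          "fold": fold_id})
    return CVReport(k=k, per_fold=per_fold, aggregate=agg, pooled=pooled,
                    predictions=preds)
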