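"""Iteratively retaining informative variables (IRIV).

Each round builds a random binary inclusion design: every row defines a
variable subset, fitted by PLS and scored by 5-fold RMSECV (vector RMSECV0).
Flipping variable i's column (include <-> exclude) in every row gives a
second score vector RMSECVi. The ratio RMSECV0/RMSECVi, split by whether
variable i was originally included (phi0, rows with A=1) or excluded (phii,
rows with A=0), yields

    DMEAN_i = mean(phi0) - mean(phii)

and a two-sided Mann-Whitney U p-value comparing the two ratio
distributions. Variables are classified:

    strongly informative   DMEAN < 0, p < 0.05
    weakly informative     DMEAN < 0, p > 0.05
    uninformative          DMEAN > 0, p > 0.05
    interfering            DMEAN > 0, p < 0.05

(the sign convention follows from the ratio orientation: removing an
informative variable inflates RMSECVi for rows that contained it, pushing
phi0 below 1). Rounds keep only strong + weak variables until nothing is
eliminated; a greedy backward elimination then prunes the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._pls import kfold_indices, rmsecv_masked
from .dataset import SpectralDataset
from .selection import SelectionResult

log = logging.getLogger(__name__)

CATEGORIES = ("strong", "weak", "uninformative", "interfering")


@dataclass
class IrivConfig:
    n_rows: int = 500
    inclusion_prob: float = 0.5
    cv_folds: int = 5
    max_pls_components: int = 5
    alpha: float = 0.05
    max_rounds: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10:
            raise ValueError("n_rows must be >= 10")
        if not 0 < self.inclusion_prob < 1:
            raise ValueError("inclusion_prob must be in (0, 1)")


@dataclass
class IrivRound:
    """One round's design, score vectors, and per-variable classification."""

    variables: np.ndarray      # global band indices active this round
    A: np.ndarray              # (n_rows, p_active) binary inclusion matrix
    rmsecv0: np.ndarray        # (n_rows,)
    rmsecvi: np.ndarray        # (n_rows, p_active), column i = flipped design
    dmean: np.ndarray          # (p_active,)
    pvalue: np.ndarray         # (p_active,)
    category: list             # per-variable, one of CATEGORIES

    @property
    def retained(self) -> np.ndarray:
        keep = [c in ("strong", "weak") for c in self.category]
        return self.variables[np.asarray(keep, bool)]


@dataclass
class IrivResult:
    rounds: list
    final_selected: np.ndarray
    backward_trace: list = field(default_factory=list)

    @property
    def retained_after_rounds(self) -> list:
        return [r.retained.size for r in self.rounds]

    def history_frame(self, wavelengths=None) -> pd.DataFrame:
        rows = []
        for k, rnd in enumerate(self.rounds, start=1):
            for j, v in enumerate(rnd.variables):
                rows.append({
                    "round": k,
                    "variable": int(v),
                    "wavelength_nm": (float(wavelengths[v])
                                      if wavelengths is not None else np.nan),
                    "dmean": rnd.dmean[j],
                    "pvalue": rnd.pvalue[j],
                    "category": rnd.category[j],
                })
        return pd.DataFrame(rows)


def classify(dmean: float, pvalue: float, alpha: float = 0.05) -> str:
    """Map (DMEAN, p) to a variable class.

    Boundary cases (DMEAN = 0 or p = alpha exactly) go to the weaker class
    on their side: weak for DMEAN < 0, uninformative otherwise.
    """
    if dmean < 0:
        return "strong" if pvalue < alpha else "weak"
    if dmean > 0:
        return "interfering" if pvalue < alpha else "uninformative"
    return "uninformative"


def build_inclusion_matrix(p_active: int, cfg: IrivConfig,
                           seed_offset: int = 0) -> np.ndarray:
    """n_rows x p_active Bernoulli(inclusion_prob) matrix; rows with fewer
    than two ones are redrawn."""
    if p_active < 2:
        raise ValueError("need at least 2 active variables")
    rng = np.random.default_rng((cfg.seed + seed_offset) % (2**31))
    A = (rng.random((cfg.n_rows, p_active)) < cfg.inclusion_prob).astype(np.int8)
    for _ in range(1000):
        bad = A.sum(axis=1) < 2
        if not bad.any():
            break
        A[bad] = (rng.random((int(bad.sum()), p_active))
                  < cfg.inclusion_prob).astype(np.int8)
    return A


def _round_scores(X, y, A, n_components, folds):
    """RMSECV0 for the design and RMSECVi for every column flip."""
    n_rows, p_active = A.shape
    rmsecv0 = rmsecv_masked(X, y, A, n_components, folds)
    rmsecvi = np.empty((n_rows, p_active))
    for i in range(p_active):
        B = A.copy()
        B[:, i] = 1 - B[:, i]
        rmsecvi[:, i] = rmsecv_masked(X, y, B, n_components, folds)
    return rmsecv0, rmsecvi


def iriv_round(X: np.ndarray, y: np.ndarray, variables: np.ndarray,
               cfg: IrivConfig, round_index: int = 0) -> IrivRound:
    """Score and classify every active variable from one inclusion design."""
    variables = np.asarray(variables, int)
    if variables.size < 3:
        raise ValueError(
            "iriv_round needs at least 3 variables (a 2-variable design "
            "with >= 2 inclusions per row cannot exclude anything)")
    n = X.shape[0]
    if n < cfg.cv_folds:
        raise ValueError("need n >= cv_folds samples")
    Xa = X[:, variables]
    p_active = variables.size
    for attempt in range(10):
        A = build_inclusion_matrix(p_active, cfg,
                                   seed_offset=1000 * round_index + attempt)
        col_ones = A.sum(axis=0)
        if np.all((col_ones > 0) & (col_ones < cfg.n_rows)):
            break
        log.warning("inclusion matrix column degenerate; redrawing (attempt %d)",
                    attempt + 1)
    else:
        raise RuntimeError("could not build a usable inclusion matrix")

    rng = np.random.default_rng((cfg.seed + 7919 * (round_index + 1)) % (2**31))
    folds = kfold_indices(n, cfg.cv_folds, rng)
    n_comp = max(1, min(cfg.max_pls_components, p_active - 1, n - 2))
    rmsecv0, rmsecvi = _round_scores(Xa, y, A, n_comp, folds)

    ratio = rmsecv0[:, None] / np.maximum(rmsecvi, 1e-12)
    dmean = np.empty(p_active)
    pvalue = np.empty(p_active)
    category = []
    for i in range(p_active):
        in_rows = A[:, i] == 1
        phi0 = ratio[in_rows, i]
        phii = ratio[~in_rows, i]
        dmean[i] = phi0.mean() - phii.mean()
        if np.ptp(ratio[:, i]) == 0:
            pvalue[i] = 1.0  # identical distributions; no evidence either way
        else:
            pvalue[i] = stats.mannwhitneyu(
                phi0, phii, alternative="two-sided", method="asymptotic"
            ).pvalue
        category.append(classify(dmean[i], pvalue[i], cfg.alpha))
    return IrivRound(variables=variables, A=A, rmsecv0=rmsecv0,
                     rmsecvi=rmsecvi, dmean=dmean, pvalue=pvalue,
                     category=category)


def backward_eliminate(X: np.ndarray, y: np.ndarray, variables: np.ndarray,
                       cfg: IrivConfig, trace: list = None,
                       folds: list = None) -> np.ndarray:
    """Greedy backward elimination of the retained variables.

    Repeatedly drop the variable whose removal gives the smallest
    leave-one-variable-out RMSECV theta_-i, as long as min(theta_-i) does not
    exceed the current all-variable RMSECV theta_t; ties break to the lower
    band index. ``trace`` (optional list) collects
    ``(variables, theta_t, theta_minus)`` tuples per step for auditing;
    ``folds`` overrides the seeded fold partition.
    """
    variables = np.sort(np.asarray(variables, int))
    n = X.shape[0]
    if folds is None:
        rng = np.random.default_rng((cfg.seed + 104729) % (2**31))
        folds = kfold_indices(n, cfg.cv_folds, rng)
    while variables.size > 1:
        t = variables.size
        Xa = X[:, variables]
        n_comp = max(1, min(cfg.max_pls_components, t - 1, n - 2))
        masks = np.ones((t + 1, t), dtype=np.int8)
        for i in range(t):
            masks[i + 1, i] = 0
        scores = rmsecv_masked(Xa, y, masks, n_comp, folds)
        theta_t = float(scores[0])
        theta_minus = scores[1:]
        if trace is not None:
            trace.append((variables.copy(), theta_t, theta_minus.copy()))
        i_best = int(np.argmin(theta_minus))  # argmin ties -> lower index
        if theta_minus[i_best] > theta_t:
            break
        variables = np.delete(variables, i_best)
    if trace is not None and variables.size == 1:
        trace.append((variables.copy(), np.nan, np.array([])))
    return variables


def run_iriv(ds: SpectralDataset, cfg: IrivConfig):
    """Full IRIV: iterate rounds keeping strong + weak variables, then apply
    backward elimination. Returns (SelectionResult, IrivResult)."""
    X, y = ds.X, ds.y
    variables = np.arange(ds.n_bands)
    rounds = []
    for k in range(cfg.max_rounds):
        rnd = iriv_round(X, y, variables, cfg, round_index=k)
        rounds.append(rnd)
        retained = rnd.retained
        if retained.size == 0:
            raise RuntimeError(
                f"IRIV eliminated every variable in round {k + 1}")
        # below 3 variables a design with >= 2 ones per row cannot vary a
        # column, so the iteration must hand over to backward elimination
        if retained.size == variables.size or retained.size < 3:
            variables = retained
            break
        variables = retained
    btrace = []
    final = backward_eliminate(X, y, variables, cfg, trace=btrace)
    result = IrivResult(rounds=rounds, final_selected=final,
                        backward_trace=btrace)
    sel = SelectionResult(
        method="iriv", indices=final, grid=ds.wavelengths,
        diagnostics={"retained_after_rounds": result.retained_after_rounds,
                     "n_rounds": len(rounds)},
    )
    return sel, result
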