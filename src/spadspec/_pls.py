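"""Lightweight PLS1 (univariate-response partial least squares) primitives.

The wavelength selectors evaluate tens of thousands of small PLS models per
call (every row of an inclusion design, every single-variable flip, every
Monte-Carlo run), so this module provides two lean entry points:

- :func:`pls1_fit` — single NIPALS fit, returns regression coefficients on
  the original scale; numerically equivalent to standard PLS1 (and, for a
  single response, to scikit-learn's ``PLSRegression(scale=False)``).
- :func:`pls1_coef_masked` — fits B models at once on B column subsets
  (binary masks) of the same matrix. It exploits two facts: (1) a masked
  column is constant zero after centring, so the subset fit equals the fit
  on the zero-padded matrix; (2) the PLS1 coefficient after c components is
  exactly the c-th conjugate-gradient iterate on the normal equations
  ``(XᵀX) beta = Xᵀy`` started at zero (the classical PLS1 / Lanczos / CG
  equivalence). The masked Gram matrix is a submatrix of one shared Gram
  matrix, so each CG step for all B subsets is a single BLAS matmul.

Model-facing PLSR (user API) lives in :mod:`spadspec.models` and delegates
to scikit-learn.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1. Returns ``(coef, intercept)`` with ``yhat = X @ coef + b``.

    Extraction stops early if the residual covariance vanishes (rank
    deficiency), so requesting more components than the rank is safe.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    a = 0
    for _ in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_load = Xc.T @ t / tt
        W[:, a] = w
        P[:, a] = p_load
        q[a] = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_load)
        a += 1
    if a == 0:
        return np.zeros(p), y_mean
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    coef = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return coef, y_mean - x_mean @ coef


def pls1_coef_masked(X: np.ndarray, y: np.ndarray, masks: np.ndarray,
                     n_components: int):
    """PLS1 coefficients for every column subset in ``masks`` at once.

    ``masks`` is (B, p) binary; row b restricts the fit to columns where
    ``masks[b] == 1``. Returns ``(coef, intercept)`` of shapes (B, p) and
    (B,), with zero coefficients on masked-out columns. Computed via B
    simultaneous conjugate-gradient recursions on the shared Gram matrix;
    batches whose residual vanishes early (rank deficiency) simply stop
    accumulating components.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    M = np.asarray(masks, float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    G = Xc.T @ Xc                      # shared Gram, p x p
    s = Xc.T @ yc                      # shared covariance, p
    r = M * s                          # (B, p) masked residuals
    d = r.copy()
    beta = np.zeros_like(r)
    rr = np.einsum("bp,bp->b", r, r)
    for _ in range(n_components):
        live = rr > _EPS
        if not live.any():
            break
        q = (d @ G) * M                # G_b d_b for every batch: one GEMM
        dq = np.einsum("bp,bp->b", d, q)
        live = live & (dq > _EPS)
        alpha = np.where(live, rr / np.maximum(dq, _EPS), 0.0)
        beta += alpha[:, None] * d
        r = r - alpha[:, None] * q
        rr_new = np.einsum("bp,bp->b", r, r)
        gamma = np.where(live, rr_new / np.maximum(rr, _EPS), 0.0)
        d = r + gamma[:, None] * d
        rr = rr_new
    intercept = y_mean - beta @ x_mean
    return beta, intercept


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list:
    """Random near-equal k-fold partition; returns list of (train, test)."""
    if k < 2 or k > n:
        raise ValueError(f"k={k} invalid for n={n}")
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((train, test))
    return out


def rmsecv(X: np.ndarray, y: np.ndarray, n_components: int, folds: list) -> float:
    """Cross-validated RMSE of a PLS1 model with fixed component count."""
    y = np.asarray(y, float)
    sse = 0.0
    for train, test in folds:
        coef, b0 = pls1_fit(X[train], y[train], n_components)
        resid = y[test] - (X[test] @ coef + b0)
        sse += resid @ resid
    return float(np.sqrt(sse / y.size))


def rmsecv_masked(X: np.ndarray, y: np.ndarray, masks: np.ndarray,
                  n_components: int, folds: list) -> np.ndarray:
    """RMSECV for every row of a binary column-inclusion design at once.

    ``masks`` is (B, p); each row defines a variable subset of X. Returns a
    length-B vector of k-fold RMSECV values, all subsets sharing the same
    folds.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    masks = np.asarray(masks, float)
    B = masks.shape[0]
    sse = np.zeros(B)
    for train, test in folds:
        coef, b0 = pls1_coef_masked(X[train], y[train], masks, n_components)
        pred = coef @ X[test].T + b0[:, None]     # (B, n_test)
        resid = y[test][None, :] - pred
        sse += np.einsum("bt,bt->b", resid, resid)
    return np.sqrt(sse / y.size)


def select_n_components(X: np.ndarray, y: np.ndarray, max_components: int,
                        folds: list) -> int:
    """Pick the PLS1 component count minimising RMSECV on the given folds."""
    n, p = X.shape
    cap = max(1, min(max_components, p, n - 2))
    best, best_c = np.inf, 1
    for c in range(1, cap + 1):
        r = rmsecv(X, y, c, folds)
        if r < best - _EPS:
            best, best_c = r, c
    return best_c
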