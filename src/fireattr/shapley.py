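"""Interventional Shapley values for small regression models.

Feature attributions follow the Shapley decomposition of a prediction
f(x) - E[f]: the value function of a coalition S is the expected prediction
when the features in S are fixed at x and the rest are drawn from a
background sample (the training rows here). For the small predictor counts
used in ecoregion-scale burned-area models the coalition sum is enumerated
exactly; larger models fall back to permutation sampling with a fixed seed.

Exactness gives the usual guarantees: per-row attributions sum to
f(x) - E_background[f], and symmetric features receive equal credit in
expectation.
"""
from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np

__all__ = ["shapley_values", "mean_abs_importance_pct"]


def _exact(predict, X, background, d):
    n = len(X)
    nb = len(background)
    masks = []
    for size in range(d + 1):
        masks.extend(combinations(range(d), size))
    mask_index = {m: i for i, m in enumerate(masks)}
    # v[i, k] = mean_b f(x_i with features in masks[k], background otherwise)
    big = np.empty((n * len(masks) * nb, d))
    row = 0
    for i in range(n):
        for m in masks:
            block = np.array(background, copy=True)
            if m:
                block[:, list(m)] = X[i, list(m)]
            big[row: row + nb] = block
            row += nb
    preds = np.asarray(predict(big), dtype=float)
    v = preds.reshape(n, len(masks), nb).mean(axis=2)

    phi = np.zeros((n, d))
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            w = factorial(size) * factorial(d - size - 1) / factorial(d)
            for m in combinations(others, size):
                k_without = mask_index[m]
                k_with = mask_index[tuple(sorted(m + (j,)))]
                phi[:, j] += w * (v[:, k_with] - v[:, k_without])
    return phi


def _sampled(predict, X, background, d, n_permutations, rng):
    n = len(X)
    nb = len(background)
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        for i in range(n):
            block = np.array(background, copy=True)
            prev = np.asarray(predict(block), dtype=float).mean()
            for j in perm:
                block[:, j] = X[i, j]
                cur = np.asarray(predict(block), dtype=float).mean()
                phi[i, j] += cur - prev
                prev = cur
    return phi / n_permutations


def shapley_values(predict, X, background=None, seed: int = 0,
                   exact_limit: int = 10, n_permutations: int = 64) -> np.ndarray:
    """Per-row, per-feature Shapley attributions of ``predict``.

    Parameters
    ----------
    predict : callable
        Maps an (m, d) array to m predictions.
    X : (n, d) array
        Rows to explain.
    background : (m, d) array, optional
        Reference sample for marginalizing absent features; defaults to X.
    seed : int
        Seed for the sampling fallback (ignored in exact mode).
    exact_limit : int
        Maximum feature count for exact enumeration (2^d coalitions).
    n_permutations : int
        Permutations per row in sampling mode.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    background = X if background is None else np.asarray(background, dtype=float)
    d = X.shape[1]
    if d == 0:
        return np.zeros((len(X), 0))
    if d <= exact_limit:
        return _exact(predict, X, background, d)
    return _sampled(predict, X, background, d, n_permutations, np.random.default_rng(seed))


def mean_abs_importance_pct(phi: np.ndarray, constant_mask=None) -> np.ndarray:
    """Mean |Shapley value| per feature, normalized to percentages summing to 100.

    Features flagged constant receive exactly 0%. If all importances vanish,
    percentages are all zero (degenerate constant model).
    """
    imp = np.abs(phi).mean(axis=0)
    if constant_mask is not None:
        imp = np.where(constant_mask, 0.0, imp)
    total = imp.sum()
    if total == 0:
        return np.zeros_like(imp)
    return 100.0 * imp / total
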