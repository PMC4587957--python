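"""Independent reference implementations used as test oracles.

Deliberately coded without the package's numerical machinery: plain
python loops for weighted means and Pearson correlation, and a
log-domain (scipy logsumexp) route for leave-one-out error curves.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp


def weighted_mean_oracle(values, weights) -> float:
    """Plain-loop weighted arithmetic mean."""
    num = 0.0
    den = 0.0
    for y, w in zip(values, weights):
        num += y * w
        den += w
    return num / den


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation, no numpy statistics."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def kernel_oracle(rho: float, bandwidth: float) -> float:
    return math.exp(-((1.0 - rho) ** 2) / (2.0 * bandwidth**2))


def loo_predictions_oracle(rho: np.ndarray, Y: np.ndarray, bandwidth: float) -> np.ndarray:
    """Leave-one-out kernel-weighted means across rows, in log domain.

    pred[t, j] averages Y[i, j] over observed i != t with Gaussian
    kernel weights; computed with scipy logsumexp (signed numerator),
    a route independent of the package's max-shift implementation.
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    E = -((1.0 - rho) ** 2) / (2.0 * bandwidth**2)
    pred = np.full((n, p), np.nan)
    for j in range(p):
        valid = np.flatnonzero(~np.isnan(Y[:, j]))
        for t in range(n):
            nb = valid[valid != t]
            if len(nb) == 0:
                continue
            e = E[t, nb]
            logden = logsumexp(e)
            lognum, sign = logsumexp(e, b=Y[nb, j], return_sign=True)
            pred[t, j] = sign * np.exp(lognum - logden)
    return pred


def layer_curve_oracle(rho: np.ndarray, Y: np.ndarray, grid) -> np.ndarray:
    """Summed squared leave-one-out error along a bandwidth grid.

    Rows of Y are the smoothed axis (pass Y.T and the drug-side rho for
    the drug layer).  Pairs without an observed neighbor are excluded
    at every grid value.
    """
    Y = np.asarray(Y, float)
    obs = ~np.isnan(Y)
    dense = bool(obs.all())
    costs = np.empty(len(grid))
    d2 = (1.0 - np.asarray(rho, float)) ** 2
    n, p = Y.shape
    n_other = obs.sum(axis=0, keepdims=True) - obs
    include = obs & (n_other >= 1)
    for k, b in enumerate(grid):
        if dense:
            E = -d2 / (2.0 * b * b)
            np.fill_diagonal(E, -np.inf)
            logden = logsumexp(E, axis=1)
            lognum, sign = logsumexp(
                E[None, :, :], b=Y.T[:, None, :], axis=2, return_sign=True
            )
            pred = (sign * np.exp(lognum - logden[None, :])).T
            err = np.where(include, Y - pred, 0.0)
        else:
            pred = loo_predictions_oracle(rho, Y, b)
            err = np.where(include, Y - pred, 0.0)
        costs[k] = float((err**2).sum())
    return costs


def lambda_grid_oracle(y, csn, dsn, step: float = 0.001) -> float:
    """Grid search for the convex layer-mixing weight."""
    best_lam, best_sse = 0.0, np.inf
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        pred = lam * np.asarray(dsn) + (1.0 - lam) * np.asarray(csn)
        sse = float(((np.asarray(y) - pred) ** 2).sum())
        if sse < best_sse:
            best_lam, best_sse = float(lam), sse
    return best_lam
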