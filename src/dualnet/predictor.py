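"""Kernel-weighted mean prediction from the two network layers.

The CSN layer predicts the response of cell line C to drug D as the
kernel-weighted mean of the responses of all *other* cell lines with an
observed response to D; the DSN layer symmetrically averages C's
observed responses to all other drugs.  The integrated prediction mixes
the two layers with a per-drug convex weight lambda:

    Sens_hat(D, C) = lambda_D * DSN(D, C) + (1 - lambda_D) * CSN(D, C)

The target pair itself never contributes to its own prediction, so the
same code path serves leave-one-out validation and true imputation.

Weighted means are computed after subtracting each target's maximum
neighbor exponent (logsumexp-style), which keeps the ratio exact even
at bandwidths where the raw kernel weights underflow to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedStudy
from .similarity import KernelWeights, build_similarity, kernel_weights

LAYERS = ("CSN", "DSN", "integrated")


@dataclass
class ModelParams:
    """Fitted model parameters: global bandwidths and per-drug mixing weights."""

    sigma: float  # CSN bandwidth
    tau: float  # DSN bandwidth
    lambda_by_drug: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        for d, lam in self.lambda_by_drug.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lambda for {d!r} outside [0, 1]: {lam}")

    def lam(self, drug: str) -> float:
        """Mixing weight for a drug; 0.5 when the drug was never fitted."""
        return self.lambda_by_drug.get(drug, 0.5)


@dataclass
class PredictionResult:
    """Predictions aligned to a response matrix.

    ``coverage`` is False where the required neighborhood was empty
    (no other observed cell for the drug / no other observed drug for
    the cell), in which case ``predicted`` holds NaN.
    """

    predicted: pd.DataFrame  # cells x drugs
    layer: str
    coverage: pd.DataFrame  # bool, same shape

    @property
    def cell_ids(self) -> pd.Index:
        return self.predicted.index

    @property
    def drug_ids(self) -> pd.Index:
        return self.predicted.columns


def _masked_exponents(kw: KernelWeights) -> np.ndarray:
    expo = kw.exponents.copy()
    np.fill_diagonal(expo, -np.inf)  # self-exclusion
    return expo


def _smooth_over_rows(E: np.ndarray, Y: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """pred[t, j] = sum_i w_ti Y_ij / sum_i w_ti over observed i (diag of E is -inf).

    E holds kernel exponents; each target row is shifted by its maximum
    valid exponent before exponentiating, an exact transformation of
    the ratio that avoids 0/0 underflow at small bandwidths.
    """
    n, p = Y.shape
    m = E.max(axis=1, keepdims=True)
    if not np.isfinite(m).all():  # an entity alone in the network
        m = np.where(np.isfinite(m), m, 0.0)
    W = np.exp(E - m)
    if obs.all():
        return (W @ Y) / W.sum(axis=1, keepdims=True)
    Yz = np.where(obs, Y, 0.0)
    O = obs.astype(float)
    den = W @ O
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(den > 0, (W @ Yz) / den, np.nan)
    # den can underflow to 0 when the target's closest entity overall is
    # unobserved for this column and far closer than its closest observed
    # one; recompute those entries with a shift over observed entities only
    n_other = obs.sum(axis=0, keepdims=True) - O
    retry = np.argwhere((den < 1e-250) & (n_other >= 1))
    for t, j in retry:
        valid = obs[:, j].copy()
        valid[t] = False
        e = E[t, valid]
        w = np.exp(e - e.max())
        pred[t, j] = w @ Y[valid, j] / w.sum()
    return pred


def csn_predictions(Y: np.ndarray, obs: np.ndarray, csn_weights: KernelWeights) -> np.ndarray:
    """CSN predictions for every (cell, drug) pair; NaN where uncovered."""
    return _smooth_over_rows(_masked_exponents(csn_weights), Y, obs)


def dsn_predictions(Y: np.ndarray, obs: np.ndarray, dsn_weights: KernelWeights) -> np.ndarray:
    """DSN predictions for every (cell, drug) pair; NaN where uncovered."""
    return _smooth_over_rows(_masked_exponents(dsn_weights), Y.T, obs.T).T


def _scalar_weighted_mean(expo_row: np.ndarray, y: np.ndarray, valid: np.ndarray) -> float:
    if not valid.any():
        return float("nan")
    e = expo_row[valid]
    m = e.max()
    if not np.isfinite(m):
        return float("nan")
    w = np.exp(e - m)
    return float(w @ y[valid] / w.sum())


def predict_csn(target_cell: str, drug: str, study: AlignedStudy, csn_weights: KernelWeights) -> float:
    """Response of ``target_cell`` to ``drug`` from similar cell lines.

    Returns NaN when no other cell line has an observed response to the
    drug (empty neighborhood).
    """
    rm = study.responses
    ci = rm.cell_ids.get_loc(target_cell)
    dj = rm.drug_ids.get_loc(drug)
    expo = _masked_exponents(csn_weights)[ci]
    y = rm.data.to_numpy(float)[:, dj]
    return _scalar_weighted_mean(expo, np.nan_to_num(y), ~np.isnan(y))


def predict_dsn(cell: str, target_drug: str, study: AlignedStudy, dsn_weights: KernelWeights) -> float:
    """Response of ``cell`` to ``target_drug`` from similar drugs.

    Returns NaN when the cell has no observed response to any other drug.
    """
    rm = study.responses
    ci = rm.cell_ids.get_loc(cell)
    dj = rm.drug_ids.get_loc(target_drug)
    expo = _masked_exponents(dsn_weights)[dj]
    y = rm.data.to_numpy(float)[ci, :]
    return _scalar_weighted_mean(expo, np.nan_to_num(y), ~np.isnan(y))


def combine_layers(csn: float, dsn: float, lam: float) -> float:
    """Convex combination of the two layer predictions with fallback.

    When exactly one layer is computable its prediction is returned
    alone; when neither is, NaN.
    """
    csn_ok, dsn_ok = not np.isnan(csn), not np.isnan(dsn)
    if csn_ok and dsn_ok:
        return lam * dsn + (1.0 - lam) * csn
    if dsn_ok:
        return dsn
    if csn_ok:
        return csn
    return float("nan")


def predict_integrated(
    cell: str,
    drug: str,
    study: AlignedStudy,
    params: ModelParams,
    csn_weights: KernelWeights,
    dsn_weights: KernelWeights,
) -> float:
    """Dual-layer prediction for one (cell, drug) pair."""
    return combine_layers(
        predict_csn(cell, drug, study, csn_weights),
        predict_dsn(cell, drug, study, dsn_weights),
        params.lam(drug),
    )


def study_kernels(study: AlignedStudy, params: ModelParams) -> tuple[KernelWeights, KernelWeights]:
    """CSN and DSN kernel weights for a study at the given bandwidths."""
    csn = kernel_weights(build_similarity(study.expression), params.sigma, "CSN")
    dsn = kernel_weights(build_similarity(study.descriptors, standardize=True), params.tau, "DSN")
    return csn, dsn


def predict_matrix(
    study: AlignedStudy,
    params: ModelParams,
    targets: set[tuple[str, str]] | None = None,
    layer: str = "integrated",
    kernels: tuple[KernelWeights, KernelWeights] | None = None,
) -> PredictionResult:
    """Predictions for a set of (cell, drug) targets (default: all pairs).

    The target pair's own observation never contributes to its
    prediction, so predictions at observed targets are leave-one-out
    values.  Results are on the same response scale as ``study.responses``.
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    rm = study.responses
    Y = np.nan_to_num(rm.data.to_numpy(float))
    obs = rm.observed_mask.to_numpy()
    if kernels is None:
        kernels = study_kernels(study, params)
    csn_kw, dsn_kw = kernels

    if layer in ("CSN", "integrated"):
        csn = csn_predictions(Y, obs, csn_kw)
    if layer in ("DSN", "integrated"):
        dsn = dsn_predictions(Y, obs, dsn_kw)
    if layer == "CSN":
        pred = csn
    elif layer == "DSN":
        pred = dsn
    else:
        lam = np.array([params.lam(d) for d in rm.drug_ids])
        pred = lam * dsn + (1.0 - lam) * csn
        only_csn = np.isnan(dsn) & ~np.isnan(csn)
        only_dsn = np.isnan(csn) & ~np.isnan(dsn)
        pred[only_csn] = csn[only_csn]
        pred[only_dsn] = dsn[only_dsn]

    pred_df = pd.DataFrame(pred, index=rm.cell_ids, columns=rm.drug_ids)
    if targets is not None:
        keep = pd.DataFrame(False, index=rm.cell_ids, columns=rm.drug_ids)
        for c, d in targets:
            keep.loc[c, d] = True
        pred_df = pred_df.where(keep)
    coverage = pred_df.notna()
    return PredictionResult(predicted=pred_df, layer=layer, coverage=coverage)
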