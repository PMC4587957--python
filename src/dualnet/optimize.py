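"""Leave-one-out fitting of the model parameters sigma, tau and lambda.

The three parameters are fitted in a fixed order so that each layer is
a complete predictor on its own:

1. sigma — CSN bandwidth, grid search over (0, 1] at step 0.001,
   minimizing the summed squared leave-one-out CSN error over all
   observed (drug, cell) pairs.
2. tau — DSN bandwidth, grid search over (0, 1] at step 0.01 with the
   DSN error.
3. lambda — per drug, the convex mixing weight minimizing the summed
   squared error of the combined prediction over that drug's held-out
   pairs; a 1-D quadratic solved in closed form and clipped to [0, 1].

Ties on the grid break toward the smallest bandwidth (the more local
model).  Pairs without any observed neighbor are excluded from the
objective at every grid value, so sums are comparable across the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedStudy, StudyInputError
from .predictor import ModelParams, _smooth_over_rows
from .similarity import build_similarity


@dataclass
class GridSpec:
    """Bandwidth search grids; values strictly positive (the kernel is
    undefined at bandwidth 0)."""

    sigma_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 1001) * 0.001, 3)
    )
    tau_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 101) * 0.01, 2)
    )

    def __post_init__(self) -> None:
        for name, g in (("sigma_grid", self.sigma_grid), ("tau_grid", self.tau_grid)):
            g = np.asarray(g, float)
            if len(g) == 0 or (g <= 0).any() or (np.diff(g) <= 0).any():
                raise ValueError(f"{name} must be strictly increasing and positive")

    @classmethod
    def with_steps(cls, sigma_step: float = 0.001, tau_step: float = 0.01) -> "GridSpec":
        return cls(
            sigma_grid=np.round(np.arange(sigma_step, 1.0 + sigma_step / 2, sigma_step), 9),
            tau_grid=np.round(np.arange(tau_step, 1.0 + tau_step / 2, tau_step), 9),
        )


@dataclass
class FitReport:
    """Fitted parameters with their leave-one-out error curves."""

    params: ModelParams
    sigma_curve: pd.Series  # sigma -> J(sigma)
    tau_curve: pd.Series  # tau -> J(tau)
    lambda_table: pd.DataFrame  # per drug: lambda, n_pairs, sse at 0 / fitted / 1
    j_sigma: float
    j_tau: float

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"sigma\t{self.params.sigma}\n")
            fh.write(f"tau\t{self.params.tau}\n")
            fh.write(f"j_sigma\t{self.j_sigma}\nj_tau\t{self.j_tau}\n\n")
            fh.write("[lambda]\n")
            self.lambda_table.to_csv(fh, sep="\t")
            fh.write("\n[sigma_curve]\n")
            self.sigma_curve.to_csv(fh, sep="\t", header=["J"])
            fh.write("\n[tau_curve]\n")
            self.tau_curve.to_csv(fh, sep="\t", header=["J"])


def _layer_curve(
    d2: np.ndarray, Y: np.ndarray, obs: np.ndarray, grid: np.ndarray, transpose: bool
) -> pd.Series:
    """Summed squared LOOCV error along a bandwidth grid for one layer.

    ``d2`` is the matrix of (1 - rho)^2 over the layer's entities.
    ``transpose=True`` evaluates the drug layer (smoothing across
    columns of Y).
    """
    if transpose:
        Y, obs = Y.T, obs.T
    Yz = np.nan_to_num(Y)
    # pairs with an observed neighbor (independent of bandwidth): the
    # drug/cell must have >=1 other observed entity
    n_other = obs.sum(axis=0, keepdims=True) - obs
    include = obs & (n_other >= 1)
    if include.sum() < 2:
        raise StudyInputError("fewer than 2 computable pairs for bandwidth fitting")
    cost = np.empty(len(grid))
    for k, b in enumerate(grid):
        E = -d2 / (2.0 * b * b)
        np.fill_diagonal(E, -np.inf)
        pred = _smooth_over_rows(E, Yz, obs)
        err = np.where(include, Y - pred, 0.0)
        cost[k] = float(np.einsum("ij,ij->", err, err))
    return pd.Series(cost, index=np.asarray(grid, float))


def _argmin_series(curve: pd.Series) -> float:
    # first index at the minimum == smallest bandwidth (grid increasing)
    return float(curve.index[int(np.argmin(curve.to_numpy()))])


def _squared_dissimilarity(study: AlignedStudy, axis: str) -> np.ndarray:
    if axis == "cells":
        rho = build_similarity(study.expression).rho
        ids = study.responses.cell_ids
    else:
        rho = build_similarity(study.descriptors, standardize=True).rho
        ids = study.responses.drug_ids
    rho = rho.loc[ids, ids].to_numpy(float)
    return (1.0 - rho) ** 2


def fit_sigma(study: AlignedStudy, grid: GridSpec | None = None) -> tuple[float, pd.Series]:
    """Grid-search the CSN bandwidth by summed squared LOOCV error."""
    grid = grid or GridSpec()
    Y = study.responses.data.to_numpy(float)
    obs = study.responses.observed_mask.to_numpy()
    curve = _layer_curve(_squared_dissimilarity(study, "cells"), Y, obs, grid.sigma_grid, False)
    return _argmin_series(curve), curve


def fit_tau(study: AlignedStudy, grid: GridSpec | None = None) -> tuple[float, pd.Series]:
    """Grid-search the DSN bandwidth by summed squared LOOCV error."""
    grid = grid or GridSpec()
    Y = study.responses.data.to_numpy(float)
    obs = study.responses.observed_mask.to_numpy()
    curve = _layer_curve(_squared_dissimilarity(study, "drugs"), Y, obs, grid.tau_grid, True)
    return _argmin_series(curve), curve


def _loocv_layer_predictions(
    study: AlignedStudy, sigma: float, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    Y = study.responses.data.to_numpy(float)
    obs = study.responses.observed_mask.to_numpy()
    Yz = np.nan_to_num(Y)
    Ec = -_squared_dissimilarity(study, "cells") / (2.0 * sigma * sigma)
    np.fill_diagonal(Ec, -np.inf)
    Ed = -_squared_dissimilarity(study, "drugs") / (2.0 * tau * tau)
    np.fill_diagonal(Ed, -np.inf)
    csn = _smooth_over_rows(Ec, Yz, obs)
    dsn = _smooth_over_rows(Ed, Yz.T, obs.T).T
    return csn, dsn


def fit_lambda(study: AlignedStudy, sigma: float, tau: float) -> pd.DataFrame:
    """Per-drug convex mixing weight by closed-form least squares.

    Over the drug's held-out pairs where both layers are computable,
    with r = Sens - CSN and d = DSN - CSN, the summed squared error of
    the combination is quadratic in lambda and minimized at
    lambda = sum(r d) / sum(d^2), clipped into [0, 1].  Drugs with no
    valid pair, or with identical layer predictions everywhere (flat
    objective), get lambda = 0.5 by convention with a warning.
    """
    rm = study.responses
    Y = rm.data.to_numpy(float)
    obs = rm.observed_mask.to_numpy()
    csn, dsn = _loocv_layer_predictions(study, sigma, tau)
    rows = []
    flat: list[str] = []
    for j, drug in enumerate(rm.drug_ids):
        valid = obs[:, j] & ~np.isnan(csn[:, j]) & ~np.isnan(dsn[:, j])
        r = Y[valid, j] - csn[valid, j]
        d = dsn[valid, j] - csn[valid, j]
        denom = float(d @ d)
        # flat objective when the layers agree to floating precision
        scale = float(np.abs(np.concatenate([csn[valid, j], dsn[valid, j]])).max()) if valid.any() else 0.0
        if valid.sum() == 0 or denom <= (1e-12 * max(1.0, scale)) ** 2 * max(1, valid.sum()):
            lam = 0.5
            flat.append(str(drug))
        else:
            lam = float(np.clip((r @ d) / denom, 0.0, 1.0))
        resid = r - lam * d
        rows.append(
            {
                "drug": drug,
                "lambda": lam,
                "n_pairs": int(valid.sum()),
                "sse_csn": float(r @ r),
                "sse_dsn": float((r - d) @ (r - d)),
                "sse_integrated": float(resid @ resid),
            }
        )
    if flat:
        warnings.warn(
            f"lambda defaulted to 0.5 for {len(flat)} drug(s) with no usable "
            f"pairs or identical layer predictions: {flat}",
            stacklevel=2,
        )
    return pd.DataFrame(rows).set_index("drug")


def fit_all(study: AlignedStudy, grid: GridSpec | None = None) -> FitReport:
    """Fit sigma, then tau, then per-drug lambda; fully deterministic."""
    grid = grid or GridSpec()
    sigma, sigma_curve = fit_sigma(study, grid)
    tau, tau_curve = fit_tau(study, grid)
    table = fit_lambda(study, sigma, tau)
    params = ModelParams(
        sigma=sigma, tau=tau, lambda_by_drug={str(d): float(v) for d, v in table["lambda"].items()}
    )
    return FitReport(
        params=params,
        sigma_curve=sigma_curve,
        tau_curve=tau_curve,
        lambda_table=table,
        j_sigma=float(sigma_curve.min()),
        j_tau=float(tau_curve.min()),
    )
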