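"""Filling missing response entries with dual-layer predictions.

Large screens are incomplete (in the motivating application only 76%
of the cell line x drug grid had measured responses).  Each missing
entry is predicted once from the observed entries with the integrated
model (single-layer fallback when only one neighborhood is non-empty);
imputed values are never recycled as training data, so imputation is a
single pass and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlignedStudy, ResponseMatrix, denormalize_responses
from .predictor import ModelParams, predict_matrix


@dataclass
class ImputedMatrix:
    """Response matrix with computable missing entries filled.

    ``provenance`` marks each entry ``observed``, ``imputed`` or
    ``uncomputable``.  Values are on the original (unnormalized)
    response scale when the study carried a normalization record.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame  # str entries

    @property
    def n_imputed(self) -> int:
        return int((self.provenance == "imputed").to_numpy().sum())

    @property
    def n_uncomputable(self) -> int:
        return int((self.provenance == "uncomputable").to_numpy().sum())

    def write(self, values_path, provenance_path, sep: str = "\t") -> None:
        self.values.to_csv(values_path, sep=sep, na_rep="NA")
        self.provenance.to_csv(provenance_path, sep=sep)


def impute_missing(study: AlignedStudy, params: ModelParams) -> ImputedMatrix:
    """Predict every missing (cell, drug) entry from the observed ones.

    Observed entries are copied through unchanged; entries where
    neither layer has an observed neighbor stay missing and are
    flagged ``uncomputable``.
    """
    rm = study.responses
    obs = rm.observed_mask
    missing = [
        (c, d) for c in rm.cell_ids for d in rm.drug_ids if not obs.loc[c, d]
    ]
    values = rm.data.copy()
    provenance = pd.DataFrame(
        np.where(obs, "observed", "uncomputable"), index=rm.cell_ids, columns=rm.drug_ids
    )
    if missing:
        pred = predict_matrix(study, params, targets=set(missing), layer="integrated")
        filled = pred.predicted.notna()
        values = values.where(obs | ~filled, pred.predicted)
        provenance = provenance.where(~(filled & ~obs), "imputed")
    out = ResponseMatrix(values, norm_record=rm.norm_record)
    if rm.is_normalized:
        out = denormalize_responses(out)
    return ImputedMatrix(values=out.data, provenance=provenance)


@dataclass
class CoverageReport:
    fraction_observed: float
    per_drug: pd.Series  # observed count per drug
    per_cell: pd.Series  # observed count per cell line


def coverage_report(rm: ResponseMatrix) -> CoverageReport:
    """Fraction of the cell x drug grid with an observed response."""
    obs = rm.observed_mask
    total = obs.size
    return CoverageReport(
        fraction_observed=float(obs.to_numpy().sum() / total) if total else float("nan"),
        per_drug=obs.sum(axis=0),
        per_cell=obs.sum(axis=1),
    )
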