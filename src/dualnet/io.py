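"""Reading, writing, aligning and normalizing the three study matrices.

A study consists of a gene-expression matrix over cell lines, a chemical
descriptor matrix over drugs, and a partially observed response matrix
(cell lines x drugs, activity area or IC50).  All three arrive as
delimited text with one header row and one identifier column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Cell values treated as missing in delimited input (case-insensitive).
MISSING_SENTINELS = frozenset({"", "na", "nan", "null"})


class StudyInputError(ValueError):
    """Raised when an input matrix violates a structural precondition."""


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=[s for s in MISSING_SENTINELS if s] + ["NA", "NaN", "NULL", "Na"],
        keep_default_na=False,
        encoding="utf-8",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()]))
        raise StudyInputError(f"duplicate {what}: {dups}")


def _coerce_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise StudyInputError(
            f"non-numeric value {df.iat[r, c]!r} in {what} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out.astype(float)


@dataclass
class FeatureMatrix:
    """Numeric entities x features table (expression of cell lines, or
    descriptors of drugs).

    ``excluded_features`` lists features that are constant across
    entities or contain a non-finite value; they are kept in ``data``
    for round-tripping but skipped when correlations are computed.
    """

    data: pd.DataFrame  # entities x features
    excluded_features: pd.Index = field(default_factory=lambda: pd.Index([]))

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "entity identifiers")
        _check_unique(self.data.columns, "feature identifiers")
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            raise StudyInputError(
                f"entities with no feature values: {list(self.data.index[all_missing])}"
            )

    @property
    def entity_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def usable(self) -> pd.DataFrame:
        """Feature columns that participate in correlation computation."""
        return self.data.drop(columns=self.excluded_features)


def _flag_features(data: pd.DataFrame) -> pd.Index:
    vals = data.to_numpy(float)
    nonfinite = ~np.isfinite(vals).all(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-nan columns
        constant = np.nanstd(vals, axis=0) == 0
    return data.columns[nonfinite | constant]


def read_feature_matrix(path, orientation: str = "entities", sep: str | None = None) -> FeatureMatrix:
    """Load a feature matrix from delimited text.

    Parameters
    ----------
    orientation : ``"entities"`` if rows are entities (cell lines /
        drugs), ``"features"`` if rows are features (genes /
        descriptors); the result is always entities x features.
    """
    if orientation not in ("entities", "features"):
        raise ValueError("orientation must be 'entities' or 'features'")
    df = _read_table(path, sep)
    _check_unique(df.index, "row identifiers")
    _check_unique(df.columns, "column identifiers")
    df = _coerce_numeric(df, "feature matrix")
    if orientation == "features":
        df = df.T
    return FeatureMatrix(df, excluded_features=_flag_features(df))


def write_feature_matrix(fm: FeatureMatrix, path, sep: str = "\t") -> None:
    fm.data.to_csv(path, sep=sep)


@dataclass
class ResponseMatrix:
    """Cell lines x drugs response values with explicit missingness.

    Missing entries are NaN in ``data``.  ``norm_record`` is present
    after per-drug normalization and maps each drug to the (min, max)
    of its observed raw values, so predictions can be reported back on
    the original measurement scale.
    """

    data: pd.DataFrame  # cells x drugs, NaN = missing
    norm_record: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "cell identifiers")
        _check_unique(self.data.columns, "drug identifiers")

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.index

    @property
    def drug_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def observed_mask(self) -> pd.DataFrame:
        return self.data.notna()

    @property
    def is_normalized(self) -> bool:
        return self.norm_record is not None


def _drop_sparse_drugs(df: pd.DataFrame, min_observed: int = 2) -> pd.DataFrame:
    counts = df.notna().sum(axis=0)
    thin = counts[counts < min_observed].index
    if len(thin):
        warnings.warn(
            f"dropping {len(thin)} drug(s) with <{min_observed} observed "
            f"responses: {list(thin)}",
            stacklevel=3,
        )
        df = df.drop(columns=thin)
    return df


def read_response_matrix(path, sep: str | None = None) -> ResponseMatrix:
    """Load a cells x drugs response matrix; blank/NA cells are missing."""
    df = _read_table(path, sep)
    _check_unique(df.index, "cell identifiers")
    _check_unique(df.columns, "drug identifiers")
    df = _coerce_numeric(df, "response matrix")
    if not df.notna().to_numpy().any():
        raise StudyInputError("response matrix contains no observed value")
    df = _drop_sparse_drugs(df)
    return ResponseMatrix(df)


def write_response_matrix(rm: ResponseMatrix, path, sep: str = "\t") -> None:
    rm.data.to_csv(path, sep=sep, na_rep="NA")


def normalize_responses(rm: ResponseMatrix) -> ResponseMatrix:
    """Per-drug min-max scaling of observed responses onto [0, 1].

    Different drugs have very different baseline values and ranges;
    mapping each drug's observed values by (x - min) / (max - min)
    gives every drug the same baseline (0) and range (1) so that the
    two network layers mix commensurable quantities.  The (min, max)
    pair per drug is recorded for the inverse transform.  Drugs whose
    observed values have zero range are dropped with a warning.
    """
    if rm.is_normalized:
        raise ValueError("response matrix is already normalized")
    lo = rm.data.min(axis=0)
    hi = rm.data.max(axis=0)
    degenerate = rm.data.columns[(hi - lo) == 0]
    if len(degenerate):
        warnings.warn(
            f"dropping {len(degenerate)} drug(s) with zero observed range: "
            f"{list(degenerate)}",
            stacklevel=2,
        )
    keep = rm.data.columns.difference(degenerate, sort=False)
    data = (rm.data[keep] - lo[keep]) / (hi[keep] - lo[keep])
    record = {d: (float(lo[d]), float(hi[d])) for d in keep}
    return ResponseMatrix(data, norm_record=record)


def denormalize_responses(rm: ResponseMatrix) -> ResponseMatrix:
    """Invert :func:`normalize_responses` using the stored per-drug record."""
    if not rm.is_normalized:
        raise ValueError("response matrix carries no normalization record")
    data = rm.data.copy()
    for drug, (lo, hi) in rm.norm_record.items():
        data[drug] = data[drug] * (hi - lo) + lo
    return ResponseMatrix(data)


@dataclass
class AlignedStudy:
    """Expression, descriptors and responses restricted to shared identifiers.

    Invariant: ``responses.cell_ids`` is a subset of the expression
    entities and ``responses.drug_ids`` a subset of the descriptor
    entities, so every response row/column has a similarity-network
    counterpart.
    """

    expression: FeatureMatrix  # over cell lines
    descriptors: FeatureMatrix  # over drugs
    responses: ResponseMatrix

    def __post_init__(self) -> None:
        if not self.responses.cell_ids.isin(self.expression.entity_ids).all():
            raise StudyInputError("response cells missing from expression matrix")
        if not self.responses.drug_ids.isin(self.descriptors.entity_ids).all():
            raise StudyInputError("response drugs missing from descriptor matrix")
        if len(self.responses.cell_ids) == 0 or len(self.responses.drug_ids) == 0:
            raise StudyInputError("empty identifier intersection")

    def with_responses(self, rm: ResponseMatrix) -> "AlignedStudy":
        return replace(self, responses=rm)


def align_study(
    expression: FeatureMatrix,
    descriptors: FeatureMatrix,
    responses: ResponseMatrix,
) -> AlignedStudy:
    """Restrict all three matrices to the common cell-line and drug sets.

    Identifier order follows sorted intersection so that the result is
    invariant to input row/column ordering.  Counts of dropped
    identifiers are reported via warnings.
    """
    cells = responses.cell_ids.intersection(expression.entity_ids).sort_values()
    drugs = responses.drug_ids.intersection(descriptors.entity_ids).sort_values()
    if len(cells) == 0:
        raise StudyInputError("no cell line shared between expression and responses")
    if len(drugs) == 0:
        raise StudyInputError("no drug shared between descriptors and responses")
    n_cell_drop = len(responses.cell_ids) - len(cells)
    n_drug_drop = len(responses.drug_ids) - len(drugs)
    if n_cell_drop or n_drug_drop:
        warnings.warn(
            f"alignment dropped {n_cell_drop} cell line(s) and "
            f"{n_drug_drop} drug(s) without feature data",
            stacklevel=2,
        )
    data = responses.data.loc[cells, drugs]
    data = _drop_sparse_drugs(data)
    record = None
    if responses.is_normalized:
        record = {d: responses.norm_record[d] for d in data.columns}
    expr = expression.data.loc[cells].sort_index(axis=1)
    desc = descriptors.data.loc[drugs].sort_index(axis=1)
    # re-flag: features can become constant on the restricted entity set
    return AlignedStudy(
        expression=FeatureMatrix(
            expr, excluded_features=expression.excluded_features.union(_flag_features(expr))
        ),
        descriptors=FeatureMatrix(
            desc, excluded_features=descriptors.excluded_features.union(_flag_features(desc))
        ),
        responses=ResponseMatrix(data, norm_record=record),
    )


def normalize_study(study: AlignedStudy) -> AlignedStudy:
    """Return the study with per-drug min-max normalized responses."""
    return study.with_responses(normalize_responses(study.responses))
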