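"""Scoring, permutation null, similarity stratification and group tests.

Per-drug accuracy is reported as Pearson r, RMSE and NRMSE (RMSE
divided by the drug's observed response range).  The shuffle control
permutes each drug's observed responses across cell lines and repeats
the leave-one-out predictions with unchanged parameters; any remaining
correlation measures optimism of the cross-validation itself.  The
stratification check bins entity pairs by similarity and compares
their response-vector correlations between bins, the model's core
assumption that similar cell lines (drugs) respond similarly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlignedStudy, ResponseMatrix
from .predictor import ModelParams, PredictionResult, predict_matrix
from .similarity import SimilarityNetwork

#: |r| below this counts as "no signal" in the shuffle-null summary.
NULL_R_THRESHOLD = 0.08


@dataclass
class DrugEvaluation:
    """Per-drug agreement between observed and predicted responses."""

    drug_id: str
    n_pairs: int
    pearson_r: float  # NaN when n_pairs < 3 or a vector is constant
    rmse: float
    nrmse: float  # NaN when the observed range is zero
    note: str = ""


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's t-test; two zero-variance groups with equal means give t=0."""
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    return t, p


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def evaluate_predictions(
    observed: ResponseMatrix, predicted: PredictionResult
) -> list[DrugEvaluation]:
    """Score predictions per drug over pairs both observed and covered."""
    out = []
    for drug in observed.drug_ids:
        if drug not in predicted.drug_ids:
            continue
        y = observed.data[drug]
        p = predicted.predicted[drug].reindex(y.index)
        valid = y.notna() & p.notna()
        yv, pv = y[valid].to_numpy(), p[valid].to_numpy()
        n = int(valid.sum())
        if n == 0:
            out.append(DrugEvaluation(str(drug), 0, np.nan, np.nan, np.nan, "no covered pairs"))
            continue
        rmse = float(np.sqrt(np.mean((yv - pv) ** 2)))
        rng = float(yv.max() - yv.min())
        nrmse = rmse / rng if rng > 0 else float("nan")
        r = _pearson(yv, pv)
        note = ""
        if n < 3:
            note = "fewer than 3 pairs; correlation not reported"
        elif np.isnan(r):
            note = "constant vector; correlation undefined"
        elif rng == 0:
            note = "zero observed range; NRMSE undefined"
        out.append(DrugEvaluation(str(drug), n, r, rmse, nrmse, note))
    return out


def evaluation_table(evals: list[DrugEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in evals]).set_index("drug_id")


def loocv_correlations(study: AlignedStudy, params: ModelParams, layer: str = "integrated") -> pd.Series:
    """Per-drug Pearson r between observed responses and their
    leave-one-out predictions at fixed parameters."""
    pred = predict_matrix(study, params, layer=layer)
    evals = evaluate_predictions(study.responses, pred)
    return pd.Series({e.drug_id: e.pearson_r for e in evals}, name="pearson_r")


def shuffle_responses(rm: ResponseMatrix, rng: np.random.Generator) -> ResponseMatrix:
    """Permute each drug's observed responses across its observed cells.

    Missingness pattern and each drug's multiset of values are
    preserved; only the assignment of value to cell line is destroyed.
    """
    data = rm.data.copy()
    for drug in data.columns:
        col = data[drug].to_numpy(float)
        idx = np.flatnonzero(~np.isnan(col))
        col[idx] = col[idx[rng.permutation(len(idx))]]
        data[drug] = col
    return ResponseMatrix(data, norm_record=rm.norm_record)


@dataclass
class ShuffleReport:
    null_r: pd.Series  # per-drug correlation on shuffled responses
    threshold: float
    fraction_below: float  # fraction of drugs with |r| < threshold


def shuffle_control(
    study: AlignedStudy,
    params: ModelParams,
    seed: int,
    threshold: float = NULL_R_THRESHOLD,
) -> ShuffleReport:
    """Permutation null for the leave-one-out correlations.

    Responses are shuffled per drug (seeded), predictions recomputed
    with the same fitted parameters, and per-drug correlations with
    the shuffled truth reported.  Near-zero null correlations indicate
    the cross-validation is not optimistically biased.
    """
    rng = np.random.default_rng(seed)
    shuffled = study.with_responses(shuffle_responses(study.responses, rng))
    null_r = loocv_correlations(shuffled, params)
    finite = null_r.dropna()
    frac = float((finite.abs() < threshold).mean()) if len(finite) else float("nan")
    return ShuffleReport(null_r=null_r, threshold=threshold, fraction_below=frac)


@dataclass
class StratificationReport:
    """Pairwise response-correlation distributions across similarity bins."""

    axis: str  # "cells" or "drugs"
    pairs: pd.DataFrame  # entity_a, entity_b, similarity, response_r, bin
    bin_means: pd.Series  # per-bin mean response correlation
    tests: pd.DataFrame  # adjacent-bin Welch t-tests: bin_a, bin_b, t, p
    n_skipped: int  # pairs with <3 shared observations


def stratify_similarity(
    sn: SimilarityNetwork,
    rm: ResponseMatrix,
    axis: str = "cells",
    bins: int | np.ndarray | None = None,
) -> StratificationReport:
    """Bin entity pairs by similarity and compare response correlations.

    For cells, each pair's correlation is over their shared observed
    drug responses (expression-similar cell lines should respond
    alike); for drugs, over shared observed cell lines.  ``bins`` is a
    number of quantile bins (default 10 for cells, 3 for drugs —
    low/intermediate/high) or explicit edges.  Adjacent bins are
    compared with Welch's t-test.
    """
    if axis not in ("cells", "drugs"):
        raise ValueError("axis must be 'cells' or 'drugs'")
    if bins is None:
        bins = 10 if axis == "cells" else 3
    mat = rm.data if axis == "cells" else rm.data.T
    ids = [e for e in sn.entity_ids if e in mat.index]
    vals = mat.loc[ids].to_numpy(float)
    rho = sn.rho.loc[ids, ids].to_numpy(float)
    rows, n_skipped = [], 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            shared = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if shared.sum() < 3:
                n_skipped += 1
                continue
            r = _pearson(vals[i, shared], vals[j, shared])
            if np.isnan(r):
                n_skipped += 1
                continue
            rows.append((ids[i], ids[j], rho[i, j], r))
    pairs = pd.DataFrame(rows, columns=["entity_a", "entity_b", "similarity", "response_r"])
    if len(pairs) == 0:
        raise ValueError("no entity pair with >=3 shared observed responses")
    if np.isscalar(bins):
        binned = pd.qcut(pairs["similarity"], int(bins), labels=False, duplicates="drop")
    else:
        binned = pd.cut(pairs["similarity"], np.asarray(bins, float), labels=False, include_lowest=True)
    pairs["bin"] = binned
    bin_means = pairs.groupby("bin")["response_r"].mean()
    tests = []
    labels = sorted(pairs["bin"].dropna().unique())
    for a, b in zip(labels, labels[1:]):
        ga = pairs.loc[pairs["bin"] == a, "response_r"]
        gb = pairs.loc[pairs["bin"] == b, "response_r"]
        if len(ga) < 2 or len(gb) < 2:
            t, p = float("nan"), float("nan")
        else:
            t, p = _welch(ga.to_numpy(), gb.to_numpy())
        tests.append({"bin_a": a, "bin_b": b, "t": t, "p": p})
    return StratificationReport(
        axis=axis,
        pairs=pairs,
        bin_means=bin_means,
        tests=pd.DataFrame(tests),
        n_skipped=n_skipped,
    )


@dataclass
class GroupComparison:
    """Welch t-test of predicted responses between two cell-line groups."""

    drug_id: str
    n_pos: int
    n_neg: int
    mean_pos: float
    mean_neg: float
    direction: str  # "positive-lower", "positive-higher" or "equal"
    t: float | None
    p: float | None
    n_unlabeled: int


def group_compare(
    predicted: PredictionResult | pd.DataFrame,
    labels: dict[str, bool],
    drug: str,
) -> GroupComparison:
    """Compare a drug's predicted responses between binary cell groups.

    Cells absent from ``labels`` are excluded (counted).  A group with
    fewer than 2 members yields a report without a test statistic.
    """
    if isinstance(predicted, PredictionResult):
        col = predicted.predicted[drug]
    else:
        col = predicted[drug]
    col = col.dropna()
    n_unlabeled = int((~col.index.isin(list(labels))).sum())
    lab = pd.Series({c: bool(labels[c]) for c in col.index if c in labels})
    pos = col[lab.index[lab]].to_numpy(float)
    neg = col[lab.index[~lab]].to_numpy(float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both label groups must be non-empty among covered cells")
    mp, mn = float(pos.mean()), float(neg.mean())
    direction = "equal" if mp == mn else ("positive-lower" if mp < mn else "positive-higher")
    if len(pos) < 2 or len(neg) < 2:
        t = p = None
    else:
        t, p = _welch(pos, neg)
    return GroupComparison(
        drug_id=str(drug),
        n_pos=len(pos),
        n_neg=len(neg),
        mean_pos=mp,
        mean_neg=mn,
        direction=direction,
        t=t,
        p=p,
        n_unlabeled=n_unlabeled,
    )
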