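import numpy as np
import pandas as pd
import pytest

from conftest import IdentityRng, make_toy_study
from dualnet import (
    ModelParams,
    PredictionResult,
    ResponseMatrix,
    evaluate_predictions,
    group_compare,
    loocv_correlations,
    predict_matrix,
    shuffle_control,
    shuffle_responses,
    stratify_similarity,
)
from dualnet.similarity import SimilarityNetwork


def _result(df):
    return PredictionResult(predicted=df, layer="integrated", coverage=df.notna())


class TestDrugEvaluation:
    def test_perfect_prediction(self):
        obs = ResponseMatrix(pd.DataFrame({"d": [0.1, 0.5, 0.9, 0.3]}, index=list("abcd")))
        evals = evaluate_predictions(obs, _result(obs.data.copy()))
        e = evals[0]
        assert e.pearson_r == pytest.approx(1.0)
        assert e.rmse == 0.0 and e.nrmse == 0.0

    def test_hand_computed_reversal(self):
        # observed [0,1,2] vs predicted [2,1,0]: r=-1, RMSE=sqrt(8/3), NRMSE=RMSE/2
        obs = ResponseMatrix(pd.DataFrame({"d": [0.0, 1.0, 2.0]}, index=list("abc")))
        pred = pd.DataFrame({"d": [2.0, 1.0, 0.0]}, index=list("abc"))
        e = evaluate_predictions(obs, _result(pred))[0]
        assert e.pearson_r == pytest.approx(-1.0)
        assert e.rmse == pytest.approx(np.sqrt(8.0 / 3.0))
        assert e.nrmse == pytest.approx(np.sqrt(8.0 / 3.0) / 2.0)

    def test_constant_prediction_has_no_correlation(self):
        obs = ResponseMatrix(pd.DataFrame({"d": [0.0, 1.0, 2.0]}, index=list("abc")))
        pred = pd.DataFrame({"d": [1.0, 1.0, 1.0]}, index=list("abc"))
        e = evaluate_predictions(obs, _result(pred))[0]
        assert np.isnan(e.pearson_r) and "constant" in e.note
        assert e.rmse > 0

    def test_too_few_pairs_suppress_correlation(self):
        obs = ResponseMatrix(pd.DataFrame({"d": [0.0, 1.0, np.nan]}, index=list("abc")))
        pred = pd.DataFrame({"d": [0.2, 0.8, 0.5]}, index=list("abc"))
        e = evaluate_predictions(obs, _result(pred))[0]
        assert e.n_pairs == 2 and np.isnan(e.pearson_r)

    def test_zero_range_makes_nrmse_missing(self):
        obs = ResponseMatrix(pd.DataFrame({"d": [1.0, 1.0, 1.0]}, index=list("abc")))
        pred = pd.DataFrame({"d": [0.9, 1.1, 1.0]}, index=list("abc"))
        e = evaluate_predictions(obs, _result(pred))[0]
        assert np.isnan(e.nrmse) and e.rmse > 0

    def test_nrmse_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(size=10)
        p = y + rng.normal(scale=0.1, size=10)
        ids = [f"c{i}" for i in range(10)]
        base = evaluate_predictions(
            ResponseMatrix(pd.DataFrame({"d": y}, index=ids)),
            _result(pd.DataFrame({"d": p}, index=ids)),
        )[0]
        scaled = evaluate_predictions(
            ResponseMatrix(pd.DataFrame({"d": 7 * y - 3}, index=ids)),
            _result(pd.DataFrame({"d": 7 * p - 3}, index=ids)),
        )[0]
        assert scaled.nrmse == pytest.approx(base.nrmse, rel=1e-12)
        assert scaled.pearson_r == pytest.approx(base.pearson_r, rel=1e-12)


class TestShuffleControl:
    def test_same_seed_reproduces(self, toy_study):
        params = ModelParams(sigma=0.4, tau=0.4)
        a = shuffle_control(toy_study, params, seed=5)
        b = shuffle_control(toy_study, params, seed=5)
        pd.testing.assert_series_equal(a.null_r, b.null_r)

    def test_permutation_preserves_value_multisets(self, toy_study):
        rng = np.random.default_rng(1)
        shuffled = shuffle_responses(toy_study.responses, rng)
        for d in toy_study.responses.drug_ids:
            assert sorted(shuffled.data[d].dropna()) == pytest.approx(
                sorted(toy_study.responses.data[d].dropna())
            )

    def test_identity_permutation_reproduces_evaluation(self, default_study):
        study, _ = default_study
        params = ModelParams(sigma=0.3, tau=0.4)
        unshuffled = shuffle_responses(study.responses, IdentityRng())
        pd.testing.assert_frame_equal(unshuffled.data, study.responses.data)
        null = loocv_correlations(study.with_responses(unshuffled), params)
        real = loocv_correlations(study, params)
        pd.testing.assert_series_equal(null, real)

    def test_shuffling_destroys_signal(self, default_study):
        study, _ = default_study
        params = ModelParams(sigma=0.3, tau=0.4)
        real = loocv_correlations(study, params)
        null = shuffle_control(study, params, seed=11).null_r
        assert null.abs().median() < real.abs().median()


class TestStratification:
    def _smooth_case(self, n=20, p=60, noise=0.0, seed=0):
        # entities on a circle: both similarity and response correlation
        # approximate cos(theta_i - theta_j), monotone in each other
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0, np.pi / 2, size=n))
        basis = rng.normal(size=(2, p))
        rows = np.cos(theta)[:, None] * basis[0] + np.sin(theta)[:, None] * basis[1]
        rows += noise * rng.normal(size=rows.shape)
        ids = [f"e{i}" for i in range(n)]
        rho = np.cos(theta[:, None] - theta[None, :])
        sn = SimilarityNetwork(pd.DataFrame(rho, index=ids, columns=ids))
        rm = ResponseMatrix(pd.DataFrame(rows, index=ids, columns=[f"d{j}" for j in range(p)]))
        return sn, rm

    def test_mean_correlation_increases_across_bins(self):
        sn, rm = self._smooth_case()
        rep = stratify_similarity(sn, rm, axis="cells", bins=5)
        assert np.all(np.diff(rep.bin_means.to_numpy()) > 0)
        assert (rep.tests["t"] < 0).all()  # lower bin mean < upper bin mean

    def test_null_responses_show_no_systematic_differences(self):
        # independent noise: adjacent-bin tests significant at ~alpha rate
        n_sig = n_tests = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ids = [f"e{i}" for i in range(12)]
            x = rng.normal(size=(12, 15))
            rho = np.corrcoef(x)
            np.fill_diagonal(rho, 1.0)
            sn = SimilarityNetwork(pd.DataFrame((rho + rho.T) / 2, index=ids, columns=ids))
            rm = ResponseMatrix(
                pd.DataFrame(rng.normal(size=(12, 30)), index=ids,
                             columns=[f"d{j}" for j in range(30)])
            )
            rep = stratify_similarity(sn, rm, axis="cells", bins=3)
            n_sig += int((rep.tests["p"] < 0.05).sum())
            n_tests += len(rep.tests)
        assert n_sig / n_tests <= 0.10

    def test_drug_axis_three_groups(self, default_study):
        study, _ = default_study
        from dualnet import build_similarity

        sn = build_similarity(study.descriptors, standardize=True)
        rep = stratify_similarity(sn, study.responses, axis="drugs")
        assert rep.pairs["bin"].nunique() == 3

    def test_sparse_pairs_skipped_and_counted(self):
        sn, rm = self._smooth_case(n=5, p=4)
        data = rm.data.copy()
        data.iloc[0, :2] = np.nan
        data.iloc[1, 2:] = np.nan  # pair (e0, e1) shares 0 observations
        rep = stratify_similarity(SimilarityNetwork(sn.rho), ResponseMatrix(data), bins=2)
        assert rep.n_skipped >= 1

    def test_identical_bin_populations_give_zero_t(self):
        from dualnet.evaluate import _welch

        t, p = _welch(np.array([0.5, 0.5, 0.5]), np.array([0.5, 0.5, 0.5]))
        assert t == 0.0 and p == 1.0


class TestGroupCompare:
    def _pred_frame(self, pos, neg, drug="d"):
        vals = np.concatenate([pos, neg])
        ids = [f"p{i}" for i in range(len(pos))] + [f"n{i}" for i in range(len(neg))]
        return pd.DataFrame({drug: vals}, index=ids), {
            **{f"p{i}": True for i in range(len(pos))},
            **{f"n{i}": False for i in range(len(neg))},
        }

    def test_detects_sensitization_direction_with_power(self):
        # shift of 2 noise-sd at 30 per group: detected in >=95% of seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = rng.normal(loc=-2.0, scale=1.0, size=30)
            neg = rng.normal(loc=0.0, scale=1.0, size=30)
            df, labels = self._pred_frame(pos, neg)
            rep = group_compare(df, labels, "d")
            hits += rep.direction == "positive-lower" and rep.p < 0.05
        assert hits >= 95

    def test_identical_groups_give_zero_t(self):
        df, labels = self._pred_frame(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        rep = group_compare(df, labels, "d")
        assert rep.t == pytest.approx(0.0)

    def test_unlabeled_cells_excluded_and_counted(self):
        df, labels = self._pred_frame(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        del labels["p0"]
        rep = group_compare(df, labels, "d")
        assert rep.n_unlabeled == 1 and rep.n_pos == 1

    def test_tiny_group_reports_without_pvalue(self):
        df, labels = self._pred_frame(np.array([1.0]), np.array([2.0, 3.0]))
        rep = group_compare(df, labels, "d")
        assert rep.p is None and rep.n_pos == 1

    def test_empty_group_rejected(self):
        df, labels = self._pred_frame(np.array([1.0, 2.0]), np.array([3.0]))
        labels = {k: True for k in labels}
        with pytest.raises(ValueError, match="non-empty"):
            group_compare(df, labels, "d")
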