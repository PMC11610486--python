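"""The five regression models: kNN mixed distance, OLS/PLS, stacking, ensembles."""

import math

import numpy as np
import pandas as pd
import pytest

from nanozeta.exceptions import ConfigurationError, DomainError, FitError
from nanozeta.models import (
    ADABOOST_CONFIG,
    AdaBoostZP,
    EnsembleConfig,
    KNNReadAcross,
    MLP_STACKER_PARAMS,
    QRASPR_DESCRIPTOR_SETS,
    RF_CONFIG,
    RandomForestZP,
    StackedQRASPR,
    design_frame,
    ensemble_fit_predict,
    fit_mlr,
    mixed_distance,
    pls1_fit_predict,
)
from nanozeta.synthetic import SynthConfig, generate_dataset
from nanozeta.datasets import apply_split


class TestMixedDistance:
    def test_identical_records(self):
        a = {"x": 1.0, "c": "rod"}
        assert mixed_distance(a, a, ["x"], ["c"]) == 0.0

    def test_numeric_plus_categorical(self):
        a = {"x": 0.0, "c": "rod"}
        b = {"x": 0.3, "c": "spherical"}
        assert mixed_distance(a, b, ["x"], ["c"]) == pytest.approx(
            math.sqrt(0.09 + 1), abs=1e-9
        )

    def test_two_categorical_mismatches(self):
        a = {"c1": "u", "c2": "v"}
        b = {"c1": "x", "c2": "y"}
        assert mixed_distance(a, b, [], ["c1", "c2"]) == pytest.approx(math.sqrt(2))

    def test_missing_feature_rejected(self):
        with pytest.raises(DomainError):
            mixed_distance({"x": 1}, {}, ["x"], [])


def _knn_frame(dls, ct=None, ids=None):
    n = len(dls)
    return pd.DataFrame({
        "CF": ["CeO2"] * n, "Dsph": [20.0] * n, "Shape": ["spherical"] * n,
        "CT": ct or ["uncoated"] * n, "DLS": dls, "MW": [172.1] * n,
        "A11": [14.0] * n, "A132": [3.9] * n, "Nmetal": [1.0] * n,
        "Noxygen": [2] * n, "Metals_SumIP": [534.4] * n,
    }, index=ids or [f"r{i}" for i in range(n)])


class TestKNNReadAcross:
    def test_predictions_match_brute_force_oracle(self, micro):
        # independent re-computation: z-score numerics on the training rows,
        # mixed distances by explicit loops, k=3 inverse-distance weighting
        train, test = apply_split(micro, "flags")
        X_tr, y_tr = design_frame(train)
        X_te, _ = design_frame(test)
        num, cat = ["Dsph", "DLS", "Noxygen", "A132"], ["CT", "Shape"]
        mean, std = X_tr[num].mean(), X_tr[num].std(ddof=0)
        knn = KNNReadAcross(k=3).fit(X_tr, y_tr)
        pred = knn.predict(X_te)
        for qi, qid in enumerate(X_te.index):
            dists = []
            for tid in X_tr.index:
                d2 = sum(((X_te.loc[qid, f] - mean[f]) / std[f]
                          - (X_tr.loc[tid, f] - mean[f]) / std[f]) ** 2 for f in num)
                d2 += sum(X_te.loc[qid, f] != X_tr.loc[tid, f] for f in cat)
                dists.append((math.sqrt(d2), tid))
            dists.sort()
            top = dists[:3]
            w = np.array([1.0 / d for d, _ in top])
            yv = np.array([y_tr[t] for _, t in top])
            assert pred[qi] == pytest.approx(float((w * yv).sum() / w.sum()), abs=1e-9)

    def test_fixed_distance_weighting_example(self):
        # the weighting rule itself: d=[1,2], y=[10,40] -> 20
        w = np.array([1.0, 0.5])
        y = np.array([10.0, 40.0])
        assert (w @ y) / w.sum() == pytest.approx(20.0)

    def test_zero_distance_rule_returns_duplicate_response(self):
        train = _knn_frame([100.0, 150.0, 200.0, 250.0])
        knn = KNNReadAcross(k=3, numeric_features=("DLS",), categorical_features=(),
                            exclude_matching_id=False)
        knn.fit(train, [1.0, 2.0, 3.0, 4.0])
        query = _knn_frame([150.0], ids=["q"])
        assert knn.predict(query)[0] == pytest.approx(2.0)

    def test_zero_distance_tie_averages_duplicates(self):
        train = _knn_frame([100.0, 100.0, 200.0, 300.0])
        knn = KNNReadAcross(k=3, numeric_features=("DLS",), categorical_features=(),
                            exclude_matching_id=False)
        knn.fit(train, [5.0, 9.0, 1.0, 1.0])
        query = _knn_frame([100.0], ids=["q"])
        assert knn.predict(query)[0] == pytest.approx(7.0)

    def test_self_exclusion_for_training_queries(self):
        train = _knn_frame([100.0, 150.0, 200.0])
        knn = KNNReadAcross(k=2, numeric_features=("DLS",), categorical_features=())
        knn.fit(train, [1.0, 2.0, 3.0])
        rep = knn.kneighbors(train.iloc[[0]])
        assert "r0" not in rep["neighbor_id"].tolist()

    def test_neighbour_bound_property(self, study_split):
        X_tr, y_tr, X_te, _ = study_split
        knn = KNNReadAcross().fit(X_tr, y_tr)
        rep = knn.kneighbors(X_te)
        preds = knn.predict(X_te)
        for qid, p in zip(X_te.index.astype(str), preds):
            nb = rep.loc[rep["query_id"] == qid, "neighbor_zp"]
            assert nb.min() - 1e-9 <= p <= nb.max() + 1e-9

    def test_k_larger_than_training_rejected(self):
        train = _knn_frame([100.0, 150.0])
        with pytest.raises(FitError):
            KNNReadAcross(k=7).fit(train, [1.0, 2.0])


class TestMlr:
    def test_exact_linear_recovery(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = 2 * X["x"] + 1
        m = fit_mlr(X, y)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)
        assert m.coefficients["x"] == pytest.approx(2.0, abs=1e-10)

    def test_orthogonal_response_gives_zero_coefficients(self):
        X = pd.DataFrame({"x": [-1.0, 1.0, -1.0, 1.0]})
        y = [-1.0, -1.0, 1.0, 1.0]  # orthogonal to x and to the intercept
        m = fit_mlr(X, y)
        assert m.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_shrinks_to_true_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        beta = np.array([1.5, -2.0, 0.5])
        y = X.to_numpy() @ beta + rng.normal(0, 1e-8, 200)
        m = fit_mlr(X, y)
        assert np.allclose([m.coefficients[c] for c in "abc"], beta, atol=1e-6)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(FitError, match="x"):
            fit_mlr(X, rng.normal(size=30))


class TestPls1:
    def test_single_column_equals_simple_regression(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 3.0 * X["x"] + rng.normal(0, 0.1, 40)
        Xq = pd.DataFrame({"x": rng.normal(size=10)})
        pls = pls1_fit_predict(X, y, Xq, n_lv=1)
        ols = fit_mlr(X, y).predict(Xq)
        assert np.allclose(pls, ols, atol=1e-8)

    def test_full_rank_full_lv_equals_ols(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(size=50)
        Xq = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        pls = pls1_fit_predict(X, y, Xq, n_lv=4)
        ols = fit_mlr(X, y).predict(Xq)
        assert np.allclose(pls, ols, atol=1e-8)

    def test_constant_response_predicts_constant(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = np.full(20, 7.0)
        pred = pls1_fit_predict(X, y, X, n_lv=1)
        assert np.allclose(pred, 7.0, atol=1e-8)

    def test_excess_components_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=20)})
        with pytest.raises(FitError):
            pls1_fit_predict(X, rng.normal(size=20), X, n_lv=3)


class TestEnsembles:
    def test_constant_response(self, study_split, rng):
        X_tr, _, X_te, _ = study_split
        y_const = np.full(len(X_tr), -12.5)
        for model in (RandomForestZP(), AdaBoostZP()):
            model.fit(X_tr, y_const)
            assert np.allclose(model.predict(X_te), -12.5)

    def test_published_hyperparameters_pinned(self):
        assert RF_CONFIG.hyperparameters == {
            "n_estimators": 128, "max_depth": 5, "random_state": 42}
        assert ADABOOST_CONFIG.hyperparameters == {
            "n_estimators": 9, "learning_rate": 0.997, "random_state": 786}
        assert MLP_STACKER_PARAMS == {
            "activation": "logistic", "alpha": 1.0, "learning_rate_init": 0.01,
            "max_iter": 1000, "random_state": 0, "solver": "lbfgs"}

    def test_generic_dispatch_matches_wrappers_are_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        p1 = ensemble_fit_predict(X, y, X, RF_CONFIG)
        p2 = ensemble_fit_predict(X, y, X, RF_CONFIG)
        assert np.array_equal(p1, p2)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            EnsembleConfig("boosted_llama").build()


class TestStackedQRASPR:
    def test_descriptor_sets_match_published_combinations(self):
        assert QRASPR_DESCRIPTOR_SETS["M1"] == (
            "Metals_SumIP", "ra_function", "cvsim", "pos_avg_sim", "neg_avg_sim", "sm1")
        assert QRASPR_DESCRIPTOR_SETS["M2"][0] == "LOG_DLS"
        assert all(len(v) == 6 for v in QRASPR_DESCRIPTOR_SETS.values())

    def test_degenerate_stack_equals_single_mlr(self, study_split):
        # four identical descriptor sets -> rank-1 stack; PLS(1) on the OLS
        # fitted values reproduces them (slope 1, intercept 0 in-sample)
        X_tr, y_tr, X_te, _ = study_split
        sets = {f"M{i}": QRASPR_DESCRIPTOR_SETS["M1"] for i in range(1, 5)}
        model = StackedQRASPR(descriptor_sets=sets).fit(X_tr, y_tr)
        single = model.mlr_predictions(X_te)["M1"].to_numpy()
        assert np.allclose(model.predict(X_te), single, atol=1e-8)

    def test_noiseless_recovery_through_stack(self):
        # response a pure function of LOG_DLS, which M2-M4 contain: with
        # enough latent variables to span the stack (M2-M4 collapse to one
        # exact column, so rank 2), the stacked fit is exact as noise vanishes
        coef = {"intercept": 0.0, "coating:sodium citrate": 0.0,
                "coating:L-arginine": 0.0, "coating:PVP": 0.0,
                "coating:uncoated": 0.0, "coating:other": 0.0,
                "core_metal": 0.0, "log_dls": -20.0, "mw_per_100": 0.0}
        ds = generate_dataset(SynthConfig(seed=4, zp_coefficients=coef, noise_sd=0.0))
        train, test = apply_split(ds, "flags")
        X_tr, y_tr = design_frame(train)
        X_te, y_te = design_frame(test)
        model = StackedQRASPR(n_lv=2).fit(X_tr, y_tr)
        pred = model.predict(X_te)
        ss_res = float(((y_te - pred) ** 2).sum())
        ss_tot = float(((y_te - y_te.mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot > 0.999

    def test_missing_descriptor_rejected(self, study_split):
        X_tr, y_tr, _, _ = study_split
        bad = {"M1": ("no_such_descriptor",) + QRASPR_DESCRIPTOR_SETS["M1"][1:]}
        with pytest.raises(ConfigurationError, match="no_such_descriptor"):
            StackedQRASPR(descriptor_sets=bad).fit(X_tr, y_tr)

    def test_mlp_stacker_runs_with_published_settings(self, study_split):
        X_tr, y_tr, X_te, _ = study_split
        model = StackedQRASPR(stacker="mlp").fit(X_tr, y_tr)
        assert len(model.predict(X_te)) == len(X_te)
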