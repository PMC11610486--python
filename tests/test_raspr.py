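"""Read-across similarity kernels and RASPR descriptor computation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanozeta.exceptions import ConfigurationError, DomainError
from nanozeta.raspr import (
    CloseSourceSet,
    RasprCalculator,
    SimilarityConfig,
    optimize_raspr_hyperparameters,
    raspr_descriptors,
    select_close_sources,
    similarity,
)


class TestSimilarity:
    @pytest.mark.parametrize("kernel", ["euclidean", "gaussian", "laplacian"])
    def test_identity_gives_one(self, kernel):
        cfg = SimilarityConfig(kernel=kernel, sigma=2.0)
        assert similarity(np.ones(3), np.ones(3), cfg) == pytest.approx(1.0)

    def test_laplacian_at_one_sigma(self):
        cfg = SimilarityConfig(kernel="laplacian", sigma=2.0)
        assert similarity(np.zeros(1), np.array([2.0]), cfg) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_euclidean_reciprocal_form(self):
        cfg = SimilarityConfig(kernel="euclidean")
        assert similarity(np.zeros(1), np.ones(1), cfg) == pytest.approx(0.5)

    def test_gaussian_closed_form(self):
        cfg = SimilarityConfig(kernel="gaussian", sigma=1.0)
        assert similarity(np.zeros(1), np.array([2.0]), cfg) == pytest.approx(
            math.exp(-2.0), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            similarity(np.zeros(2), np.zeros(3), SimilarityConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimilarityConfig(kernel="cosine")
        with pytest.raises(ConfigurationError):
            SimilarityConfig(sigma=0.0)


def _sources(values):
    return pd.DataFrame({"f": values}, index=[f"s{i}" for i in range(len(values))])


class TestSelectCloseSources:
    def test_all_returned_sorted_when_pool_equals_n_close(self):
        css = select_close_sources(
            np.array([0.0]), "q", _sources([0.1, 0.5, 0.2, 0.9, 0.3]),
            [1, 2, 3, 4, 5], SimilarityConfig(n_close=5),
        )
        assert len(css.source_ids) == 5
        assert all(np.diff(css.similarities) <= 0)

    def test_tie_breaks_by_ascending_id(self):
        css = select_close_sources(
            np.array([0.0]), "q", _sources([1.0, 1.0, 5.0]),
            [10, 20, 30], SimilarityConfig(n_close=2),
        )
        assert css.source_ids == ["s0", "s1"]

    def test_leave_self_out_excludes_query(self):
        css = select_close_sources(
            np.array([0.0]), "s0", _sources([0.0, 1.0, 2.0]),
            [1, 2, 3], SimilarityConfig(n_close=2), exclude_id="s0",
        )
        assert "s0" not in css.source_ids

    def test_insufficient_pool_rejected(self):
        with pytest.raises(DomainError):
            select_close_sources(
                np.array([0.0]), "q", _sources([1.0, 2.0]), [1, 2],
                SimilarityConfig(n_close=3),
            )

    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=8, max_size=20))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_sort(self, values):
        cfg = SimilarityConfig(n_close=5)
        src = _sources(values)
        css = select_close_sources(np.array([0.0]), "q", src, values, cfg)
        sims = {f"s{i}": similarity(np.array([0.0]), np.array([v]), cfg)
                for i, v in enumerate(values)}
        brute = sorted(sims, key=lambda k: (-sims[k], k))[:5]
        assert css.source_ids == brute


class TestRasprDescriptors:
    def test_equal_similarities_give_plain_mean(self):
        css = CloseSourceSet("q", list("abcde"), np.full(5, 0.5),
                             np.array([1.0, 2, 3, 4, 5]))
        d = raspr_descriptors(css, train_mean_response=3.0, cfg=SimilarityConfig())
        assert d["ra_function"] == pytest.approx(3.0)
        assert d["cvsim"] == pytest.approx(0.0)
        assert d["sd_similarity"] == pytest.approx(0.0)

    def test_weighted_mean_two_to_one(self):
        css = CloseSourceSet("q", ["a", "b"], np.array([2 / 3, 1 / 3]),
                             np.array([10.0, 40.0]))
        d = raspr_descriptors(css, 0.0, SimilarityConfig())
        assert d["ra_function"] == pytest.approx(20.0)

    def test_all_sources_at_query_value(self):
        css = CloseSourceSet("q", list("abc"), np.array([0.9, 0.8, 0.7]),
                             np.full(3, -7.5))
        d = raspr_descriptors(css, 0.0, SimilarityConfig())
        assert d["ra_function"] == pytest.approx(-7.5)
        assert d["sd_activity"] == pytest.approx(0.0, abs=1e-12)

    def test_positive_negative_partition(self):
        css = CloseSourceSet("q", list("abcd"), np.array([0.9, 0.8, 0.7, 0.6]),
                             np.array([10.0, -10.0, 20.0, -20.0]))
        d = raspr_descriptors(css, 0.0, SimilarityConfig(posneg_rule="zero"))
        assert d["max_pos"] == pytest.approx(0.9)
        assert d["max_neg"] == pytest.approx(0.8)
        assert d["pos_avg_sim"] == pytest.approx(0.8)   # (0.9 + 0.7)/2
        assert d["neg_avg_sim"] == pytest.approx(0.7)   # (0.8 + 0.6)/2
        assert d["sm1"] == pytest.approx((0.9 - 0.8) * 0.5)
        assert d["sm2"] == pytest.approx((0.8 - 0.7) * 0.5)

    @given(
        sims=st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=8),
        ys=st.lists(st.floats(min_value=-50, max_value=50), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_ra_function_is_convex_combination(self, sims, ys):
        y = np.array(ys[: len(sims)])
        css = CloseSourceSet("q", [str(i) for i in range(len(sims))],
                             np.array(sorted(sims, reverse=True)), y)
        d = raspr_descriptors(css, 0.0, SimilarityConfig())
        assert y.min() - 1e-9 <= d["ra_function"] <= y.max() + 1e-9


class TestRasprCalculator:
    def test_training_rows_leave_self_out(self, rng):
        X = pd.DataFrame({"f1": rng.normal(size=12), "f2": rng.normal(size=12)},
                         index=[f"nm{i}" for i in range(12)])
        y = rng.normal(size=12)
        calc = RasprCalculator(SimilarityConfig(n_close=5)).fit(X, y)
        # with self-inclusion the top source would be the query itself (s=1)
        # and ra_function would be pulled hard toward the query's own response;
        # verify against a brute-force leave-self-out computation instead
        out = calc.transform(X.iloc[[0]])
        pool = calc.scaler_.apply(X)
        q = pool.iloc[0].to_numpy()
        sims = {i: 1 / (1 + np.linalg.norm(q - pool.iloc[i].to_numpy()))
                for i in range(1, 12)}
        top = sorted(sims, key=lambda i: (-sims[i], f"nm{i}"))[:5]
        s = np.array([sims[i] for i in top])
        expected = float(s @ y[top] / s.sum())
        assert out["ra_function"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_descriptor_frame_shape(self, study_split):
        X_tr, y_tr, X_te, _ = study_split
        from nanozeta.models import qraspr_feature_frame

        q_tr = qraspr_feature_frame(X_tr)
        cols = [c for c in q_tr.columns if q_tr[c].std(ddof=0) > 0]
        calc = RasprCalculator(SimilarityConfig()).fit(q_tr[cols], y_tr)
        out = calc.transform(qraspr_feature_frame(X_te)[cols])
        assert len(out) == len(X_te)
        assert set(out.columns) >= {"ra_function", "cvsim", "se", "sd_activity",
                                    "sd_similarity", "pos_avg_sim", "neg_avg_sim",
                                    "max_pos", "sm1", "sm2"}
        assert out.notna().all().all()


class TestOptimizer:
    def test_single_config_returned(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=20)})
        y = rng.normal(size=20)
        cfg = SimilarityConfig(n_close=3)
        assert optimize_raspr_hyperparameters(X, y, [cfg], split_seed=0) is cfg

    def test_matched_kernel_beats_mis_scaled(self, rng):
        # smooth response of one feature: a well-scaled Gaussian kernel must
        # out-predict a grossly mis-scaled one on the validation split
        X = pd.DataFrame({"f": rng.uniform(-2, 2, size=60)})
        y = np.sin(X["f"].to_numpy()) * 10
        good = SimilarityConfig(kernel="gaussian", sigma=0.5, n_close=5)
        bad = SimilarityConfig(kernel="gaussian", sigma=200.0, n_close=5)
        best = optimize_raspr_hyperparameters(X, y, [bad, good], split_seed=1)
        assert best is good

    def test_published_setting_is_expressible(self):
        cfg = SimilarityConfig(kernel="euclidean", n_close=5)
        assert cfg.kernel == "euclidean" and cfg.n_close == 5

    def test_tiny_validation_set_rejected(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=5)})
        with pytest.raises(DomainError):
            optimize_raspr_hyperparameters(
                X, rng.normal(size=5), [SimilarityConfig(n_close=2)], split_seed=0
            )
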