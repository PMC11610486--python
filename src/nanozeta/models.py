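"""The five zeta-potential regression models.

All estimators follow the scikit-learn contract (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing underscores)
and consume the canonical nanomaterial feature frame (columns ``CF, Dsph,
Shape, CT, DLS, MW, A11, A132, Nmetal, Noxygen, Metals_SumIP`` indexed by
record id).  Each estimator owns its preprocessing recipe — encodings and
scalings are fitted on the training rows inside ``fit`` and replayed
unchanged inside ``predict`` — so a bare frame in, predictions out.

Models:

- :class:`KNNReadAcross` — inverse-distance-weighted k-nearest neighbours
  with a mixed Euclidean/categorical-mismatch distance (read-across).
- :class:`RandomForestZP`, :class:`AdaBoostZP` — tree ensembles with the
  published hyperparameters, delegated to scikit-learn.
- :class:`StackedQRASPR` — four multiple-linear-regression models on fused
  physicochemical + read-across similarity (RASPR) descriptors, stacked by a
  PLS (1 latent variable) or MLP meta-regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .exceptions import ConfigurationError, DomainError, FitError
from .features import (
    COATING_GROUPS,
    ScalerParams,
    UNCOATED,
    group_coating,
    log_transform_dls,
    parse_formula,
    zscore_fit,
)
from .raspr import RasprCalculator, SimilarityConfig

FEATURE_COLUMNS = ("CF", "Dsph", "Shape", "CT", "DLS", "MW", "A11", "A132",
                   "Nmetal", "Noxygen", "Metals_SumIP")

#: descriptor sets of the four individual q-RASPR regressions
QRASPR_DESCRIPTOR_SETS: dict[str, tuple[str, ...]] = {
    "M1": ("Metals_SumIP", "ra_function", "cvsim", "pos_avg_sim", "neg_avg_sim", "sm1"),
    "M2": ("LOG_DLS", "se", "sd_similarity", "pos_avg_sim", "neg_avg_sim", "sm2"),
    "M3": ("Tot_num_atoms", "LOG_DLS", "sd_activity", "max_pos", "neg_avg_sim", "sm1"),
    "M4": ("LOG_DLS", "sd_activity", "max_pos", "sd_similarity", "neg_avg_sim", "sm1"),
}

#: published MLP stacker hyperparameters
MLP_STACKER_PARAMS = dict(
    activation="logistic", alpha=1.0, learning_rate_init=0.01,
    max_iter=1000, random_state=0, solver="lbfgs",
)


def design_frame(ds) -> tuple[pd.DataFrame, pd.Series]:
    """Split an NMDataset into (feature frame indexed by id, response series)."""
    df = ds.df.set_index("ID")
    X = df[list(FEATURE_COLUMNS)].copy()
    y = df["ZP"].astype(float)
    return X, y


# ---------------------------------------------------------------------------
# kNN / read-across
# ---------------------------------------------------------------------------

def mixed_distance(
    a: Mapping[str, float],
    b: Mapping[str, float],
    numeric_features: Sequence[str],
    categorical_features: Sequence[str],
) -> float:
    """Euclidean distance on numeric features plus a unit penalty per
    categorical mismatch: d = sqrt(sum (a_i-b_i)^2 + sum 1[a_j != b_j])."""
    total = 0.0
    for f in numeric_features:
        if f not in a or f not in b:
            raise DomainError(f"missing numeric feature {f!r}")
        total += (float(a[f]) - float(b[f])) ** 2
    for f in categorical_features:
        if f not in a or f not in b:
            raise DomainError(f"missing categorical feature {f!r}")
        total += 0.0 if a[f] == b[f] else 1.0
    return float(np.sqrt(total))


class KNNReadAcross(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighted kNN with a mixed numeric/categorical metric.

    Numeric features are z-scored with training-set parameters; categorical
    features contribute a unit squared distance on mismatch.  The prediction
    is  sum(w_i y_i)/sum(w_i)  with  w_i = 1/d_i  over the k nearest training
    compounds; if any neighbour is at distance zero the prediction is the
    mean response of the zero-distance neighbours.

    ``exclude_matching_id=True`` removes a training compound from its own
    neighbour pool when it reappears as a query (leave-self-out), so training
    predictions are genuine cross-predictions.
    """

    def __init__(
        self,
        k: int = 7,
        numeric_features: Sequence[str] = ("Dsph", "DLS", "Noxygen", "A132"),
        categorical_features: Sequence[str] = ("CT", "Shape"),
        exclude_matching_id: bool = True,
    ):
        self.k = k
        self.numeric_features = numeric_features
        self.categorical_features = categorical_features
        self.exclude_matching_id = exclude_matching_id

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "KNNReadAcross":
        if self.k > len(X):
            raise FitError(f"k={self.k} exceeds training size {len(X)}")
        num = list(self.numeric_features)
        self.scaler_: ScalerParams = zscore_fit(X, num)
        self.train_num_ = self.scaler_.apply(X[num])[num].to_numpy(float)
        self.train_cat_ = X[list(self.categorical_features)].astype(str).to_numpy()
        self.train_ids_ = [str(i) for i in X.index]
        self.y_ = np.asarray(y, float)
        return self

    def _distances(self, row_num: np.ndarray, row_cat: np.ndarray) -> np.ndarray:
        d2 = ((self.train_num_ - row_num) ** 2).sum(axis=1)
        d2 = d2 + (self.train_cat_ != row_cat).sum(axis=1)
        return np.sqrt(d2)

    def kneighbors(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-query neighbour report: ids, distances and responses of the k
        nearest training compounds (the read-across grouping)."""
        num = list(self.numeric_features)
        Xn = self.scaler_.apply(X[num])[num].to_numpy(float)
        Xc = X[list(self.categorical_features)].astype(str).to_numpy()
        rows = []
        for i, qid in enumerate(str(j) for j in X.index):
            d = self._distances(Xn[i], Xc[i])
            cand = [
                j for j in range(len(d))
                if not (self.exclude_matching_id and self.train_ids_[j] == qid)
            ]
            cand.sort(key=lambda j: (d[j], self.train_ids_[j]))
            for rank, j in enumerate(cand[: self.k], start=1):
                rows.append({
                    "query_id": qid, "rank": rank,
                    "neighbor_id": self.train_ids_[j],
                    "distance": float(d[j]), "neighbor_zp": float(self.y_[j]),
                })
        return pd.DataFrame(rows)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        report = self.kneighbors(X)
        preds = []
        for qid in (str(j) for j in X.index):
            nb = report[report["query_id"] == qid]
            d = nb["distance"].to_numpy()
            yv = nb["neighbor_zp"].to_numpy()
            zero = d == 0.0
            if zero.any():
                preds.append(float(yv[zero].mean()))
            else:
                w = 1.0 / d
                preds.append(float((w * yv).sum() / w.sum()))
        return np.asarray(preds)


# ---------------------------------------------------------------------------
# ordinary least squares and PLS
# ---------------------------------------------------------------------------

@dataclass
class MlrModel:
    """A fitted ordinary-least-squares regression with named coefficients."""

    intercept: float
    coefficients: dict[str, float]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in cols])
        return self.intercept + X[cols].to_numpy(float) @ beta


def fit_mlr(X: pd.DataFrame, y: Sequence[float]) -> MlrModel:
    """OLS with intercept; raises on rank deficiency, naming the columns."""
    yv = np.asarray(y, float)
    if len(X) <= X.shape[1]:
        raise FitError(
            f"need more rows ({len(X)}) than descriptors ({X.shape[1]}) for OLS"
        )
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # point at the most collinear columns via the smallest singular vectors
        _, sv, vt = np.linalg.svd(A, full_matrices=False)
        weights = np.abs(vt[rank:]).sum(axis=0)[1:]
        worst = [c for c, w in zip(X.columns, weights) if w > 1e-8]
        raise FitError(f"rank-deficient design; near-collinear columns: {worst}")
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return MlrModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(X.columns, beta[1:])},
    )


def pls1_fit_predict(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_query: pd.DataFrame,
    n_lv: int = 1,
) -> np.ndarray:
    """Univariate-response PLS regression (NIPALS, autoscaled columns).

    With ``n_lv`` equal to the column rank of a full-rank design, predictions
    coincide with OLS.  Delegated to scikit-learn's PLSRegression.
    """
    rank = np.linalg.matrix_rank(X_train.to_numpy(float) - X_train.to_numpy(float).mean(0))
    if n_lv > rank:
        raise FitError(f"n_lv={n_lv} exceeds design rank {rank}")
    pls = PLSRegression(n_components=n_lv, scale=True)
    pls.fit(X_train.to_numpy(float), np.asarray(y_train, float))
    return pls.predict(X_query.to_numpy(float)).ravel()


# ---------------------------------------------------------------------------
# tree ensembles with the published settings
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    """Named algorithm + complete hyperparameter map (seed included)."""

    algorithm: str
    hyperparameters: dict = dc_field(default_factory=dict)

    def build(self):
        if self.algorithm == "random_forest":
            return RandomForestRegressor(**self.hyperparameters)
        if self.algorithm == "adaboost":
            return AdaBoostRegressor(**self.hyperparameters)
        if self.algorithm == "mlp":
            return MLPRegressor(**self.hyperparameters)
        raise ConfigurationError(f"unknown ensemble algorithm {self.algorithm!r}")


RF_CONFIG = EnsembleConfig(
    "random_forest", dict(n_estimators=128, max_depth=5, random_state=42)
)
ADABOOST_CONFIG = EnsembleConfig(
    "adaboost", dict(n_estimators=9, learning_rate=0.997, random_state=786)
)


def ensemble_fit_predict(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_query: pd.DataFrame,
    cfg: EnsembleConfig,
) -> np.ndarray:
    """Fit the named algorithm with exactly the configured settings and predict."""
    est = cfg.build()
    est.fit(X_train.to_numpy(float), np.asarray(y_train, float))
    return est.predict(X_query.to_numpy(float))


class RandomForestZP(RegressorMixin, BaseEstimator):
    """Random forest on DLS, equivalent sphere diameter, MW and the 5-group
    coating one-hot (trees need no scaling; the near-collinear in-vacuum
    Hamaker constant never enters this recipe)."""

    def __init__(self, n_estimators: int = 128, max_depth: int = 5, random_state: int = 42):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        cols = [X["DLS"].to_numpy(float), X["Dsph"].to_numpy(float), X["MW"].to_numpy(float)]
        groups = [group_coating(v) for v in X["CT"]]
        for g in COATING_GROUPS:
            cols.append(np.array([float(x == g) for x in groups]))
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "RandomForestZP":
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            random_state=self.random_state,
        )
        self.model_.fit(self._encode(X), np.asarray(y, float))
        self.feature_names_ = ["DLS", "Dsph", "MW"] + [f"CT={g}" for g in COATING_GROUPS]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(self._encode(X))


class AdaBoostZP(RegressorMixin, BaseEstimator):
    """AdaBoost on z-scored DLS, Dsph, A11, MW plus the binary coated(0) /
    uncoated(1) coating indicator, with the published boosting settings."""

    def __init__(self, n_estimators: int = 9, learning_rate: float = 0.997,
                 random_state: int = 786):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state

    _NUMERIC = ("DLS", "Dsph", "A11", "MW")

    def _encode(self, X: pd.DataFrame, fit: bool = False) -> np.ndarray:
        num = list(self._NUMERIC)
        if fit:
            self.scaler_ = zscore_fit(X, num)
        scaled = self.scaler_.apply(X[num])[num].to_numpy(float)
        ct = np.array([float(group_coating(v) == UNCOATED) for v in X["CT"]])
        return np.column_stack([scaled, ct])

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "AdaBoostZP":
        self.model_ = AdaBoostRegressor(
            n_estimators=self.n_estimators, learning_rate=self.learning_rate,
            random_state=self.random_state,
        )
        self.model_.fit(self._encode(X, fit=True), np.asarray(y, float))
        self.feature_names_ = list(self._NUMERIC) + ["CT_uncoated"]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(self._encode(X))


# ---------------------------------------------------------------------------
# stacked q-RASPR
# ---------------------------------------------------------------------------

def qraspr_feature_frame(X: pd.DataFrame) -> pd.DataFrame:
    """Physicochemical descriptors feeding the q-RASPR similarity space.

    LOG_DLS, total atom count, Ce/Zr amounts and the rod-shape indicator are
    derived on the fly; the coating enters as an ordinal group code over the
    five canonical coating groups.
    """
    comp = [parse_formula(cf) for cf in X["CF"]]
    out = pd.DataFrame(index=X.index)
    out["A132"] = X["A132"].astype(float)
    out["Metals_SumIP"] = X["Metals_SumIP"].astype(float)
    out["LOG_DLS"] = [log_transform_dls(v) for v in X["DLS"].astype(float)]
    out["Tot_num_atoms"] = X["Nmetal"].astype(float) + X["Noxygen"].astype(float)
    out["amount_Ce"] = [c.get("Ce", 0.0) for c in comp]
    out["amount_Zr"] = [c.get("Zr", 0.0) for c in comp]
    out["rod"] = (X["Shape"] == "rod").astype(float)
    out["coating_code"] = [float(COATING_GROUPS.index(group_coating(v))) for v in X["CT"]]
    return out


class StackedQRASPR(RegressorMixin, BaseEstimator):
    """Four MLR q-RASPR models stacked by a PLS or MLP meta-regressor.

    fit() computes RASPR descriptors against the training pool (training
    compounds leave themselves out of their own source pool), fits the four
    descriptor-set regressions, and fits the stacker on their training
    predictions; predict() replays the chain for new queries.
    """

    def __init__(
        self,
        stacker: str = "pls",
        n_lv: int = 1,
        n_close: int = 5,
        kernel: str = "euclidean",
        sigma: float = 1.0,
        descriptor_sets: Mapping[str, tuple[str, ...]] | None = None,
        mlp_params: Mapping | None = None,
    ):
        self.stacker = stacker
        self.n_lv = n_lv
        self.n_close = n_close
        self.kernel = kernel
        self.sigma = sigma
        self.descriptor_sets = descriptor_sets
        self.mlp_params = mlp_params

    def _descriptor_table(self, X: pd.DataFrame, fit: bool = False,
                          y: Sequence[float] | None = None) -> pd.DataFrame:
        qspr = qraspr_feature_frame(X)
        # drop similarity features that are constant in the training pool
        if fit:
            self.similarity_features_ = [
                c for c in qspr.columns if qspr[c].std(ddof=0) > 0
            ]
            cfg = SimilarityConfig(kernel=self.kernel, sigma=self.sigma,
                                   n_close=self.n_close)
            self.raspr_ = RasprCalculator(cfg).fit(
                qspr[self.similarity_features_], np.asarray(y, float)
            )
        rd = self.raspr_.transform(qspr[self.similarity_features_])
        return pd.concat([qspr, rd], axis=1)

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "StackedQRASPR":
        yv = np.asarray(y, float)
        table = self._descriptor_table(X, fit=True, y=yv)
        sets = dict(self.descriptor_sets or QRASPR_DESCRIPTOR_SETS)
        missing = [
            d for cols in sets.values() for d in cols if d not in table.columns
        ]
        if missing:
            raise ConfigurationError(f"descriptor(s) not available: {sorted(set(missing))}")
        self.mlr_models_: dict[str, MlrModel] = {
            name: fit_mlr(table[list(cols)], yv) for name, cols in sets.items()
        }
        self.descriptor_sets_ = sets
        stack = self._stack_matrix(table)
        self.stack_train_ = stack
        if self.stacker == "pls":
            self.stacker_ = PLSRegression(n_components=self.n_lv, scale=True)
            self.stacker_.fit(stack.to_numpy(float), yv)
        elif self.stacker == "mlp":
            params = dict(MLP_STACKER_PARAMS)
            params.update(self.mlp_params or {})
            # the MLP stacker consumes z-scored stack columns
            self.stack_scaler_ = zscore_fit(stack, list(stack.columns))
            self.stacker_ = MLPRegressor(**params)
            self.stacker_.fit(self.stack_scaler_.apply(stack).to_numpy(float), yv)
        else:
            raise ConfigurationError(f"unknown stacker {self.stacker!r}")
        return self

    def _stack_matrix(self, table: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {name: m.predict(table) for name, m in self.mlr_models_.items()},
            index=table.index,
        )

    def mlr_predictions(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-query predictions of the four individual q-RASPR regressions."""
        return self._stack_matrix(self._descriptor_table(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        stack = self.mlr_predictions(X)
        if self.stacker == "pls":
            return self.stacker_.predict(stack.to_numpy(float)).ravel()
        return self.stacker_.predict(self.stack_scaler_.apply(stack).to_numpy(float))
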