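"""Read-across similarity (RASPR) descriptors.

For each query compound, the ``n_close`` most similar training ("source")
compounds under a chosen similarity kernel are located, and a battery of
similarity-weighted descriptors is computed from their observed responses:
the read-across function (similarity-weighted mean response), dispersion
measures of the similarities and responses, and concordance descriptors that
contrast the "positive" and "negative" close sources (positives are sources
whose response is at or above a threshold, by default the training mean).

These descriptors serve both as a standalone read-across prediction
(``ra_function``) and as inputs to the stacked q-RASPR regression models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .features import ScalerParams, zscore_fit

DESCRIPTOR_NAMES = (
    "ra_function", "cvsim", "se", "sd_activity", "sd_similarity",
    "pos_avg_sim", "neg_avg_sim", "max_pos", "max_neg", "sm1", "sm2",
)


@dataclass(frozen=True)
class SimilarityConfig:
    """Kernel choice and read-across hyperparameters.

    kernel: 'euclidean' (s = 1/(1+d)), 'gaussian' (exp(-d^2/(2 sigma^2))),
    or 'laplacian' (exp(-d/sigma)); d is the Euclidean distance on z-scored
    features.  ``n_close`` close source compounds feed the descriptors.
    ``posneg_rule`` sets the positive/negative response threshold: the
    training-set mean response or 0 mV.
    """

    kernel: str = "euclidean"
    sigma: float = 1.0
    n_close: int = 5
    posneg_rule: str = "train_mean"

    def __post_init__(self) -> None:
        if self.kernel not in {"euclidean", "gaussian", "laplacian"}:
            raise ConfigurationError(f"unknown similarity kernel {self.kernel!r}")
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be positive, got {self.sigma}")
        if self.n_close < 1:
            raise ConfigurationError(f"n_close must be >= 1, got {self.n_close}")
        if self.posneg_rule not in {"train_mean", "zero"}:
            raise ConfigurationError(f"unknown posneg_rule {self.posneg_rule!r}")


@dataclass
class CloseSourceSet:
    """The close source compounds of one query, sorted by descending similarity."""

    query_id: str
    source_ids: list[str]
    similarities: np.ndarray
    responses: np.ndarray


def similarity(query: np.ndarray, source: np.ndarray, cfg: SimilarityConfig) -> float:
    """Similarity in (0, 1] between two feature vectors."""
    q, s = np.asarray(query, float), np.asarray(source, float)
    if q.shape != s.shape:
        raise DomainError(f"feature length mismatch: {q.shape} vs {s.shape}")
    d = float(np.linalg.norm(q - s))
    if cfg.kernel == "euclidean":
        return 1.0 / (1.0 + d)
    if cfg.kernel == "gaussian":
        return math.exp(-(d * d) / (2.0 * cfg.sigma ** 2))
    return math.exp(-d / cfg.sigma)


def select_close_sources(
    query: np.ndarray,
    query_id: str,
    sources: pd.DataFrame,
    responses: Sequence[float],
    cfg: SimilarityConfig,
    exclude_id: str | None = None,
) -> CloseSourceSet:
    """Top-``n_close`` sources by similarity; ties broken by ascending id.

    ``exclude_id`` removes the query itself from its source pool when a
    training compound is being cross-predicted (leave-self-out).
    """
    ids = list(sources.index.astype(str))
    y = np.asarray(responses, float)
    keep = [i for i, sid in enumerate(ids) if sid != exclude_id]
    if len(keep) < cfg.n_close:
        raise DomainError(
            f"only {len(keep)} source compounds available, need n_close={cfg.n_close}"
        )
    sims = np.array([
        similarity(query, sources.iloc[i].to_numpy(float), cfg) for i in keep
    ])
    order = sorted(range(len(keep)), key=lambda j: (-sims[j], ids[keep[j]]))
    top = order[: cfg.n_close]
    return CloseSourceSet(
        query_id=query_id,
        source_ids=[ids[keep[j]] for j in top],
        similarities=sims[top],
        responses=y[[keep[j] for j in top]],
    )


def _default_banerjee_roy(
    max_pos: float, max_neg: float, pos_avg: float, neg_avg: float, frac_pos: float
) -> tuple[float, float]:
    # Approximate concordance plug-in: each contrast is damped by the positive
    # fraction so an all-negative neighbourhood contributes 0.  Swappable.
    return (max_pos - max_neg) * frac_pos, (pos_avg - neg_avg) * frac_pos


def raspr_descriptors(
    css: CloseSourceSet,
    train_mean_response: float,
    cfg: SimilarityConfig,
    banerjee_roy: Callable[..., tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Compute the RASPR descriptor vector from one close-source set.

    Weights are the similarities.  The weighted standard deviation of the
    responses about the read-across function uses the reliability-weight
    correction  sum w - sum w^2 / sum w  in the denominator; the similarity
    dispersion (sd_similarity, cvsim) uses the sample standard deviation.
    """
    s = np.asarray(css.similarities, float)
    y = np.asarray(css.responses, float)
    if s.size == 0:
        raise DomainError("empty close-source set")
    w = s / s.sum()
    ra = float(w @ y)
    sd_sim = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    cvsim = sd_sim / float(np.mean(s))
    denom = s.sum() - (s ** 2).sum() / s.sum()
    if denom > 0:
        sd_act = math.sqrt(float(s @ (y - ra) ** 2) / denom)
    else:
        sd_act = 0.0
    se = sd_act / math.sqrt(s.size)
    thr = 0.0 if cfg.posneg_rule == "zero" else train_mean_response
    pos = y >= thr
    frac_pos = float(pos.mean())
    pos_avg = float(s[pos].mean()) if pos.any() else 0.0
    neg_avg = float(s[~pos].mean()) if (~pos).any() else 0.0
    max_pos = float(s[pos].max()) if pos.any() else 0.0
    max_neg = float(s[~pos].max()) if (~pos).any() else 0.0
    sm1, sm2 = (banerjee_roy or _default_banerjee_roy)(
        max_pos, max_neg, pos_avg, neg_avg, frac_pos
    )
    return {
        "ra_function": ra,
        "cvsim": cvsim,
        "se": se,
        "sd_activity": sd_act,
        "sd_similarity": sd_sim,
        "pos_avg_sim": pos_avg,
        "neg_avg_sim": neg_avg,
        "max_pos": max_pos,
        "max_neg": max_neg,
        "sm1": float(sm1),
        "sm2": float(sm2),
    }


class RasprCalculator:
    """Transformer computing RASPR descriptors against a fitted source pool.

    fit(X, y) z-scores the similarity features on the training pool and stores
    the pool; transform(X) returns one descriptor row per query.  Training
    compounds (recognised by index membership in the fitted pool) are
    cross-predicted with themselves excluded from their own source pool, so
    the descriptors are genuine out-of-self predictions on the training set.
    """

    def __init__(self, cfg: SimilarityConfig | None = None):
        self.cfg = cfg or SimilarityConfig()

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "RasprCalculator":
        if len(X) <= self.cfg.n_close:
            raise DomainError(
                f"need more than n_close={self.cfg.n_close} training compounds, got {len(X)}"
            )
        self.columns_ = list(X.columns)
        self.scaler_: ScalerParams = zscore_fit(X, self.columns_)
        self.pool_ = self.scaler_.apply(X)
        self.pool_.index = X.index.astype(str)
        self.y_ = np.asarray(y, float)
        self.train_mean_ = float(self.y_.mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = self.scaler_.apply(X[self.columns_])
        rows = {}
        train_ids = set(self.pool_.index)
        for idx, row in Xs.iterrows():
            qid = str(idx)
            css = select_close_sources(
                row.to_numpy(float), qid, self.pool_, self.y_, self.cfg,
                exclude_id=qid if qid in train_ids else None,
            )
            rows[qid] = raspr_descriptors(css, self.train_mean_, self.cfg)
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index = X.index
        return out

    def fit_transform(self, X: pd.DataFrame, y: Sequence[float]) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def optimize_raspr_hyperparameters(
    X: pd.DataFrame,
    y: Sequence[float],
    grid: Sequence[SimilarityConfig],
    split_seed: int = 0,
    val_fraction: float = 0.25,
) -> SimilarityConfig:
    """Pick the similarity configuration by validation MAE of the RA function.

    The training pool is split into calibration and validation subsets
    (seeded); each candidate configuration predicts the validation responses
    with its read-across function computed from the calibration pool, and the
    configuration with the lowest validation MAE wins (ties: grid order).
    """
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    y = np.asarray(y, float)
    rng = np.random.default_rng(split_seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    if n_val < 2:
        raise DomainError(f"validation set would have {n_val} < 2 compounds")
    val_idx, cal_idx = perm[:n_val], perm[n_val:]
    X_cal, y_cal = X.iloc[cal_idx], y[cal_idx]
    X_val, y_val = X.iloc[val_idx], y[val_idx]
    best, best_mae = None, np.inf
    for cfg in grid:
        calc = RasprCalculator(cfg).fit(X_cal, y_cal)
        pred = calc.transform(X_val)["ra_function"].to_numpy()
        mae = float(np.abs(pred - y_val).mean())
        if mae < best_mae:
            best, best_mae = cfg, mae
    return best
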