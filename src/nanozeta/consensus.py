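"""Consensus combination of aligned per-model predictions.

Two schemes: the simple arithmetic average, and a weighted average whose
weights are the individual models' training-set coefficients of
determination,  y_hat = sum_i (R_i^2 / sum_j R_j^2) y_hat_i .  Both outputs
are convex combinations, hence bounded by the per-row model extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError


@dataclass
class PredictionEnsemble:
    """Aligned per-model predictions plus the training R2 of each model."""

    predictions: pd.DataFrame  # rows = records, columns = models
    train_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.predictions.shape[1] < 2:
            raise ConfigurationError("consensus needs at least 2 model columns")
        if self.predictions.isna().any().any():
            bad = self.predictions.columns[self.predictions.isna().any()].tolist()
            raise DomainError(f"missing predictions in column(s): {bad}")
        extra = set(self.train_r2) - set(self.predictions.columns)
        if extra:
            raise ConfigurationError(f"weights for unknown model(s): {sorted(extra)}")


def consensus_average(pe: PredictionEnsemble) -> pd.Series:
    """Row-wise arithmetic mean of the model predictions (equal weights)."""
    return pe.predictions.mean(axis=1)


def consensus_weighted(pe: PredictionEnsemble, weights: Mapping[str, float] | None = None) -> pd.Series:
    """Training-R2-weighted row-wise average.

    Weights default to the stored per-model training R2 and are invariant to
    a common positive rescaling; they must cover every model column and sum
    to a positive total.
    """
    w = dict(weights) if weights is not None else dict(pe.train_r2)
    missing = [c for c in pe.predictions.columns if c not in w]
    if missing:
        raise ConfigurationError(f"no weight for model(s): {missing}")
    vec = np.array([w[c] for c in pe.predictions.columns], float)
    total = vec.sum()
    if total <= 0:
        raise DomainError("sum of consensus weights must be positive")
    return pd.Series(
        pe.predictions.to_numpy(float) @ (vec / total),
        index=pe.predictions.index,
    )
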