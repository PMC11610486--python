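"""Leverage-based applicability domain.

The leverage of a sample is the corresponding diagonal element of the hat
matrix H = X (X'X)^-1 X' of the training design; for an external query q it
is q' (X'X)^-1 q.  Predictions with leverage below the threshold
h* = 3 p / N (p design columns, N training rows) are interpolative and
flagged reliable; h >= h* is outside the domain (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DomainError, FitError


def leverage_values(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Hat-matrix diagonals of the training design, or query leverages.

    The training leverages sum to p (the trace identity) and each lies in
    [0, 1]; query leverages are unbounded above.
    """
    Xt = np.asarray(X_train, float)
    if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
        raise FitError(
            "X'X is singular: remove collinear/constant design columns before "
            "computing leverages"
        )
    gram_inv = np.linalg.inv(Xt.T @ Xt)
    Xq = Xt if X_query is None else np.asarray(X_query, float)
    return np.einsum("ij,jk,ik->i", Xq, gram_inv, Xq)


def leverage_threshold(p: int, n: int) -> float:
    """Warning leverage h* = 3 p / N."""
    if p < 1 or n < 1:
        raise DomainError(f"p and N must be >= 1, got p={p}, N={n}")
    return 3.0 * p / n


@dataclass
class ADReport:
    """Per-query leverage flags against the 3p/N threshold."""

    threshold: float
    p: int
    n_train: int
    leverages: pd.Series
    flags: pd.Series  # "inside" / "outside"
    design_columns: list[str] = field(default_factory=list)

    @property
    def outside_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == "outside"])


def ad_flags(
    leverages: pd.Series, threshold: float, p: int, n_train: int,
    design_columns: Sequence[str] = (),
) -> ADReport:
    """Classify queries: inside iff h < h* (boundary counts as outside)."""
    flags = pd.Series(
        np.where(leverages < threshold, "inside", "outside"), index=leverages.index
    )
    return ADReport(threshold=threshold, p=p, n_train=n_train,
                    leverages=leverages, flags=flags,
                    design_columns=list(design_columns))


class LeverageAD(BaseEstimator):
    """Applicability-domain checker over a numeric design frame.

    ``p`` is taken from the actual design matrix (no intercept column is
    appended unless the caller's design carries one).  ``fit`` stores the
    Gram inverse and threshold; ``report`` flags arbitrary query frames.
    """

    def fit(self, X: pd.DataFrame) -> "LeverageAD":
        self.columns_ = list(X.columns)
        self.X_train_ = X.to_numpy(float)
        self.p_ = X.shape[1]
        self.n_ = len(X)
        self.threshold_ = leverage_threshold(self.p_, self.n_)
        self.train_leverages_ = pd.Series(leverage_values(self.X_train_), index=X.index)
        return self

    def report(self, X_query: pd.DataFrame | None = None) -> ADReport:
        if X_query is None:
            lev = self.train_leverages_
        else:
            # query categories absent from the training design contribute
            # zero dummies (reindex), matching how the model sees them
            Xq = X_query.reindex(columns=self.columns_, fill_value=0.0)
            lev = pd.Series(
                leverage_values(self.X_train_, Xq.to_numpy(float)),
                index=X_query.index,
            )
        return ad_flags(lev, self.threshold_, self.p_, self.n_, self.columns_)


def williams_export(report: ADReport, residuals: pd.Series) -> pd.DataFrame:
    """Williams-plot table: id, leverage, standardized residual, AD flag."""
    std = residuals.std(ddof=1)
    return pd.DataFrame({
        "id": report.leverages.index,
        "leverage": report.leverages.to_numpy(),
        "std_residual": (residuals / std).reindex(report.leverages.index).to_numpy(),
        "flag": report.flags.to_numpy(),
    })
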