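"""External/internal validation battery for QSPR regression models.

MAE, RMSE, coefficient of determination, the two external explained-variance
variants (training-mean vs test-mean denominators), leave-one-out Q2, the
Golbraikh-Tropsha acceptability checks and Y-randomization (response
scrambling).  All formulas operate on plain arrays so any of the package's
estimators — or an external one — can be audited identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .exceptions import DomainError, FitError


def _check_pair(y, yhat, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise DomainError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_n:
        raise DomainError(f"need at least {min_n} samples, got {y.size}")
    return y, yhat


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> dict[str, float]:
    """MAE, RMSE and R2 (1 - RSS/TSS about the observed mean)."""
    yv, yh = _check_pair(y, yhat)
    resid = yv - yh
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise DomainError("constant observed values: R2 undefined")
    return {
        "mae": float(np.abs(resid).mean()),
        "rmse": float(np.sqrt((resid ** 2).mean())),
        "r2": 1.0 - float((resid ** 2).sum()) / tss,
    }


def external_q2(
    y_test: Sequence[float],
    yhat_test: Sequence[float],
    train_mean: float,
    variant: str = "F1",
) -> float:
    """External explained variance.

    F1 scales the residual sum by the spread of the test observations about
    the *training* mean; F2 uses the test mean (so Q2_F2 equals test R2).
    """
    yv, yh = _check_pair(y_test, yhat_test)
    if variant == "F1":
        denom = float(((yv - train_mean) ** 2).sum())
    elif variant == "F2":
        denom = float(((yv - yv.mean()) ** 2).sum())
    else:
        raise DomainError(f"unknown variant {variant!r}; expected 'F1' or 'F2'")
    if denom == 0:
        raise DomainError("zero denominator in external Q2")
    return 1.0 - float(((yv - yh) ** 2).sum()) / denom


def q2_loo(estimator, X: pd.DataFrame, y: Sequence[float]) -> float:
    """Leave-one-out cross-validated Q2 on the training set.

    Each response is predicted by a clone of the estimator fitted on the
    remaining n-1 compounds; Q2 scales the LOO residuals by the spread about
    the full training mean.
    """
    yv = np.asarray(y, float)
    n = len(X)
    if n < 3:
        raise DomainError(f"LOO needs at least 3 training samples, got {n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            m = clone(estimator).fit(X.iloc[mask], yv[mask])
            preds[i] = float(np.asarray(m.predict(X.iloc[[i]])).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - fold id matters to the caller
            raise FitError(f"LOO fold {i} (id {X.index[i]!r}) failed: {exc}") from exc
    tss = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - float(((yv - preds) ** 2).sum()) / tss


@dataclass
class GTReport:
    """Golbraikh-Tropsha external-validation statistics and pass flags."""

    r2: float
    r0_sq: float
    r0_prime_sq: float
    k: float
    k_prime: float
    ratio: float
    delta: float
    q2_loo: float | None = None
    pass_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())


def golbraikh_tropsha(
    y_test: Sequence[float],
    yhat_test: Sequence[float],
    q2: float | None = None,
) -> GTReport:
    """Golbraikh-Tropsha acceptability battery on test-set predictions.

    r2 is the squared Pearson correlation; k and k' are the through-origin
    slopes of observed-on-predicted and predicted-on-observed; r0^2 / r0'^2
    score those through-origin lines as 1 - RSS/TSS about the respective
    mean.  Acceptance thresholds: r2 > 0.6, Q2 > 0.5 (when supplied),
    (r2 - r0^2)/r2 < 0.1, 0.85 <= k or k' <= 1.15, |r0^2 - r0'^2| < 0.3.
    """
    yv, yh = _check_pair(y_test, yhat_test, min_n=3)
    sum_y2 = float((yv ** 2).sum())
    sum_yh2 = float((yh ** 2).sum())
    if sum_y2 == 0 or sum_yh2 == 0:
        raise DomainError("degenerate input: zero sum of squares")
    r = np.corrcoef(yv, yh)[0, 1]
    r2 = float(r * r)
    k = float((yv @ yh) / sum_yh2)
    k_prime = float((yv @ yh) / sum_y2)
    tss_y = float(((yv - yv.mean()) ** 2).sum())
    tss_yh = float(((yh - yh.mean()) ** 2).sum())
    r0_sq = 1.0 - float(((yv - k * yh) ** 2).sum()) / tss_y
    r0_prime_sq = 1.0 - float(((yh - k_prime * yv) ** 2).sum()) / tss_yh
    ratio = (r2 - r0_sq) / r2 if r2 != 0 else np.inf
    delta = abs(r0_sq - r0_prime_sq)
    flags = {
        "r2_gt_0.6": r2 > 0.6,
        "ratio_lt_0.1": ratio < 0.1,
        "k_or_kprime_in_band": (0.85 <= k <= 1.15) or (0.85 <= k_prime <= 1.15),
        "delta_lt_0.3": delta < 0.3,
    }
    if q2 is not None:
        flags["q2_gt_0.5"] = q2 > 0.5
    return GTReport(r2=r2, r0_sq=r0_sq, r0_prime_sq=r0_prime_sq, k=k,
                    k_prime=k_prime, ratio=ratio, delta=delta, q2_loo=q2,
                    pass_flags=flags)


def y_randomization(
    estimator,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_test: pd.DataFrame,
    y_test: Sequence[float],
    n_iter: int = 10,
    seed: int = 0,
) -> list[float]:
    """Test RMSE after refitting on permuted training responses.

    Only the training responses are scrambled; the test pairs stay intact.
    A real structure-property relationship shows scrambled RMSEs well above
    the unpermuted model's.
    """
    if n_iter < 1:
        raise DomainError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    ytr = np.asarray(y_train, float)
    yte = np.asarray(y_test, float)
    out = []
    for _ in range(n_iter):
        perm = rng.permutation(len(ytr))
        m = clone(estimator).fit(X_train, ytr[perm])
        pred = np.asarray(m.predict(X_test)).ravel()
        out.append(float(np.sqrt(((yte - pred) ** 2).mean())))
    return out


def evaluate_model(
    estimator,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_test: pd.DataFrame,
    y_test: Sequence[float],
    with_loo: bool = True,
) -> dict:
    """Fit-free convenience bundle: the estimator must already be fitted.

    Returns train/test MAE-RMSE-R2, Q2_F1/Q2_F2, the GT report and (optional,
    refit-based) Q2_LOO — the rows of the per-model statistics tables.
    """
    ytr = np.asarray(y_train, float)
    yte = np.asarray(y_test, float)
    pred_tr = np.asarray(estimator.predict(X_train)).ravel()
    pred_te = np.asarray(estimator.predict(X_test)).ravel()
    train = regression_metrics(ytr, pred_tr)
    test = regression_metrics(yte, pred_te)
    q2 = q2_loo(estimator, X_train, ytr) if with_loo else None
    gt = golbraikh_tropsha(yte, pred_te, q2=q2)
    return {
        "train": train,
        "test": test,
        "q2_loo": q2,
        "q2_f1": external_q2(yte, pred_te, float(ytr.mean()), "F1"),
        "q2_f2": external_q2(yte, pred_te, float(ytr.mean()), "F2"),
        "gt": gt,
        "predictions_train": pred_tr,
        "predictions_test": pred_te,
    }
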