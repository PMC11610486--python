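"""End-to-end round-robin orchestration.

Loads or generates the shared table, fits the requested subset of the five
models on the common training partition, runs the validation battery and
leverage applicability domain per model, combines the test predictions into
the two consensus schemes, and renders table-style reports (JSON, CSV or
markdown).  Every number in the bundle is reproducible from the config and
seeds alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ad import LeverageAD, ADReport
from .consensus import PredictionEnsemble, consensus_average, consensus_weighted
from .datasets import NMDataset, apply_split, read_nm_table
from .exceptions import ConfigurationError, NanozetaError
from .features import COATING_GROUPS, group_coating
from .models import (
    AdaBoostZP,
    KNNReadAcross,
    RandomForestZP,
    StackedQRASPR,
    design_frame,
)
from .synthetic import SynthConfig, generate_dataset
from .validation import evaluate_model, regression_metrics, external_q2, golbraikh_tropsha

MODEL_NAMES = ("knn", "random_forest", "adaboost", "stacked_pls", "stacked_mlp")

#: which reported statistics are expected to vary across library versions
IMPLEMENTATION_SENSITIVE = {"random_forest": True, "adaboost": True,
                            "stacked_mlp": True, "knn": False, "stacked_pls": False}


def make_model(name: str):
    """Construct one of the five models with its published configuration."""
    if name == "knn":
        return KNNReadAcross()
    if name == "random_forest":
        return RandomForestZP()
    if name == "adaboost":
        return AdaBoostZP()
    if name == "stacked_pls":
        return StackedQRASPR(stacker="pls", n_lv=1)
    if name == "stacked_mlp":
        return StackedQRASPR(stacker="mlp")
    raise ConfigurationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def ad_design(name: str, X: pd.DataFrame) -> pd.DataFrame:
    """Continuous design columns used for the leverage domain of each model."""
    if name == "knn":
        return X[["Dsph", "DLS", "Noxygen", "A132"]].astype(float)
    if name == "random_forest":
        out = X[["DLS", "Dsph", "MW"]].astype(float).copy()
        groups = [group_coating(v) for v in X["CT"]]
        for g in COATING_GROUPS:
            col = [float(x == g) for x in groups]
            if sum(col) > 0:  # constant-zero dummies would make X'X singular
                out[f"CT={g}"] = col
        return out
    if name == "adaboost":
        return X[["DLS", "Dsph", "A11", "MW"]].astype(float)
    # q-RASPR domains are assessed on the physicochemical similarity space
    from .models import qraspr_feature_frame

    qf = qraspr_feature_frame(X)
    return qf.loc[:, qf.std(ddof=0) > 0]


@dataclass
class RunConfig:
    """One structured config drives the whole round robin."""

    input_path: str | None = None          # CSV/TSV in canonical schema
    synthetic: SynthConfig | None = None   # used when input_path is None
    split_mode: str = "flags"
    split_ratio: float = 0.75
    split_seed: int = 0
    models: Sequence[str] = MODEL_NAMES
    with_loo: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown model(s): {unknown}")
        if not self.models:
            raise ConfigurationError("at least one model is required")


@dataclass
class ReportBundle:
    """Everything the round robin computed, ready to render."""

    per_model: dict[str, dict]
    ad_reports: dict[str, ADReport]
    predictions: pd.DataFrame            # id, split, observed, per-model, consensus
    consensus_stats: dict[str, dict]
    weights: dict[str, float]
    metadata: dict = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)


def _load(cfg: RunConfig) -> NMDataset:
    if cfg.input_path:
        return read_nm_table(cfg.input_path)
    return generate_dataset(cfg.synthetic or SynthConfig())


def run_round_robin(cfg: RunConfig) -> ReportBundle:
    """Execute the full pipeline; any stage failure aborts with its stage name."""
    stage = "load"
    try:
        ds = _load(cfg)
        stage = "split"
        train_ds, test_ds = apply_split(ds, mode=cfg.split_mode,
                                        ratio=cfg.split_ratio, seed=cfg.split_seed)
        X_train, y_train = design_frame(train_ds)
        X_test, y_test = design_frame(test_ds)

        per_model: dict[str, dict] = {}
        ad_reports: dict[str, ADReport] = {}
        preds_test: dict[str, np.ndarray] = {}
        weights: dict[str, float] = {}
        for name in cfg.models:
            stage = f"model:{name}"
            model = make_model(name).fit(X_train, y_train)
            ev = evaluate_model(model, X_train, y_train, X_test, y_test,
                                with_loo=cfg.with_loo)
            per_model[name] = ev
            preds_test[name] = ev["predictions_test"]
            weights[name] = ev["train"]["r2"]
            stage = f"ad:{name}"
            ad = LeverageAD().fit(ad_design(name, X_train))
            ad_reports[name] = ad.report(ad_design(name, X_test))

        notices: list[str] = []
        consensus_stats: dict[str, dict] = {}
        pred_table = pd.DataFrame({"ID": X_test.index, "split": "test",
                                   "zp_observed": y_test.to_numpy()})
        pred_table = pred_table.set_index("ID")
        for name in cfg.models:
            pred_table[name] = preds_test[name]
        if len(cfg.models) >= 2:
            stage = "consensus"
            pe = PredictionEnsemble(
                predictions=pd.DataFrame(preds_test, index=X_test.index),
                train_r2=weights,
            )
            for scheme, series in (
                ("consensus_average", consensus_average(pe)),
                ("consensus_weighted", consensus_weighted(pe)),
            ):
                pred_table[scheme] = series
                stats = regression_metrics(y_test, series.to_numpy())
                stats["q2_f1"] = external_q2(y_test, series.to_numpy(),
                                             float(np.mean(y_train)), "F1")
                stats["q2_f2"] = external_q2(y_test, series.to_numpy(),
                                             float(np.mean(y_train)), "F2")
                stats["gt"] = golbraikh_tropsha(y_test, series.to_numpy())
                consensus_stats[scheme] = stats
        else:
            notices.append(
                "consensus disabled: needs at least 2 models, got "
                f"{list(cfg.models)}"
            )
        # AD flag of the first model, as the headline reliability column
        first = cfg.models[0]
        pred_table["ad_flag"] = ad_reports[first].flags.reindex(pred_table.index)

        metadata = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": __import__("sklearn").__version__,
            "models": list(cfg.models),
            "implementation_sensitive": {
                m: IMPLEMENTATION_SENSITIVE[m] for m in cfg.models
            },
            "split": {"mode": cfg.split_mode, "ratio": cfg.split_ratio,
                      "seed": cfg.split_seed},
            "n_train": len(X_train), "n_test": len(X_test),
            "provenance": ds.provenance,
        }
        return ReportBundle(per_model=per_model, ad_reports=ad_reports,
                            predictions=pred_table.reset_index(),
                            consensus_stats=consensus_stats, weights=weights,
                            metadata=metadata, notices=notices)
    except NanozetaError as exc:
        raise NanozetaError(f"stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_STAT_ROWS = ("MAE", "RMSE", "R2", "Q2_LOO", "Q2_F1", "Q2_F2")


def _stats_table(rb: ReportBundle) -> pd.DataFrame:
    cols: dict[str, dict[str, float]] = {}
    for name, ev in rb.per_model.items():
        cols[name] = {
            "MAE": ev["test"]["mae"], "RMSE": ev["test"]["rmse"],
            "R2": ev["test"]["r2"],
            "Q2_LOO": np.nan if ev["q2_loo"] is None else ev["q2_loo"],
            "Q2_F1": ev["q2_f1"], "Q2_F2": ev["q2_f2"],
        }
    for scheme, stats in rb.consensus_stats.items():
        cols[scheme] = {
            "MAE": stats["mae"], "RMSE": stats["rmse"], "R2": stats["r2"],
            "Q2_LOO": np.nan, "Q2_F1": stats["q2_f1"], "Q2_F2": stats["q2_f2"],
        }
    return pd.DataFrame(cols).reindex(list(_STAT_ROWS))


def _bundle_dict(rb: ReportBundle) -> dict:
    def gt_dict(gt):
        return {"r2": gt.r2, "r0_sq": gt.r0_sq, "r0_prime_sq": gt.r0_prime_sq,
                "k": gt.k, "k_prime": gt.k_prime, "ratio": gt.ratio,
                "delta": gt.delta, "pass": gt.passed}

    out = {"metadata": rb.metadata, "weights": rb.weights,
           "notices": rb.notices, "models": {}, "consensus": {}, "ad": {}}
    for name, ev in rb.per_model.items():
        out["models"][name] = {
            "train": ev["train"], "test": ev["test"], "q2_loo": ev["q2_loo"],
            "q2_f1": ev["q2_f1"], "q2_f2": ev["q2_f2"], "gt": gt_dict(ev["gt"]),
        }
    for scheme, stats in rb.consensus_stats.items():
        out["consensus"][scheme] = {
            k: (gt_dict(v) if k == "gt" else v) for k, v in stats.items()
        }
    for name, ad in rb.ad_reports.items():
        out["ad"][name] = {
            "threshold": ad.threshold, "p": ad.p, "n_train": ad.n_train,
            "outside_ids": ad.outside_ids,
            "leverages": {str(k): float(v) for k, v in ad.leverages.items()},
        }
    return out


def render_report(rb: ReportBundle, fmt: str, outdir: str | Path) -> list[Path]:
    """Write the bundle in the requested format; output is bit-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        p = outdir / "report.json"
        p.write_text(json.dumps(_bundle_dict(rb), indent=2, sort_keys=True,
                                default=float) + "\n")
        written.append(p)
    elif fmt == "csv":
        p = outdir / "statistics.csv"
        _stats_table(rb).to_csv(p, index_label="Statistic")
        written.append(p)
    elif fmt == "markdown":
        t = _stats_table(rb)
        lines = ["| Statistic | " + " | ".join(t.columns) + " |",
                 "|" + "---|" * (len(t.columns) + 1)]
        for row in t.index:
            vals = " | ".join(f"{t.loc[row, c]:.3f}" for c in t.columns)
            lines.append(f"| {row} | {vals} |")
        p = outdir / "report.md"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}")
    q = outdir / "predictions.csv"
    rb.predictions.to_csv(q, index=False)
    written.append(q)
    return written
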