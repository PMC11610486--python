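# nanozeta

Consensus machine-learning prediction of the zeta potential of metal and
metal-oxide nanomaterials in water.

The zeta potential (ZP, mV) — the electric potential at a dispersed
particle's slipping plane — is the standard proxy for colloidal stability
and surface charge, and a key driver of how nanomaterials interact with
membranes. `nanozeta` implements a "round-robin" modelling exercise for this
endpoint: five independent regression models are trained on one shared
71-nanomaterial feature table (chemical formula, equivalent sphere diameter,
shape group, coating, hydrodynamic diameter, molecular weight, Hamaker
constants, atom counts, summed metal ionization potentials) and combined
into consensus predictions:

- **kNN read-across** — inverse-distance-weighted k-nearest neighbours
  (k = 7) with a mixed metric, Euclidean on z-scored numeric descriptors
  plus a unit penalty per categorical mismatch;
- **random forest** and **AdaBoost** — tree ensembles with pinned published
  hyperparameters (128 trees / depth 5 / seed 42; 9 estimators /
  learning-rate 0.997 / seed 786);
- **stacked PLS and MLP q-RASPR** — four multiple linear regressions on
  fused physicochemical + read-across similarity (RASPR) descriptors,
  stacked by a 1-latent-variable PLS or an MLP meta-regressor.

Every model is validated with the full QSAR battery — MAE, RMSE, R², the
external explained variances Q²_F1/Q²_F2, leave-one-out Q², the
Golbraikh–Tropsha through-origin checks, and Y-randomization — and bounded
by a leverage applicability domain (h* = 3p/N). Test predictions are
combined by the simple average and by the R²-weighted average

  ŷ = Σᵢ (Rᵢ² / Σⱼ Rⱼ²) ŷᵢ ,

with Rᵢ² each model's training-set coefficient of determination.

The package is written scikit-learn style: each model is an estimator with
`fit`/`predict` (and fitted attributes like `scaler_`, `mlr_models_`), so
everything composes with sklearn pipelines and model selection. A synthetic
library generator reproduces the statistical structure of measured
nanomaterial panels (product/replicate clustering, material-specific Hamaker
pairs with Pearson r ≈ 0.97, positively skewed hydrodynamic diameters, a
known linear ZP model plus noise) so the whole workflow is testable without
the original measured table; see `docs/methods.md` for the model and
generator details.

## Worked example

```bash
nanozeta run --seed 1 --outdir demo --format markdown
```

generates the default synthetic study library (71 nanomaterials, 53/18
train/test), fits all five models, and writes `demo/report.md`:

| Statistic | knn | random_forest | adaboost | stacked_pls | stacked_mlp | consensus_average | consensus_weighted |
|---|---|---|---|---|---|---|---|
| MAE | 6.320 | 3.648 | 5.564 | 5.034 | 4.592 | 4.113 | 4.067 |
| RMSE | 7.960 | 4.651 | 6.999 | 5.743 | 5.376 | 4.982 | 4.892 |
| R2 | 0.732 | 0.909 | 0.793 | 0.861 | 0.878 | 0.895 | 0.899 |
| Q2_LOO | 0.706 | 0.881 | 0.776 | 0.837 | 0.817 | nan | nan |
| Q2_F1 | 0.743 | 0.912 | 0.801 | 0.866 | 0.883 | 0.899 | 0.903 |
| Q2_F2 | 0.732 | 0.909 | 0.793 | 0.861 | 0.878 | 0.895 | 0.899 |

Rows are test-set statistics (Q2_LOO is the training-set leave-one-out
cross-validation; consensus columns have none because the consensus is not
refitted). The consensus columns beat or match the best individual model on
MAE/RMSE — the point of the exercise. `demo/predictions.csv` holds the
per-nanomaterial observed and predicted ZP for every model plus the
consensus columns and the leverage applicability-domain flag:

```
ID,split,zp_observed,knn,...,consensus_weighted,ad_flag
NM009,test,-45.40,-43.25,...,-45.45,inside
```

The same workflow from Python:

```python
from nanozeta import KNNReadAcross, SynthConfig, generate_dataset, apply_split
from nanozeta.models import design_frame
from nanozeta.validation import evaluate_model

ds = generate_dataset(SynthConfig(seed=1))
train, test = apply_split(ds, mode="flags")
X_tr, y_tr = design_frame(train)
X_te, y_te = design_frame(test)
knn = KNNReadAcross(k=7).fit(X_tr, y_tr)
report = evaluate_model(knn, X_tr, y_tr, X_te, y_te)
print(report["test"])        # {'mae': 6.32, 'rmse': 7.96, 'r2': 0.73}
print(report["gt"].passed)   # True — Golbraikh–Tropsha battery
```

To run on measured data instead, point `--input` at a CSV/TSV in the
canonical schema (`ID, CF, Dsph, Shape, CT, DLS, MW, A11, A132, Nmetal,
Noxygen, Metals_SumIP, ZP, Split`); `read_nm_table` accepts a column map for
other headers.

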