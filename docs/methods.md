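# Methods

`nanozeta` implements a consensus ("round-robin") modelling exercise for the
zeta potential (ZP, mV) of metal and metal-oxide nanomaterials in water: five
independent regression models are trained on one shared feature table and
their test-set predictions are combined by simple and performance-weighted
averaging. This note documents the models, the data model, the synthetic
library generator, and the numerical choices that were genuinely open.

## The shared feature table

Each record is one nanomaterial: core chemical formula (CF), equivalent
sphere diameter Dsph [nm] (diameter of the sphere whose surface area equals
the particle's), shape group (spherical / square plate / rod), coating label
CT (with an `uncoated` sentinel), hydrodynamic diameter DLS [nm], core
molecular weight MW [g/mol], Hamaker constants in vacuum (A11) and in water
(A132) [x 10^-20 J], metal- and oxygen-atom counts, the summed first
ionization potential of the metal atoms [kJ/mol], the measured ZP [mV], and a
train/test flag. Surface-area equivalences: a rod is treated as a closed
cylinder (area pi d L + pi d^2/2), a square plate as a slab (2a^2 + 4at).
Composition descriptors come from a bundled element-property table (IUPAC
atomic weights, CRC first ionization energies, Pauling electronegativities).
"Valence electron potential" is a configurable plug-in (default: valence
electrons per unit atomic number summed over metal atoms); the externally
defined descriptors `tot_metal_alpha` and `X_ActivM` are not computed — no
shipped model needs them.

## The five models

1. **kNN read-across** (`KNNReadAcross`): inverse-distance-weighted k-nearest
   neighbours, k = 7, on z-scored Dsph, DLS, Noxygen, A132 plus categorical
   CT and Shape. The metric is Euclidean on the numeric block plus a unit
   squared-distance penalty per categorical mismatch. A zero-distance
   neighbour short-circuits the weighting: the prediction becomes the mean
   response of the zero-distance neighbours. Training compounds are excluded
   from their own neighbour pool (leave-self-out), so training statistics are
   genuine cross-predictions.
2. **Random forest** (`RandomForestZP`): 128 trees, depth 5, seed 42, on DLS,
   Dsph, MW and the 5-group coating one-hot (sodium citrate, L-arginine,
   PVP, uncoated, other). The near-collinear in-vacuum Hamaker constant
   (Pearson r ~ 0.97 with the in-water one) never enters this recipe; a
   generic correlation filter (default threshold 0.95, preferring to keep
   A132) is available for other designs.
3. **AdaBoost** (`AdaBoostZP`): 9 estimators, learning rate 0.997, seed 786,
   on z-scored DLS, Dsph, A11, MW plus a binary coated(0)/uncoated(1) flag.
4. **Stacked PLS q-RASPR** (`StackedQRASPR(stacker="pls")`): read-across
   similarity (RASPR) descriptors are computed for every compound from its 5
   closest training compounds under the Euclidean-distance kernel
   s = 1/(1+d) on z-scored physicochemical descriptors (A132, Metals_SumIP,
   LOG_DLS = log10 DLS, total atom count, Ce and Zr amounts, rod indicator,
   coating group code). Four six-descriptor ordinary-least-squares models
   (M1-M4, fixed descriptor combinations mixing physicochemical and RASPR
   descriptors) are fitted; their predictions form a 4-column stack on which
   a PLS regression with 1 latent variable is the meta-regressor.
5. **Stacked MLP q-RASPR**: the same stack, with a multilayer perceptron
   meta-regressor (logistic activation, alpha 1, learning-rate 0.01, lbfgs,
   max_iter 1000, seed 0) on z-scored stack columns.

RASPR descriptors per query: the read-across function (similarity-weighted
mean response of the close sources), coefficient of variation and standard
deviation of the similarities, similarity-weighted standard deviation of the
responses about the read-across function (reliability-weight denominator
`sum s - sum s^2 / sum s`), its standard error, and positive/negative
concordance descriptors. "Positive" close sources are those whose response
is at or above a threshold — the training-set mean by default (configurable
to 0 mV), since ZP is a continuous, mostly negative endpoint with no natural
binary activity. The two similarity-concordance coefficients are a
documented plug-in; the default, an approximation,

    sm1 = (MaxPos - MaxNeg) * f_pos,   sm2 = (PosAvgSim - NegAvgSim) * f_pos

(f_pos = fraction of positive close sources), is swappable without touching
callers. Kernel, width, close-source count and the positive/negative rule can
be re-optimized on a calibration/validation split of the training set by
validation MAE of the read-across function (`optimize_raspr_hyperparameters`).

Tree, boosting, MLP and PLS internals are delegated to scikit-learn; the
package's contribution is the distance/descriptor machinery, recipes,
validation and consensus around them. Their statistics are therefore
implementation-sensitive across library versions, which the run report
records; kNN, OLS and PLS are deterministic.

## Validation battery

MAE, RMSE and R2 (1 - RSS/TSS about the observed mean); external explained
variance in both conventions (Q2_F1 with the training-set mean in the
denominator, Q2_F2 with the test-set mean — printed side by side because the
two are easily conflated); leave-one-out Q2 by refitting on each n-1 subset;
the Golbraikh-Tropsha battery (squared Pearson r2; through-origin slopes
k = sum(y yhat)/sum(yhat^2) and k' = sum(y yhat)/sum(y^2); r0^2 and r0'^2
scoring those through-origin lines as 1 - RSS/TSS about the respective mean;
acceptance: r2 > 0.6, Q2 > 0.5, (r2 - r0^2)/r2 < 0.1, k or k' in
[0.85, 1.15], |r0^2 - r0'^2| < 0.3); and Y-randomization (training responses
permuted, model refitted, test RMSE recorded; ten seeded permutations by
default, test pairs untouched).

## Applicability domain

Leverage method: h = diag(X (X'X)^-1 X') for training rows, q'(X'X)^-1 q for
queries, threshold h* = 3p/N with p the number of columns of the actual
design matrix (no intercept column is appended unless the model has one) and
N the training size. h = h* exactly is classified outside (the criterion is
strict h < h*). For the kNN model the AD design is its four continuous
descriptors, giving h* = 3*4/53 = 0.226 at the study sample sizes. For the
random forest the design is the three continuous features plus the coating
dummies present in training — 8 columns when all five groups occur; a
9-column convention for the same recipe would give h* = 0.509 at N = 53, and
the report always states which columns produced p, since p is the only free
choice in this domain definition.

## Consensus

Simple average, and the weighted average
yhat = sum_i (R_i^2 / sum_j R_j^2) yhat_i with weights the individual
models' *training-set* coefficients of determination (goodness-of-fit R2,
not Q2_LOO — switchable). Models flagged outside-AD still contribute by
default; AD-gated consensus is an option. Both schemes are convex
combinations, hence bounded by the per-row model extremes and invariant to a
common rescaling of the weights.

## Synthetic study library

The generator (`SynthConfig` / `generate_dataset`) emulates the structure of
a measured pristine-nanomaterial panel so that every stage is testable
without the measured table. Defaults are the study conditions: 71 records,
flagged 53/18 train/test partition.

- **Product/replicate hierarchy.** 18 distinct products (core material,
  coating, shape, nominal size) are drawn first; records are batch
  replicates with ~12% log-normal size jitter. Measured panels are exactly
  this clustered — near-replicate materials measured under one protocol —
  and the clustering is what makes neighbourhood methods informative at
  n ~ 70.
- **Cores** come from a built-in library of real formulas (Ag, Au, Cu, Pt;
  CeO2, CuO, ZnO, TiO2, Fe3O4, Fe2O3, Al2O3, SiO2, ZrO2, and the doped oxide
  Ce_0.75Zr_0.25O2, whose fractional composition the formula parser handles);
  ~30% of products are pure metals.
- **Coatings** follow the core material (70% its characteristic coating,
  e.g. citrate on noble metals, uncoated oxides; otherwise a class-
  conditional draw over an 8-label vocabulary that collapses to the five
  canonical groups). Material-coating correlation mirrors synthesis practice
  and is what lets tree models infer surface chemistry from MW and size.
- **Sizes**: shape-specific log-normal dimensions; Dsph follows from the
  surface-area equivalence; DLS = Dsph x a log-normal
  solvation/agglomeration factor, so DLS is positively skewed (log10 median
  2.1, sd 0.3) and tracks the geometric size.
- **Hamaker pair**: a per-material van der Waals score drives both
  constants; A132 follows A11 with a construction that hits the configured
  Pearson correlation (default 0.97) exactly in expectation.
- **Response**: ZP = intercept + coating-group effect + metal-core shift +
  slope x log10(DLS) + slope x MW/100 + N(0, noise_sd), defaults
  (-12; citrate -20, arginine +25, PVP +8, other -6; +12; -18; +8;
  noise 3 mV), chosen once to give the spread of measured libraries
  (sd ~ 12-15 mV, range roughly -50 to +25 mV) with size and material
  carrying most of the descriptor-driven variance. The generating
  coefficients and seed are stored in the dataset provenance, and
  `true_design` rebuilds the generating design matrix so parameter-recovery
  tests can verify the pipeline end to end (noise -> 0 recovers the
  coefficients to 1e-6). An optional coating-x-core interaction term
  stresses the nonlinear models.

What the generator does **not** emulate: pH/ionic-strength dependence of ZP,
physics-based (DLVO) coupling between the Hamaker constants and the
response, measurement-protocol artefacts, and real panels' exact coating
vocabulary. Green tests on synthetic data therefore demonstrate that the
machinery is correct and that the workflow behaves as designed under
realistic structure — not that the published per-model statistics are
reproduced; that requires the original measured table (see
`load_reference_dataset`), which cannot be redistributed with the package.

## Numerical choices

- Z-scoring uses the population (divide-by-n) standard deviation, matching
  common ML scaler behaviour; parameters are always fitted on training rows
  and replayed on queries. Zero-variance columns are an error, not a silent
  pass-through.
- LOG_DLS is base-10 (QSAR convention).
- Similarity ties (equal similarity competing for the last close-source
  slot) break by ascending source id; kNN neighbour ties likewise.
- The similarity dispersion (sd_similarity, cvsim) uses the sample standard
  deviation; the response dispersion uses the reliability-weighted formula
  above. Both conventions are held fixed across all models.
- OLS designs are checked for rank; rank-deficient fits fail loudly, naming
  the near-collinear columns via the smallest singular vectors.
- PLS uses autoscaled columns (scikit-learn's convention); with as many
  latent variables as the design rank it reproduces least-squares
  predictions, which the tests exploit as an oracle.
- The MLP stacker can exhaust its 1000 lbfgs iterations on some data; the
  resulting convergence warning is deliberate — the iteration cap is part of
  the pinned configuration.

## Known limitations

- The default similarity-concordance plug-in (sm1/sm2) is an approximation;
  exact coefficient definitions can be injected via the `banerjee_roy`
  argument without changing any caller.
- PLS stacking with 1 latent variable does not dominate the best individual
  model in general — a single latent direction mixes in weaker stack
  columns. At the default study conditions it stays within 10% of the best
  individual test RMSE, and the test suite pins exactly that.
- Leverage-based AD with one-hot dummies is coarse: a query with an unseen
  category maps to an all-zero dummy block rather than an explicit
  out-of-domain verdict.
- Problem sizes in the tests and the acceptance script (n = 71, 10
  Y-randomization permutations, 5-seed medians) are the study conditions,
  kept deliberately small; statistics at these sizes carry visible
  seed-to-seed variance, which the tolerances acknowledge.
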