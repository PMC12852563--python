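# Methods

This note documents the models, parameter choices and numerical conventions
behind `enpkit`, and what the synthetic benchmark can and cannot show.

## Formulation data model

A formulation is five lipid mol% values (CHOL, SM, PC, PE, PS) closed to 100
within 1e-6; quality attributes are size (nm), PDI (dimensionless ≥ 0) and
zeta potential (mV). Datasets are DataFrame-backed with a provenance tag per
record (`experimental`, `gan_synthetic`, `generator_truth`).

Preprocessing chain:

- **Outlier removal.** Per CQA, records outside median ± k·(1.4826·MAD) are
  dropped (k = 3.5 by default; 1.4826·MAD is the normal-consistent robust
  scale). The filter iterates to a fixed point so re-application is a no-op,
  and refuses to drop more than half the original records.
- **Balancing by undersampling.** For a continuous target, "class balancing"
  is interpreted as quantile-bin undersampling: records are binned into
  equal-count quantile bins of one CQA (default size, 10 bins) and every bin
  is randomly downsampled to the smallest bin's count. Binning never splits
  tied values (each distinct value goes to the bin of its mean ordinal rank),
  which makes the operation exactly idempotent on distinct-valued data.
- **Split.** Train size is round(n·frac) exactly; optional stratification on
  CQA quantile bins uses largest-remainder allocation, so each bin's train
  share matches the fraction within one record. 17,800 records at 70/30 give
  12,460/5,340.

## Synthetic cohort and ground-truth map

The generator emulates a formulation campaign concentrated in the
cholesterol-rich region observed for high-performing ENPs: compositions are
drawn from a Dirichlet with mean (0.46, 0.12, 0.18, 0.14, 0.10) in
(CHOL, SM, PC, PE, PS) order and concentration 60, giving per-component
spreads of roughly 4–7 mol%.

The truth map is centred so the reference composition (46, 12, 18, 14, 10)
yields exactly (120 nm, 0.15, −35 mV):

- size = 120 − 1.2·(pc−18) + 0.8·(chol−46) + 0.05·(pe−14)²
- pdi = max(0.15 − 0.008·(pc−18) + 0.0004·(sm−12)², 0.01)
- zeta = −35 − 0.9·(ps−10) − 0.55·(pc−18) − 0.03·(ps−10)·(pc−18)

Every PC coefficient is positive and enters negatively, so PC's marginal
effect on all three CQAs is negative by construction — the sign structure the
downstream correlation analysis must recover. The PE/SM quadratic terms and
the PS×PC interaction make the map genuinely nonlinear, so a linear baseline
is beatable. Measurement noise is Gaussian with sd 2 nm / 0.01 / 1 mV.

Effect sizes were chosen once so that (a) the signal-to-noise ratio leaves a
correlation ceiling of roughly 0.97 per CQA — high predictive accuracy is
attainable but not trivial — and (b) the population stays in the physically
sensible bands (size ≈ 120 ± 10 nm, PDI mostly < 0.2, zeta centred at
−35 mV with ~95% of records in −43…−27 mV). These two goals trade off
directly for zeta: with 1 mV noise, a signal tight enough to keep ~95% of
records strictly inside −40…−30 mV cannot support correlations above ~0.92,
so the wider band was accepted.

What the generator does *not* emulate: batch effects, instrument drift,
heteroscedastic noise, compositional measurement error, or any cell-biology
readout. Passing tests show the pipeline recovers structure it was built to
contain; they say nothing about uptake biology.

## LipidGAN

Generator latent_dim=8 → two hidden layers of 64 (leaky-ReLU 0.2) → 5 logits
→ softmax, so every sample lies exactly on the simplex. Discriminator mirrors
the generator. Non-saturating adversarial losses, Adam (lr 1e-3, β₁ 0.5),
batch 32, default 4,000 epochs over the source compositions on the 0–1
fraction scale. Training is deterministic end-to-end from one seed and
resumable (optimizer and RNG state are part of the checkpoint), and a
non-finite loss aborts with the epoch index.

Adversarial dynamics on a 225-row table cycle around the equilibrium rather
than settling; on some seeds the raw generator's marginal means drift by
several mol%. Sampling therefore uses an exponential moving average of the
generator weights (decay 0.999), a standard stabilization that reduces the
drift to ~0.3 mol% without touching the adversarial objective.

Fidelity is measured marginal-by-marginal: both samples are sorted, the
longer resampled to the shorter's length by linear quantile interpolation,
and MAE/RMSE computed on fractions; the pooled R is the Pearson correlation
of the paired quantiles concatenated across the five components. If either
side has no within-component spread the correlation is reported as a
degenerate flag rather than a number.

Known limitation: the generator mildly compresses the tails of the design
space, so models trained purely on GAN output lose some accuracy at extreme
compositions. Augmentation is therefore evaluated (and recommended) as
source ∪ synthetic.

## Hybrid boosted regressor

One ensemble per CQA behind a single facade; features are fractions (mol%
divided by 100), targets are raw CQA values. Each ensemble starts at the
training mean F₀ and adds stages F_n = F_{n-1} + y_n·W_n(x, E_n), where W_n
is a depth-unbounded regression tree (min 8 samples per leaf) fit to the
current residuals under the current sample weights.

Training runs in epochs (default 10) of 50 stages each; the study-scale
schedule (1,000 × 500) is a config value. Within an epoch each stage is
applied with the provisional multiplier `learning_rate` (0.02). At the epoch
boundary:

1. stage weights y_n = (RMSE_n − RMSE_min)/(RMSE_max − RMSE_min) are computed
   over the epoch's stage RMSEs (all-equal RMSEs give all zeros by
   convention);
2. the applied multiplier becomes learning_rate · w(y_n) with
   w = 1 − y_n (default "inverted"), w = y_n ("as_printed") or w = 1
   ("uniform" — plain least-squares gradient boosting, used as the oracle
   bridge to reference implementations);
3. sample weights are reset to 1 + |residual|/max|residual| (normalized to
   mean 1), so hard records get up to double weight in the next epoch.

The raw y_n is stored on every stage alongside the applied multiplier. The
"inverted" default exists because the printed ranking rewards the
worst-fitting stage; down-weighting it is what makes the epoch-level
re-weighting an accuracy refinement, and the per-epoch training RMSE is
checked to be non-increasing in this mode. The feature equation E_n is
recorded per stage (split-gain importances, plus the signed difference of
mean stage predictions over each feature's top vs bottom quartile) and
aggregated over stages weighted by applied multiplier; E_n does not feed back
into subsequent splits.

Determinism: tree seeds derive from the config seed; the three per-CQA
ensembles are independent (parallelizable by contract). Checkpoints serialize
trees as node arrays and reload into a vectorized predictor, preserving
predictions to floating tolerance.

## Evaluation conventions

- `eq10` is the Pearson correlation between prediction and observation;
  `eq10_sq` its square. Performance claims quote `eq10`. Zero variance on
  either side flags the value undefined.
- Residual analysis reports mean, skewness, a binomial sign test, and an
  unbiasedness flag (|mean| within two standard errors of zero).
- ROC classes: a record is "high accuracy" when |residual| ≤ τ, default τ =
  median |residual| (guaranteeing both classes are non-empty for continuous
  residuals); the default confidence score is the negative across-stage
  prediction spread. AUC is trapezoidal.
- MCCV repeats a stratified split (size-nm deciles) and retrains from
  scratch; the per-iteration error ε_i is the mean over CQAs of blind RMSE
  after min–max scaling each CQA by its training-set range, so ε is
  unit-free. ε_MCCV is the mean of the ε_i.
- Ablation baselines (MLR, RBF-SVR with standardization, random forest,
  XGBoost) run with library defaults and a fixed seed on the identical split;
  a failing baseline is marked skipped, never fatal.

## Ranking

Identity-line distance is |pred − obs|/√2 per CQA. The pooled distance
divides each CQA's distance by that CQA's blind RMSE (unit-free) before the
Euclidean pool; ties break by record order. Re-ranking divides the pooled
distance by a reliability factor 1/(1 + normalized stage-prediction spread),
so among near-equidistant candidates the ensemble's most internally
consistent predictions win; membership of the top-k never changes. The
CMA–CQA matrix is plain Pearson; the "rmse_normalized" mode multiplies each
CQA column by (1 − blind RMSE/range), which shrinks poorly predicted columns
without changing signs. Cell-line profiles add a compositional affinity
penalty (weighted |fraction − target|) to express per-cell-line preferences;
physicochemical CQAs alone cannot encode cell specificity, so these profiles
are declarative inputs, not predictions.

## Assembly physics

CPP classification is total and deterministic: theoretical boundaries
{1/3, 1 ± 0.05}, empirical boundaries {0.5, 1 ± 0.05}, boundary values
belonging to the lower class. The closed-sphere Helfrich energy
2πκ(2 − c₀R)² + 4πκ̄ reduces to the classical 8πκ + 4πκ̄ at c₀ = 0 and is
cross-checked against numerical surface integration. The Gibbs model uses a
saturating entropy term s·(1 − exp(−R/R_sat)) — an explicit construction, not
a fitted thermodynamic model — with defaults κ = 20 kT, κ̄ = −15 kT,
c₀ = 2/60 nm⁻¹, s = 1 kT, R_sat = 20 nm chosen so the free-energy minimum
sits at a ~120 nm vesicle diameter; with s = 0 the minimum is exactly
R = 2/c₀. The equilibrium search is a 512-point grid scan refined by bounded
scalar minimization to 0.01 nm, with a boundary flag when the minimum is not
interior. Line tension γ is carried in the parameters as the reason open
disks close into vesicles, but open-edge geometries are out of scope. No
per-lipid V/a₀/l_c table ships as ground truth; geometry values are inputs.

## Problem sizes

Desk-scale defaults — 225-record cohort, 4,000 GAN epochs, 2,000 augmented
records, 10×50 boosting stages, 10 MCCV iterations — run the full loop in a
few minutes on one CPU and are the sizes used throughout the test suite. The
study-scale configuration (17,800 records, 1,000×500 stages, 100 iterations)
is available via config and changes no code path.
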