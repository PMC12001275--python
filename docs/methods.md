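# Methods

## Model

The package implements amortized variational inference for nonlinear
mixed-effects PK models. For patient *i* with covariates `x_i`, dose
regimen `d_i` and concentrations `y_i(t)`:

1. **Structural model.** A compartmental ODE system with parameter vector
   `theta_i` predicts concentrations `yhat_i(t)`. Doses always enter
   compartment 1 (bolus additions for oral doses, zero-order input over the
   infusion duration for IV), and the initial state is zero.
2. **IIV map.** `theta_k,i = TV_k * exp(eta_k,i)` for the IIV set `K`,
   `theta_k,i = TV_k` otherwise. The construction keeps every parameter
   positive for any finite `eta`. A subset `L` of typical values is learned
   in the log domain; the complement is fixed.
3. **Amortized posterior.** An encoder network emits `mu` and
   `log sigma^2` per `k` in `K` — a diagonal Gaussian posterior per
   patient (per measurement for 5FU, see below).
4. **Objective.** Negative ELBO with the reparametrization trick: the
   proportional-error Gaussian reconstruction term plus the closed-form KL
   to the `N(0, lambda^2)` prior, averaged over sample units. One Monte
   Carlo draw of `eta` per unit per step.

Prediction uses posterior means (the expected value of `eta`), no residual
noise. Simulation draws `eta` either from each unit's posterior or from the
prior, with optional proportional residual error.

### Structural systems

**5FU** (IV infusion, one compartment): `dA/dt = D/IT - (CL/V) A`. The
half-life under typical values (~0.14 h) is far shorter than the 24 h
infusion, so samples drawn 16.8-25.0 h after the start are at steady state
`C_ss = D/(IT*CL)`, independent of `V`. `V` is therefore structurally
non-identifiable from these data and stays fixed at 46.1 L without IIV;
only `CL` is learned with IIV.

**Sunitinib** (oral, parent + metabolite, five states): gut, parent
central/peripheral, metabolite central/peripheral. Hepatic first pass is a
well-stirred construct: the liver-inflow concentration
`C_LIV = (KA*A1 + (QH/V2S)*A2)/(QH + CLS)` drives both parent elimination
(`CLS*C_LIV`) and presystemic metabolite formation (`FM*CLS*C_LIV`). This
is the only dimensionally consistent arrangement of the named quantities
that yields hepatic extraction plus presystemic metabolite formation.
States are treated as amounts (mg) because every transfer term divides a
clearance by a volume; observed concentrations map to the central
compartments: parent `1000*A2/V2S`, metabolite `1000*A4/V2M` (ng/mL).
Which measured matrix corresponds to which compartment concentration is an
assumption (the central-compartment map is the field's standard choice).
Flows `{CLS, QS, CLM, QM, QH}` scale allometrically by `(weight/70)^0.75`
and volumes `{V2S, V3S, V2M, V3M}` by `weight/70`; `QH` keeps its fixed
typical value (standard liver blood flow, 80 L/h) and is then scaled per
patient like the other flows.

### Solvers

Both systems are linear and time-invariant between dose events. The
default path is therefore exact: the scalar exponential solution per
infusion segment for 5FU, and `expm(M * dt)` propagation for sunitinib
(with the matrix exponential cached per distinct inter-event gap, so a
daily regimen costs one decomposition). `method="ivp"` switches to
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-8 / atol 1e-10, restarted at
every dose event) — this is the independent numerical contract; tests
require agreement below 1e-6 relative. Negative amounts beyond tolerance
raise.

### Encoders

*5FU*: every steady-state measurement is its own sample. Input is
`[concentration, dose, weight, LBM, FM, BSA, age, sex, height]`
standardized with statistics computed on training folds only, missing
slots zero-filled after normalization, and the binary mask appended
(mask-concatenation). Trunk 2x64, SiLU, dropout 0.1 in training; two
projection heads (one hidden layer of 64) emit `mu` and `log sigma^2` for
`K = {CL}`. The log-variance head's output bias starts at -2 so posteriors
begin tighter than the prior.

*Sunitinib*: a static block (covariates + mask, 2x64) and a recurrent
block over the trough sequence, concatenated and fed to two projection
heads emitting 4 + 4 outputs for `K = {CLS, V2S, FM, V2M}`. The recurrent
cell is an LSTM with a single multiplicative time gate
`T = exp(-softplus(w) * dt)` applied to the carried cell state: at `dt = 0`
the gate is exactly neutral (plain LSTM), and longer gaps discount older
memory. Elapsed times are scaled by their training mean. Sequence inputs
are the standardized `(parent, metabolite)` pair per trough; dosing history
enters only through the structural model, not the encoder.

Per-measurement 5FU encoding means the encoder sees the measurement it is
later asked to predict — mirrored from the study design this package
emulates, and the reason cross-validated errors sit far below the residual
noise. A leave-measurement-out mode (`mode="loo"` in
`predict_individual`/`run_cv`) provides honest predictive error: each
target is predicted from the patient's *other* measurements (typical-value
prediction when there are none).

### Loss and residual-error model

`reconstruction_nll` is the proportional-error weighted SSE
`sum (y - yhat)^2 / (2 eps^2)`. Two error models are available:
`prop_to_pred` (`eps = b * yhat`, default) and `prop_to_obs`
(`eps^2 = b^2 * y`). When `b` is learned (the default, log domain,
initialized at 0.2), the Gaussian normalization term `sum log eps` is added
to the training objective — without it the weighted SSE is degenerate in
`b` — and reported as a separate part of the loss decomposition
(`reconstruction + kl + lognorm = total`).

`prop_to_pred` is the default for two reasons: it is scale-invariant
(independent of concentration units), and at the exact variational optimum
its clearance bias is small (about -1%; the weighting and Jensen effects
nearly cancel), whereas the observation-weighted variant carries a
`+3 sigma^2/2` inflation of recovered clearances (~+8% at this noise
level). Both statements were verified by solving the per-observation
variational problem to machine precision.

### Identifiability and re-centering

The likelihood is invariant under `(TV_k, mu_k) -> (TV_k e^m, mu_k - m)`
for learned TVs with IIV; only the KL term selects the point `mean(mu) = 0`
on this manifold, and first-order descent along it is slow. Training
therefore re-centers exactly every `center_every` (default 50) epochs and
once after training: the training-set mean of `mu_k` is folded into `TV_k`
and subtracted from the `mu` head's output bias. Predictions are unchanged;
the reported typical values become the KL-optimal representative.

### Optimization

Full-batch Adam (lr 1e-3, global gradient-norm clip 1.0), up to 2000
epochs by default. Early stopping monitors a 10% patient-level validation
split (posterior means, no sampling) every 10 epochs with patience 30
checks, restoring the best state; setting `val_fraction=0` disables it
(used in the scripted experiments, which fix the epoch budget instead).
All randomness (weight init, eta draws, dropout, splits) derives from the
single seed passed to `fit`; identical seed and data give identical
results. Sunitinib gradients flow through the ODE solution via one-sided
finite differences (relative step 1e-6) on the differentiable parameter
subset, wrapped as a custom autodiff op; everything else is exact
reverse-mode. `FM` is clamped below 1 in the forward solve because a wide
early-training `eta` draw can push `TV_FM * exp(eta)` past its (0,1)
domain; the log-normal IIV law on a bounded fraction is kept as-is
otherwise, a known tension documented rather than re-modeled.

## Evaluation

`compute_metrics` gives MAE and RMSE; aggregation is mean ± sample SD
(n-1), by default across all fold-level values (per-repeat averaging
available). `pcvpc` applies the standard prediction correction
`pcY = Y * median(PRED in bin)/PRED` with `PRED` the typical-value
(`eta = 0`) prediction, to observed data and to every simulated replicate,
then compares observed 5/50/95 percentiles per bin with the 90% interval
of the same statistic across replicates. Binning defaults: a single
steady-state bin for 5FU (all samples fall in a narrow window after
infusion start), eight equal-count time bins for sunitinib. Empty bins are
dropped with a warning. `run_cv` performs repeated patient-stratified
k-fold CV (default 10x5, 80/20): weight imputation (train-set mean by sex)
and input normalization are computed inside each fold from training
patients only; fold seeds derive from the master seed.

## Synthetic cohorts

The 5FU generator draws sex (male fraction 96/156), BSA (truncated normal,
median 1.915 on [1.35, 2.85]), height by sex, weight from BSA and height by
inverting Du Bois, LBM by the James formula and FM as the remainder —
choices made once as plausible for an oncology TDM population, since the
body-composition derivations of the emulated study are not documented.
Doses are weekly 24 h infusions at 2000 or 2600 mg/m^2 (probabilities
0.6/0.4), rounded to 10 mg and clipped to [2700, 5720] mg; each sample is
its own weekly occasion with constant clearance (no inter-occasion
variability). True clearance is `(TV_CL + slope*(BSA - median)) * exp(eta)`
with `TV_CL = 223 L/h`, `omega = 0.3`, BSA slope 80 L/h per m^2, and
observations add proportional noise (`b = 0.2`) to the steady-state closed
form — computed by the structural module itself, never re-derived.
Samples per patient follow a 1-9 distribution with median 3.

The sunitinib generator uses daily 37.5 or 50 mg boluses on the
4-on/2-off schedule for 2-3 cycles, trough samples 0.5 h before intake on
randomly chosen on-treatment days (1-14 per patient, median ~6.5),
log-normal IIV on `{CLS, V2S, FM, V2M}` (SDs 0.35/0.30/0.25/0.30),
allometric scaling by the true weight, per-analyte proportional noise
(0.2), covariate missingness at rates 12.9/10.9/6.6% (weight/height/BSA)
and a 0.06 ng/mL BLQ flag. Typical values: `KA = 0.13 1/h` and
`V2S = 1820 L` follow the published model this structure derives from; the
remaining entries are implementer defaults chosen for physiological
plausibility and are overridable.

What the generators do *not* emulate: assay rounding, time-varying
covariates, adherence gaps, dose adjustments, correlated IIV, and
inter-occasion variability. Passing tests therefore demonstrate correct
inference under the stated generative assumptions, not performance on real
clinical data.

Two deterministic fixtures (fixed internal seeds, byte-identical across
calls) reproduce the preprocessing bookkeeping of the emulated studies:
157 patients / 549 observations with exactly 8 implausible entries on 8
distinct patients (4 BLQ at 0.03 mg/L, 4 with implied clearance 1900 L/h;
one BLQ entry is its patient's only sample, so that patient drops out),
and 47 patients / 308 paired observations with 6 BLQ parent samples
(0.04 ng/mL) on 5 patients. Violation values sit far from the thresholds
to avoid rounding ambiguity.

## Experiment sizes

The scripted experiments use problem sizes chosen to make each effect
measurable while keeping a full run in the minutes range on one CPU:
parameter recovery on 150 patients (80/20 split, 1500 epochs, TV started
at 150 L/h); cross-validation with 1x5 folds at 800 epochs; pcVPC
calibration over 20 simulate-fit-check seeds with 60-patient cohorts, 600
epochs and 500 replicates. The sunitinib fit demonstrations use ~10
patients and tens of epochs; the mechanism (FD gradients through the
matrix-exponential solve) is identical at larger sizes, only slower.

## Known limitations

* Per-parameter diagonal posteriors; no correlated IIV block.
* `lambda` is a fixed prior scale, not a learned population SD; prior-mode
  simulation spread reflects `lambda`, not the fitted cohort's IIV.
* The MC-sampled ELBO with multiplicative random effects carries small
  systematic offsets in recovered typical values (error-model dependent,
  ~1-2% under the default); see the error-model discussion above.
* Sunitinib ODE gradients are finite-difference (1e-6 relative), so
  extremely tight optimization tolerances are not meaningful there.
* No inter-occasion variability, lag times, transit absorption or
  enterohepatic recirculation.
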