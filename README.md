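# mmpk

Mechanistic mixed-effects pharmacokinetic (PK) modeling in which a neural
encoder learns each patient's random effects from their covariates and
concentration history, while a compartmental ODE system supplies the drug
disposition. The package is aimed at pharmacometricians and ML researchers
who want population-PK structure (typical values, inter-individual
variability, proportional residual error) without hand-specifying covariate
relationships: the encoder infers them from data.

## The model

Individual PK parameters follow the classical log-normal IIV construction

```
theta_k,i = TV_k * exp(eta_k,i)   for k in K (parameters with IIV)
theta_k,i = TV_k                  otherwise,
```

where `TV_k` are population typical values (a learned subset, the rest
fixed) and `eta_k,i` is patient *i*'s random effect. An encoder network
`phi` maps patient data to a diagonal Gaussian posterior per random effect,

```
{ mu_k,i, log sigma^2_k,i } = phi(x_i, y_i(t)),
```

and training minimizes the negative evidence lower bound with the
reparametrization trick (`eta = mu + sigma * z`, `z ~ N(0,1)`):

```
loss = mean_i [ sum_t (y_it - yhat_it)^2 / (2 eps_it^2)        # reconstruction
              + sum_k KL( N(mu_k,i, sigma^2_k,i) || N(0, lambda^2) ) ]
```

with proportional residual error (`eps = b * yhat` by default) and prior
scale `lambda`. Predictions use the posterior means — no sampling.

Two study designs are built in:

* **5FU (fluorouracil)** — steady-state 24 h IV infusions. One-compartment
  model `dA/dt = D/IT - (CL/V) A`; at steady state the concentration is
  `D/(IT*CL)`, independent of `V` (so `V` is fixed at 46.1 L and only `CL`
  carries IIV). Each steady-state measurement is treated as its own sample;
  the encoder reads `[concentration, dose, weight, LBM, FM, BSA, age, sex,
  height]` plus a missing-data mask.
* **Sunitinib** — daily oral dosing, 4 weeks on / 2 off, trough sampling,
  paired parent/metabolite observations. Five-state linear system with a
  well-stirred hepatic first-pass construct
  (`C_LIV = (KA*A1 + (QH/V2S)*A2)/(QH + CLS)`), IIV on
  `{CLS, V2S, FM, V2M}`, and allometric scaling (flows by `(wt/70)^0.75`,
  volumes by `wt/70`). The encoder combines a static-covariate block with a
  time-gated LSTM over the `(gap, parent, metabolite)` sequence.

Both systems are linear time-invariant between dose events, so the default
solver uses exact piecewise closed forms (scalar/matrix exponentials); a
`solve_ivp` path provides an independent numerical cross-check. The neural
components run on a small, fully-tested reverse-mode autodiff engine in
numpy; gradients pass through the ODE solution via finite-difference
vector-Jacobian products.

Synthetic-cohort generators emulate both study designs with known ground
truth (including covariate missingness, BLQ floors, BSA-dosed regimens),
and deterministic fixtures reproduce the exclusion-filter bookkeeping of
the motivating datasets (549 obs/157 patients -> 541/156 for 5FU;
308 paired obs/47 patients -> 302 of each analyte for sunitinib).

## Worked example

```python
from mmpk import CohortConfig5FU, generate_5fu_cohort, fit, split_cv
from mmpk.population import PopulationParameterSet
from mmpk.training import TrainConfig, posterior_stats_fu5

ds, truth = generate_5fu_cohort(CohortConfig5FU(n_patients=150), seed=11)
split = split_cv(ds, 1, 5, seed=7)[0]
pop = PopulationParameterSet("fu5", {"CL": 150.0, "V": 46.1}, {"CL"}, {"CL"})
result = fit(ds.subset(split.train_patient_ids), "fu5",
             TrainConfig(epochs=1500, val_fraction=0.0), seed=2, popset=pop)
print(result.popset.tv["CL"], result.popset.error_b)
```

Running `python examples/03_fit_and_recover.py` (this exact experiment)
prints:

```
recovered TV_CL : 236.7 L/h  (truth 223)
recovered b     : 0.181       (truth 0.2)
held-out Pearson r(true eta, posterior mean): 0.870
```

The typical clearance starts at 150 L/h and is recovered within ~6% of the
generating value; the residual-error coefficient is recovered near 0.2; and
on patients never seen in training, the posterior-mean random effects
correlate with the true ones at r ≈ 0.87 — the encoder has learned to read
individual clearance from covariates and measurements. The other examples
cover filtering bookkeeping (`01`), the structural models and their closed
forms (`02`), pcVPC calibration (`04`), cross-validated predictive error
(`05`), and a small sunitinib fit (`06`).

A thin CLI wraps the same library calls:

```
mmpk synth --scenario fixture-fu5 --out raw.csv
mmpk data filter --drug fu5 --in raw.csv --out filtered.csv --report report.json
mmpk fit --drug fu5 --train filtered.csv --seed 1 --out ckpt.json
```

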