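"""Variational training: negative-ELBO loss, reparametrized sampling, fit loop.

The loss for a batch is the mean over sample units (measurements for 5FU,
patients for sunitinib) of

    reconstruction_nll + kl_weight * sum_k KL(q_k || N(0, lambda^2))

with q_k = N(mu_k, sigma_k^2) emitted by the encoder and eta sampled via
the reparametrization trick.  The reconstruction term is the proportional
squared error (y - yhat)^2 / (2 eps^2); when the residual coefficient b is
learned, the Gaussian normalization term sum log(eps) is added to the
objective (without it, the proportional-error weighted SSE is degenerate
in b), reported separately in the loss decomposition.

5FU predictions use the steady-state closed form D/(IT*CL) end-to-end in
the autodiff graph; sunitinib predictions pass through the matrix-
exponential ODE solution with a finite-difference vector-Jacobian product.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from mmpk.autodiff import Tensor, Parameter, Adam, custom_op, concat
from mmpk.data import Dataset, governing_dose
from mmpk.encoder import Encoder5FU, EncoderSunitinib, EncoderConfig
from mmpk.odes import ThetaSunitinib, model_spec, solve_profile, \
    REFERENCE_WEIGHT, ALLOMETRIC_FLOW_EXP
from mmpk.population import PopulationParameterSet, default_popset, \
    theta_from_params

_SUN_ORDER = ("KA", "FM", "CLS", "QS", "CLM", "QM", "QH",
              "V2S", "V3S", "V2M", "V3M")
_SUN_FLOWS = {"CLS", "QS", "CLM", "QM", "QH"}
_SUN_VOLS = {"V2S", "V3S", "V2M", "V3M"}


@dataclass
class LossConfig:
    error_model: str = "prop_to_pred"   # eps = b*yhat; "prop_to_obs": eps^2 = b^2*y
    learn_b: bool = True
    kl_weight: float = 1.0
    n_mc: int = 1                       # MC samples of eta per unit per step

    def __post_init__(self):
        if self.error_model not in ("prop_to_pred", "prop_to_obs"):
            raise ValueError(f"unknown error model {self.error_model!r}")


@dataclass
class TrainConfig:
    epochs: int = 2000
    lr: float = 1e-3
    clip_norm: float = 1.0
    val_fraction: float = 0.1
    check_every: int = 10
    patience: int = 30                  # checks without val improvement
    center_every: int = 50              # epochs between invariant re-centerings
    loss: LossConfig = field(default_factory=LossConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fd_rel_step: float = 1e-6           # ODE-gradient finite-difference step


@dataclass
class FitResult:
    drug_type: str
    encoder: object
    popset: PopulationParameterSet
    loss_trajectory: list
    decomposition: dict
    seed: int
    config: TrainConfig

    def save(self, path):
        d = {"drug_type": self.drug_type, "encoder": self.encoder.to_dict(),
             "popset": self.popset.to_dict(),
             "loss_trajectory": self.loss_trajectory,
             "decomposition": self.decomposition, "seed": self.seed}
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def load(cls, path):
        from mmpk.encoder import load_encoder
        with open(path) as fh:
            d = json.load(fh)
        if d["drug_type"] == "fu5":
            enc = Encoder5FU.from_dict(d["encoder"])
        else:
            enc = EncoderSunitinib.from_dict(d["encoder"])
        return cls(d["drug_type"], enc,
                   PopulationParameterSet.from_dict(d["popset"]),
                   d["loss_trajectory"], d["decomposition"], d["seed"],
                   TrainConfig())


# ---------------------------------------------------------------------------
# loss primitives

def kl_gaussian(mu, sigma2, lambda2):
    """KL( N(mu, sigma2) || N(0, lambda2) ), elementwise.

    = 1/2 * (sigma2/lambda2 + mu^2/lambda2 - 1 + log(lambda2/sigma2)), >= 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0) or lambda2 <= 0:
        raise ValueError("variances must be strictly positive")
    return 0.5 * (sigma2 / lambda2 + mu ** 2 / lambda2 - 1.0
                  + np.log(lambda2 / sigma2))


def _kl_tensor(mu, log_var, lambda2):
    sigma2 = log_var.exp()
    return (sigma2 * (1.0 / lambda2) + mu * mu * (1.0 / lambda2) - 1.0
            + math.log(lambda2) - log_var) * 0.5


def reconstruction_nll(y, yhat, cfg=None, b=0.2):
    """Proportional-error weighted SSE: sum (y - yhat)^2 / (2 eps^2)."""
    error_model = cfg.error_model if cfg is not None else "prop_to_pred"
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted shapes must match")
    if error_model == "prop_to_pred":
        if np.any(yhat <= 0):
            raise ValueError("predictions must be > 0 under prop_to_pred")
        eps2 = (b * yhat) ** 2
    else:
        eps2 = b ** 2 * y
    return float(((y - yhat) ** 2 / (2.0 * eps2)).sum())


def _recon_tensor(y, yhat, b, error_model):
    """Tensor reconstruction term and (optional) log-normalization term."""
    yv = Tensor(np.asarray(y, dtype=float))
    if error_model == "prop_to_pred":
        eps2 = (b * yhat) ** 2
        lognorm = (b * yhat).log().sum()
    else:
        eps2 = b * b * Tensor(np.asarray(y, dtype=float))
        lognorm = eps2.log().sum() * 0.5
    recon = ((yv - yhat) ** 2 / (eps2 * 2.0)).sum()
    return recon, lognorm


# ---------------------------------------------------------------------------
# feature assembly

def fu5_sample_table(ds):
    """Flatten a 5FU dataset to per-measurement rows.

    Returns features (N,9), mask (N,9), dose (N,), duration (N,), y (N,),
    patient ids (N,).  Feature order: concentration, dose, weight, LBM, FM,
    BSA, age, sex, height.
    """
    cov_order = ("weight", "lbm", "fm", "bsa", "age", "sex", "height")
    feats, masks, doses, durs, ys, pids = [], [], [], [], [], []
    for p in ds.patients:
        for o in p.observations:
            d = governing_dose(p, o)
            row = [o.value, d.amount]
            m = [1.0, 1.0]
            for name in cov_order:
                v = p.covariates.get(name)
                row.append(0.0 if v is None else float(v))
                m.append(0.0 if v is None else 1.0)
            feats.append(row)
            masks.append(m)
            doses.append(d.amount)
            durs.append(d.infusion_duration)
            ys.append(o.value)
            pids.append(p.patient_id)
    return (np.array(feats), np.array(masks), np.array(doses),
            np.array(durs), np.array(ys), np.array(pids))


def sunitinib_patient_inputs(patient):
    """Static (values, mask) and the paired (times, parent, metab) sequence."""
    vals, mask = patient.covariate_vector()
    by_time = {}
    for o in patient.observations:
        by_time.setdefault(o.time, {})[o.analyte] = o.value
    times = sorted(by_time)
    seq = np.array([[by_time[t].get("parent", 0.0),
                     by_time[t].get("metab", 0.0)] for t in times])
    return vals, mask, np.asarray(times, dtype=float), seq


def _allometric_factors(weight):
    if weight is None:
        raise ValueError("sunitinib fitting requires body weight; impute upstream")
    fw = (weight / REFERENCE_WEIGHT) ** ALLOMETRIC_FLOW_EXP
    vw = weight / REFERENCE_WEIGHT
    return fw, vw


def _sun_theta_tensor(log_tv, popset, eta_by_name, weight):
    """Scaled parameter vector in _SUN_ORDER as one graph tensor."""
    fw, vw = _allometric_factors(weight)
    parts = []
    for name in _SUN_ORDER:
        if name in log_tv:
            base = log_tv[name].exp()
        else:
            base = Tensor(np.array(popset.tv[name]))
        if name in eta_by_name:
            base = base * eta_by_name[name].exp()
        if name in _SUN_FLOWS:
            base = base * fw
        elif name in _SUN_VOLS:
            base = base * vw
        parts.append(base.reshape(1))
    return concat(parts, axis=0)


def _sun_predict_op(theta_t, regimen, t_parent, t_metab, grad_idx, rel_step):
    """ODE predictions [parent..., metab...] with finite-difference VJP."""
    spec = model_spec("sunitinib")
    all_times = np.array(sorted(set(t_parent) | set(t_metab)))
    ip = np.searchsorted(all_times, t_parent)
    im = np.searchsorted(all_times, t_metab)

    def solve(vec):
        # FM is bounded in (0,1); a wide eta draw early in training can
        # push TV_FM*exp(eta) past 1 -- clamp for the forward solve only
        vec = np.array(vec, dtype=float)
        vec[1] = min(vec[1], 0.98)
        th = ThetaSunitinib(ka=vec[0], fm=vec[1], cls=vec[2], qs=vec[3],
                            clm=vec[4], qm=vec[5], qh=vec[6], v2s=vec[7],
                            v3s=vec[8], v2m=vec[9], v3m=vec[10])
        prof = solve_profile(spec, th, regimen, all_times)
        return np.concatenate([prof["parent"][ip], prof["metab"][im]])

    y0 = solve(theta_t.data)

    def vjp(g):
        grad = np.zeros_like(theta_t.data)
        for j in grad_idx:
            h = max(abs(theta_t.data[j]) * rel_step, 1e-9)
            v = theta_t.data.copy()
            v[j] += h
            grad[j] = g @ ((solve(v) - y0) / h)
        return [grad]

    return custom_op([theta_t], y0, vjp)


# ---------------------------------------------------------------------------
# ELBO

def _elbo_graph_fu5(table, encoder, popset, log_tv, log_b, cfg, rng,
                    sample_eta=True, train=False, unit_ix=None):
    feats, masks, doses, durs, ys, _ = table
    if unit_ix is not None:
        feats, masks = feats[unit_ix], masks[unit_ix]
        doses, durs, ys = doses[unit_ix], durs[unit_ix], ys[unit_ix]
    n = len(ys)
    mu, lv = encoder.forward(feats, masks, train=train, rng=rng)
    mu, lv = mu[:, 0], lv[:, 0]
    if sample_eta:
        z = rng.standard_normal(n)
        eta = mu + (lv * 0.5).exp() * Tensor(z)
    else:
        eta = mu
    log_cl = log_tv["CL"] + eta
    yhat = Tensor(doses / durs) * (-log_cl).exp()
    b = log_b.exp() if log_b is not None else Tensor(np.array(popset.error_b))
    recon, lognorm = _recon_tensor(ys, yhat, b, cfg.error_model)
    kl = _kl_tensor(mu, lv, popset.prior_scale ** 2).sum()
    scale = 1.0 / n
    parts = {"reconstruction": recon * scale,
             "kl": kl * (cfg.kl_weight * scale)}
    if log_b is not None:
        parts["lognorm"] = lognorm * scale
    total = parts["reconstruction"] + parts["kl"]
    if "lognorm" in parts:
        total = total + parts["lognorm"]
    return total, parts


def _elbo_graph_sunitinib(patients, encoder, popset, log_tv, log_b, cfg, rng,
                          fd_rel, sample_eta=True, train=False):
    n = len(patients)
    recon_t, lognorm_t, kl_t = None, None, None
    b = log_b.exp() if log_b is not None else Tensor(np.array(popset.error_b))
    grad_idx = [i for i, name in enumerate(_SUN_ORDER)
                if name in popset.learned or name in popset.iiv]
    for p in patients:
        vals, mask, times, seq = sunitinib_patient_inputs(p)
        mu, lv = encoder.forward(vals, mask, seq, times, train=train, rng=rng)
        if sample_eta:
            z = rng.standard_normal(len(encoder.names))
            eta_vec = mu + (lv * 0.5).exp() * Tensor(z)
        else:
            eta_vec = mu
        eta_by_name = {name: eta_vec[i] for i, name in enumerate(encoder.names)}
        theta_t = _sun_theta_tensor(log_tv, popset, eta_by_name,
                                    p.covariates.get("weight"))
        t_parent = np.array(sorted(o.time for o in p.observations
                                   if o.analyte == "parent"))
        t_metab = np.array(sorted(o.time for o in p.observations
                                  if o.analyte == "metab"))
        yhat = _sun_predict_op(theta_t, p.doses, t_parent, t_metab,
                               grad_idx, fd_rel)
        y = np.concatenate([
            np.array([o.value for o in sorted(
                (o for o in p.observations if o.analyte == "parent"),
                key=lambda o: o.time)]),
            np.array([o.value for o in sorted(
                (o for o in p.observations if o.analyte == "metab"),
                key=lambda o: o.time)])])
        recon, lognorm = _recon_tensor(y, yhat, b, cfg.error_model)
        kl = _kl_tensor(mu, lv, popset.prior_scale ** 2).sum()
        recon_t = recon if recon_t is None else recon_t + recon
        lognorm_t = lognorm if lognorm_t is None else lognorm_t + lognorm
        kl_t = kl if kl_t is None else kl_t + kl
    scale = 1.0 / n
    parts = {"reconstruction": recon_t * scale, "kl": kl_t * (cfg.kl_weight * scale)}
    if log_b is not None:
        parts["lognorm"] = lognorm_t * scale
    total = parts["reconstruction"] + parts["kl"]
    if "lognorm" in parts:
        total = total + parts["lognorm"]
    return total, parts


def elbo_loss(patients, encoder, popset, cfg, seed=0, drug_type=None,
              learned_tv=None, b=None):
    """Negative-ELBO value and decomposition for a batch of patients.

    ``learned_tv`` optionally overrides typical values; ``b`` overrides the
    residual coefficient.  The parts of the decomposition sum to the total.
    """
    drug_type = drug_type or popset.drug_type
    rng = np.random.default_rng(seed)
    tv = dict(popset.tv)
    if learned_tv:
        tv.update(learned_tv)
    pop = PopulationParameterSet(popset.drug_type, tv, popset.iiv,
                                 popset.learned, popset.prior_scale,
                                 b if b is not None else popset.error_b)
    log_tv = {k: Tensor(np.array(math.log(pop.tv[k]))) for k in pop.learned}
    log_b = Tensor(np.array(math.log(pop.error_b))) if cfg.learn_b else None
    if drug_type == "fu5":
        ds = Dataset(list(patients), "fu5")
        table = fu5_sample_table(ds)
        total, parts = _elbo_graph_fu5(table, encoder, pop, log_tv, log_b,
                                       cfg, rng)
    else:
        total, parts = _elbo_graph_sunitinib(list(patients), encoder, pop,
                                             log_tv, log_b, cfg, rng, 1e-6)
    decomp = {k: float(v.data) for k, v in parts.items()}
    return float(total.data), decomp


# ---------------------------------------------------------------------------
# fit loop

def _collect_params(encoder, log_tv, log_b):
    params = dict(encoder.parameters())
    for k, p in log_tv.items():
        params[f"log_tv.{k}"] = p
    if log_b is not None:
        params["log_b"] = log_b
    return params


def fit(train, drug_type=None, cfg=None, seed=0, popset=None):
    """Gradient-based minimization of the negative ELBO; deterministic per seed.

    Returns a :class:`FitResult` holding the trained encoder, the population
    parameter set with learned typical values and residual coefficient, and
    the loss trajectory.  Early stopping monitors a patient-level validation
    split (posterior means, no sampling).
    """
    cfg = cfg or TrainConfig()
    drug_type = drug_type or train.drug_type
    popset = popset or default_popset(drug_type)
    if not train.patients:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(seed)
    log_tv = {k: Parameter(np.array(math.log(popset.tv[k])))
              for k in popset.learned}
    log_b = Parameter(np.array(math.log(popset.error_b))) \
        if cfg.loss.learn_b else None

    # patient-level validation split; a 1-2 patient split is too noisy to
    # steer early stopping, so small cohorts train for the full epoch budget
    pids = sorted(p.patient_id for p in train.patients)
    n_val = int(round(cfg.val_fraction * len(pids)))
    if n_val < 3:
        n_val = 0
    val_ids = set(np.array(pids)[rng.permutation(len(pids))[:n_val]])
    train_p = [p for p in train.patients if p.patient_id not in val_ids]
    val_p = [p for p in train.patients if p.patient_id in val_ids]
    if not train_p:
        train_p, val_p = list(train.patients), []

    if drug_type == "fu5":
        encoder = Encoder5FU(cfg.encoder, seed=int(rng.integers(2 ** 31)))
        tab_train = fu5_sample_table(Dataset(train_p, "fu5"))
        tab_val = fu5_sample_table(Dataset(val_p, "fu5")) if val_p else None
        encoder.fit_normalizer(tab_train[0], tab_train[1])

        def graph(sample, train_mode):
            return _elbo_graph_fu5(tab_train, encoder, popset, log_tv, log_b,
                                   cfg.loss, rng, sample, train_mode)

        def val_loss():
            t, _ = _elbo_graph_fu5(tab_val, encoder, popset, log_tv, log_b,
                                   cfg.loss, rng, sample_eta=False)
            return float(t.data)
    else:
        encoder = EncoderSunitinib(cfg.encoder, seed=int(rng.integers(2 ** 31)))
        stat_vals, stat_masks, seq_rows, dts = [], [], [], []
        for p in train_p:
            v, m, times, seq = sunitinib_patient_inputs(p)
            stat_vals.append(v)
            stat_masks.append(m)
            seq_rows.extend(seq.tolist())
            dts.extend(np.diff(times, prepend=times[0]).tolist())
        encoder.fit_normalizers(np.array(stat_vals), np.array(stat_masks),
                                np.array(seq_rows), np.array(dts))

        def graph(sample, train_mode):
            return _elbo_graph_sunitinib(train_p, encoder, popset, log_tv,
                                         log_b, cfg.loss, rng,
                                         cfg.fd_rel_step, sample, train_mode)

        def val_loss():
            t, _ = _elbo_graph_sunitinib(val_p, encoder, popset, log_tv,
                                         log_b, cfg.loss, rng,
                                         cfg.fd_rel_step, sample_eta=False)
            return float(t.data)

    params = _collect_params(encoder, log_tv, log_b)
    opt = Adam(params.values(), lr=cfg.lr, clip_norm=cfg.clip_norm)
    trajectory = []
    best_val, best_state, stale = np.inf, None, 0
    decomp = {}
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        total, parts = graph(sample=True, train_mode=True)
        if not np.isfinite(total.data):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
        total.backward()
        opt.step()
        trajectory.append(float(total.data))
        decomp = {k: float(v.data) for k, v in parts.items()}
        if cfg.center_every and (epoch + 1) % cfg.center_every == 0:
            _center_posterior(encoder, log_tv, train_p, drug_type)
        if val_p and (epoch + 1) % cfg.check_every == 0:
            vl = val_loss()
            if vl < best_val - 1e-10:
                best_val, stale = vl, 0
                best_state = {k: p.data.copy() for k, p in params.items()}
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    _center_posterior(encoder, log_tv, train_p, drug_type)
    tv = dict(popset.tv)
    for k, p in log_tv.items():
        tv[k] = float(np.exp(p.data))
    fitted = PopulationParameterSet(
        popset.drug_type, tv, popset.iiv, popset.learned, popset.prior_scale,
        float(np.exp(log_b.data)) if log_b is not None else popset.error_b)
    return FitResult(drug_type, encoder, fitted, trajectory, decomp, seed, cfg)


def _center_posterior(encoder, log_tv, train_patients, drug_type):
    """Project to the KL-optimal point of the likelihood-invariant manifold.

    The map (TV_k, mu_k) -> (TV_k * e^m, mu_k - m) leaves every prediction
    unchanged for learned TVs with IIV; among those equivalent solutions the
    KL term is minimal where the training-set mean of mu_k is zero.  Descent
    along this flat direction is slow, so the trained model is re-centered
    exactly: the mean posterior mean is folded into the typical value and
    subtracted from the mu head's output bias.
    """
    if drug_type == "fu5":
        if "CL" not in log_tv:
            return
        tab = fu5_sample_table(Dataset(list(train_patients), "fu5"))
        mu, _ = encoder.forward(tab[0], tab[1])
        m = float(mu.data[:, 0].mean())
        encoder.head_mu.biases[-1].data[0] -= m
        log_tv["CL"].data += m
        return
    mus = []
    for p in train_patients:
        vals, mask, times, seq = sunitinib_patient_inputs(p)
        mu, _ = encoder.forward(vals, mask, seq, times)
        mus.append(mu.data)
    mus = np.array(mus)
    for i, name in enumerate(encoder.names):
        if name in log_tv:
            m = float(mus[:, i].mean())
            encoder.head_mu.biases[-1].data[i] -= m
            log_tv[name].data += m


# ---------------------------------------------------------------------------
# prediction / simulation

def posterior_stats_fu5(fit_result, patient, mode="paper"):
    """Per-measurement posterior stats; 'loo' encodes each target from the
    patient's *other* measurements (honest prediction)."""
    tab = fu5_sample_table(Dataset([patient], "fu5"))
    feats, masks = tab[0], tab[1]
    enc = fit_result.encoder
    if mode == "paper":
        st = enc.encode(feats, masks)
        return st.mu[:, 0], st.log_var[:, 0]
    mus, lvs = [], []
    n = len(feats)
    for j in range(n):
        others = [i for i in range(n) if i != j]
        if not others:
            mus.append(0.0)
            lvs.append(0.0)
            continue
        st = enc.encode(feats[others], masks[others])
        mus.append(float(st.mu[:, 0].mean()))
        lvs.append(float(st.log_var[:, 0].mean()))
    return np.array(mus), np.array(lvs)


def predict_individual(fit_result, patient, times=None, mode="paper"):
    """Posterior-mean predictions (no sampling, no residual error).

    For 5FU returns one prediction per observation (each measurement uses
    its own encoding in 'paper' mode, or the other measurements in 'loo'
    mode).  For sunitinib returns ``{"parent": ..., "metab": ...}`` at the
    patient's observation times (or ``times`` if given).
    """
    if fit_result.drug_type == "fu5":
        tab = fu5_sample_table(Dataset([patient], "fu5"))
        doses, durs = tab[2], tab[3]
        mu, _ = posterior_stats_fu5(fit_result, patient, mode)
        cl = fit_result.popset.tv["CL"] * np.exp(mu)
        return doses / (durs * cl)
    vals, mask, seq_times, seq = sunitinib_patient_inputs(patient)
    st = fit_result.encoder.encode(vals, mask, seq, seq_times)
    eta = {k: float(st.mu[i]) for i, k in enumerate(fit_result.encoder.names)}
    return _simulate_sun_once(fit_result, patient, eta, times)


def _simulate_sun_once(fit_result, patient, eta, times=None):
    pop = fit_result.popset
    params = {}
    for name in _SUN_ORDER:
        v = pop.tv[name]
        if name in eta:
            v *= math.exp(eta[name])
        params[name] = v
    from mmpk.odes import allometric_scale
    theta = allometric_scale(theta_from_params("sunitinib", params),
                             patient.covariates.get("weight"))
    spec = model_spec("sunitinib")
    if times is None:
        t_parent = np.array(sorted(o.time for o in patient.observations
                                   if o.analyte == "parent"))
        t_metab = np.array(sorted(o.time for o in patient.observations
                                  if o.analyte == "metab"))
        allt = np.array(sorted(set(t_parent) | set(t_metab)))
        prof = solve_profile(spec, theta, patient.doses, allt)
        ip = np.searchsorted(allt, t_parent)
        im = np.searchsorted(allt, t_metab)
        return {"parent": prof["parent"][ip], "metab": prof["metab"][im]}
    prof = solve_profile(spec, theta, patient.doses, np.asarray(times, float))
    return prof


def flatten_observations(ds):
    """Stable flattening (patient order; per patient parent then metab by time)."""
    rows = []
    for p in ds.patients:
        for analyte in ("parent", "metab"):
            for o in sorted((o for o in p.observations if o.analyte == analyte),
                            key=lambda o: o.time):
                rows.append((p.patient_id, o.time, analyte, o.value))
    return rows


def simulate_cohort(fit_result, patients, n_reps=500, mode="posterior",
                    with_residual=True, seed=0):
    """Replicate concentration sets at the patients' observation times.

    mode='prior' samples eta ~ N(0, lambda^2); mode='posterior' samples from
    each unit's encoder posterior.  Returns (reps, index) where ``reps`` has
    shape (n_reps, n_obs) aligned with ``flatten_observations``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ds = Dataset(list(patients), fit_result.drug_type)
    index = flatten_observations(ds)
    pop = fit_result.popset
    lam = pop.prior_scale
    b = pop.error_b
    n_obs = len(index)
    reps = np.zeros((n_reps, n_obs))
    if fit_result.drug_type == "fu5":
        col = 0
        for p in ds.patients:
            tab = fu5_sample_table(Dataset([p], "fu5"))
            doses, durs = tab[2], tab[3]
            m = len(doses)
            mu, lv = posterior_stats_fu5(fit_result, p, "paper")
            sd = np.exp(0.5 * lv)
            for r in range(n_reps):
                if mode == "prior":
                    eta = rng.normal(0.0, lam, size=m)
                else:
                    eta = mu + sd * rng.standard_normal(m)
                yhat = doses / (durs * pop.tv["CL"] * np.exp(eta))
                if with_residual:
                    yhat = yhat * (1.0 + b * rng.standard_normal(m))
                reps[r, col:col + m] = yhat
            col += m
        return reps, index
    col = 0
    for p in ds.patients:
        vals, mask, seq_times, seq = sunitinib_patient_inputs(p)
        st = fit_result.encoder.encode(vals, mask, seq, seq_times)
        names = fit_result.encoder.names
        n_parent = sum(1 for o in p.observations if o.analyte == "parent")
        n_metab = sum(1 for o in p.observations if o.analyte == "metab")
        m = n_parent + n_metab
        for r in range(n_reps):
            if mode == "prior":
                eta = {k: rng.normal(0.0, lam) for k in names}
            else:
                eta = {k: float(st.mu[i] + math.exp(0.5 * st.log_var[i])
                                * rng.standard_normal()) for i, k in enumerate(names)}
            prof = _simulate_sun_once(fit_result, p, eta)
            y = np.concatenate([prof["parent"], prof["metab"]])
            if with_residual:
                y = y * (1.0 + b * rng.standard_normal(m))
            reps[r, col:col + m] = y
        col += m
    return reps, index
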