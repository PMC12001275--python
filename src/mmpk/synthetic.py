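"""Virtual cohort generators with known ground truth, plus deterministic fixtures.

Two study designs are emulated:

* a 5FU-like cohort — weekly 24 h steady-state infusions with BSA-dosed
  regimens, samples drawn 16.8-25.0 h after infusion start, log-normal IIV
  on clearance with a linear BSA effect, proportional residual error;
* a sunitinib-like cohort — daily oral dosing (37.5/50 mg) on a 4-week-on /
  2-week-off schedule, trough samples over up to three cycles, paired
  parent/metabolite observations, covariate missingness and a BLQ floor.

Noise-free concentrations come from the structural models' own closed
forms/solvers (``css_5fu`` and ``solve_profile``), never a reimplementation,
so parameter-recovery tests compare like with like.  The two acceptance
fixtures are fully deterministic and reproduce the raw bookkeeping of the
studies the designs emulate (549 observations / 157 patients with 8
implausible entries; 308 paired observations / 47 patients with 6 BLQ
parent samples from 5 patients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from mmpk.data import Dataset, PatientRecord, DoseEvent, ObservationRecord, \
    BLQ_5FU_MG_L, BLQ_SUNITINIB_NG_ML
from mmpk.odes import css_5fu, allometric_scale, model_spec, solve_profile
from mmpk.population import SUNITINIB_DEFAULTS, theta_from_params

DU_BOIS_A, DU_BOIS_WT_EXP, DU_BOIS_HT_EXP = 0.007184, 0.425, 0.725


def du_bois_bsa(weight, height):
    """BSA (m^2) from weight (kg) and height (cm), Du Bois & Du Bois."""
    return DU_BOIS_A * weight ** DU_BOIS_WT_EXP * height ** DU_BOIS_HT_EXP


def weight_from_bsa(bsa, height):
    return (bsa / (DU_BOIS_A * height ** DU_BOIS_HT_EXP)) ** (1.0 / DU_BOIS_WT_EXP)


def james_lbm(weight, height, sex):
    """Lean body mass (kg), James formula; sex 1 = male, 0 = female."""
    if sex >= 0.5:
        return 1.10 * weight - 128.0 * (weight / height) ** 2
    return 1.07 * weight - 148.0 * (weight / height) ** 2


@dataclass
class CohortConfig5FU:
    n_patients: int = 157
    tv_cl: float = 223.0          # L/h
    v: float = 46.1               # L (fixed)
    omega: float = 0.3            # IIV SD of eta on CL
    bsa_slope: float = 80.0       # L/h per m^2 of (BSA - median BSA) on CL
    error_b: float = 0.2          # proportional residual SD
    infusion_duration: float = 24.0
    dose_per_bsa: tuple = (2000.0, 2600.0)   # weekly mg/m^2 regimens
    dose_regimen_probs: tuple = (0.6, 0.4)
    dose_range: tuple = (2700.0, 5720.0)
    male_fraction: float = 96.0 / 156.0
    bsa_median: float = 1.915
    bsa_range: tuple = (1.35, 2.85)
    age_median: float = 64.5
    age_range: tuple = (35.0, 83.0)
    sample_window: tuple = (16.8, 25.0)      # hours after infusion start
    samples_min: int = 1
    samples_max: int = 9
    occasion_spacing: float = 168.0          # weekly courses

    def __post_init__(self):
        if min(self.n_patients, self.tv_cl, self.v, self.error_b,
               self.infusion_duration) <= 0 or self.omega < 0:
            raise ValueError("cohort configuration values must be positive")
        if not 0 < self.sample_window[0] < self.sample_window[1] \
                <= self.occasion_spacing:
            raise ValueError("sampling window must fit inside one occasion")


@dataclass
class CohortConfigSunitinib:
    n_patients: int = 47
    doses_mg: tuple = (37.5, 50.0)
    dose_probs: tuple = (0.7, 0.3)
    days_on: int = 28
    days_off: int = 14
    max_cycles: int = 3
    tv: dict = field(default_factory=lambda: dict(SUNITINIB_DEFAULTS))
    iiv_sd: dict = field(default_factory=lambda: {
        "CLS": 0.35, "V2S": 0.30, "FM": 0.25, "V2M": 0.30})
    error_b_parent: float = 0.20
    error_b_metab: float = 0.20
    missing_weight: float = 0.129
    missing_height: float = 0.109
    missing_bsa: float = 0.066
    blq_threshold: float = BLQ_SUNITINIB_NG_ML
    male_fraction: float = 0.65
    samples_mean: float = 6.5
    samples_sd: float = 3.5
    samples_min: int = 1
    samples_max: int = 14
    trough_lead: float = 0.5      # hours before intake

    def __post_init__(self):
        for r in (self.missing_weight, self.missing_height, self.missing_bsa):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        if self.days_on + self.days_off != 42:
            raise ValueError("schedule period must be 42 days (4 on / 2 off weeks)")


@dataclass
class GroundTruth:
    eta: dict            # patient_id -> {param: eta}
    theta: dict          # patient_id -> {param: individual value}
    clean: dict          # patient_id -> {analyte: (times, noise-free conc)}


# ---------------------------------------------------------------------------
# 5FU cohort

def _truncnorm(rng, loc, scale, lo, hi, size=None):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return sstats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                                random_state=rng)


def _fu5_covariates(rng, cfg):
    sex = 1.0 if rng.random() < cfg.male_fraction else 0.0
    bsa = float(_truncnorm(rng, cfg.bsa_median, 0.24, *cfg.bsa_range))
    height = float(_truncnorm(rng, 176.0 if sex else 163.0, 7.0, 150.0, 200.0))
    weight = weight_from_bsa(bsa, height)
    lbm = james_lbm(weight, height, sex)
    fm = weight - lbm
    age = float(_truncnorm(rng, cfg.age_median, 11.0, *cfg.age_range))
    return {"sex": sex, "age": age, "weight": weight, "height": height,
            "bsa": bsa, "lbm": lbm, "fm": fm}

# samples-per-patient distribution targeting a median of 3 on 1..9
_FU5_COUNT_P = np.array([0.20, 0.20, 0.25, 0.12, 0.08, 0.06, 0.04, 0.03, 0.02])


def generate_5fu_cohort(cfg=None, seed=0):
    """Synthetic steady-state infusion cohort; returns (Dataset, GroundTruth)."""
    cfg = cfg or CohortConfig5FU()
    rng = np.random.default_rng(seed)
    patients, eta_map, theta_map, clean_map = [], {}, {}, {}
    for i in range(cfg.n_patients):
        pid = f"p{i + 1:03d}"
        cov = _fu5_covariates(rng, cfg)
        rate = rng.choice(cfg.dose_per_bsa, p=cfg.dose_regimen_probs)
        dose = float(np.clip(round(rate * cov["bsa"] / 10.0) * 10.0,
                             *cfg.dose_range))
        eta = rng.normal(0.0, cfg.omega) if cfg.omega > 0 else 0.0
        cl = (cfg.tv_cl + cfg.bsa_slope * (cov["bsa"] - cfg.bsa_median)) \
            * math.exp(eta)
        n_samp = int(rng.choice(np.arange(1, 10), p=_FU5_COUNT_P))
        n_samp = min(max(n_samp, cfg.samples_min), cfg.samples_max)
        doses, obs, times, cvals = [], [], [], []
        for j in range(n_samp):
            t0 = j * cfg.occasion_spacing
            doses.append(DoseEvent(pid, t0, dose, cfg.infusion_duration,
                                   "iv_infusion"))
            t = t0 + rng.uniform(*cfg.sample_window)
            c = css_5fu(dose, cfg.infusion_duration, cl)
            y = c * (1.0 + cfg.error_b * rng.standard_normal())
            y = max(y, 1e-6)
            obs.append(ObservationRecord(pid, t, y, "parent",
                                         blq_flag=y < BLQ_5FU_MG_L))
            times.append(t)
            cvals.append(c)
        patients.append(PatientRecord(pid, cov, doses, obs))
        eta_map[pid] = {"CL": eta}
        theta_map[pid] = {"CL": cl, "V": cfg.v}
        clean_map[pid] = {"parent": (np.array(times), np.array(cvals))}
    ds = Dataset(patients, "fu5", provenance=f"synthetic 5FU cohort seed={seed}")
    return ds, GroundTruth(eta_map, theta_map, clean_map)


# ---------------------------------------------------------------------------
# sunitinib cohort

def _sun_covariates(rng, cfg):
    sex = 1.0 if rng.random() < cfg.male_fraction else 0.0
    height = float(_truncnorm(rng, 177.0 if sex else 164.0, 7.0, 150.0, 200.0))
    weight = float(_truncnorm(rng, 81.0 if sex else 68.0, 13.0, 45.0, 130.0))
    bsa = du_bois_bsa(weight, height)
    age = float(_truncnorm(rng, 61.0, 10.0, 30.0, 85.0))
    return {"sex": sex, "age": age, "weight": weight, "height": height,
            "bsa": bsa, "lbm": None, "fm": None}


def _sun_schedule(cfg, n_cycles, dose, pid):
    events = []
    for cyc in range(n_cycles):
        base = cyc * (cfg.days_on + cfg.days_off)
        for day in range(cfg.days_on):
            events.append(DoseEvent(pid, 24.0 * (base + day), dose, 0.0, "oral"))
    return events


def generate_sunitinib_cohort(cfg=None, seed=0, n_samples_override=None):
    """Synthetic oral parent/metabolite cohort; returns (Dataset, GroundTruth)."""
    cfg = cfg or CohortConfigSunitinib()
    rng = np.random.default_rng(seed)
    spec = model_spec("sunitinib")
    patients, eta_map, theta_map, clean_map = [], {}, {}, {}
    for i in range(cfg.n_patients):
        pid = f"s{i + 1:03d}"
        cov = _sun_covariates(rng, cfg)
        true_weight = cov["weight"]
        dose = float(rng.choice(cfg.doses_mg, p=cfg.dose_probs))
        n_cycles = int(rng.integers(2, cfg.max_cycles + 1))
        regimen = _sun_schedule(cfg, n_cycles, dose, pid)
        eta = {k: rng.normal(0.0, sd) if sd > 0 else 0.0
               for k, sd in cfg.iiv_sd.items()}
        params = {}
        for name, tv in cfg.tv.items():
            params[name] = tv * math.exp(eta.get(name, 0.0))
        theta = allometric_scale(theta_from_params("sunitinib", params),
                                 true_weight)
        if n_samples_override is not None:
            n_samp = n_samples_override
        else:
            n_samp = int(round(_truncnorm(rng, cfg.samples_mean, cfg.samples_sd,
                                          cfg.samples_min, cfg.samples_max)))
        # trough samples: strictly before an on-treatment intake, day >= 1
        on_days = [d for cyc in range(n_cycles)
                   for d in range(cyc * 42 + 1, cyc * 42 + cfg.days_on)]
        days = sorted(rng.choice(on_days, size=min(n_samp, len(on_days)),
                                 replace=False))
        times = np.array([24.0 * d - cfg.trough_lead for d in days])
        prof = solve_profile(spec, theta, regimen, times)
        obs = []
        for t, cp, cm in zip(times, prof["parent"], prof["metab"]):
            yp = max(cp * (1.0 + cfg.error_b_parent * rng.standard_normal()), 1e-4)
            ym = max(cm * (1.0 + cfg.error_b_metab * rng.standard_normal()), 1e-4)
            obs.append(ObservationRecord(pid, t, yp, "parent",
                                         blq_flag=yp < cfg.blq_threshold))
            obs.append(ObservationRecord(pid, t, ym, "metab"))
        # covariate missingness (weight/height/BSA); ground truth keeps values
        if rng.random() < cfg.missing_weight:
            cov = dict(cov, weight=None)
        if rng.random() < cfg.missing_height:
            cov = dict(cov, height=None)
        if rng.random() < cfg.missing_bsa:
            cov = dict(cov, bsa=None)
        patients.append(PatientRecord(pid, cov, regimen, obs))
        eta_map[pid] = eta
        theta_map[pid] = params | {"weight": true_weight}
        clean_map[pid] = {"parent": (times, prof["parent"]),
                          "metab": (times, prof["metab"])}
    ds = Dataset(patients, "sunitinib",
                 provenance=f"synthetic sunitinib cohort seed={seed}")
    return ds, GroundTruth(eta_map, theta_map, clean_map)


# ---------------------------------------------------------------------------
# deterministic acceptance fixtures

def _adjust_counts(counts, total, lo, hi, rng):
    counts = list(counts)
    diff = total - sum(counts)
    order = rng.permutation(len(counts))
    k = 0
    while diff != 0:
        j = order[k % len(counts)]
        if diff > 0 and counts[j] < hi:
            counts[j] += 1
            diff -= 1
        elif diff < 0 and counts[j] > lo:
            counts[j] -= 1
            diff += 1
        k += 1
    return counts


_FIXTURE_SEED_5FU = 20250501
_FIXTURE_SEED_SUN = 20250502


def generate_acceptance_fixture_5fu():
    """157 patients, 549 observations, exactly 8 implausible entries on 8
    distinct patients (one of which has only that sample).  Deterministic."""
    cfg = CohortConfig5FU()
    rng = np.random.default_rng(_FIXTURE_SEED_5FU)
    base_counts = [int(rng.choice(np.arange(1, 10), p=_FU5_COUNT_P))
                   for _ in range(cfg.n_patients)]
    base_counts[0] = 1                # the patient excluded entirely
    for i in range(1, 8):             # other violators must survive the filter
        base_counts[i] = max(base_counts[i], 2)
    head, tail = base_counts[:8], base_counts[8:]
    tail = _adjust_counts(tail, 549 - sum(head), 1, 9, rng)
    counts = head + tail
    assert counts[0] == 1 and min(counts[1:8]) >= 2 and sum(counts) == 549
    patients = []
    for i, n_samp in enumerate(counts):
        pid = f"p{i + 1:03d}"
        cov = _fu5_covariates(rng, cfg)
        rate = rng.choice(cfg.dose_per_bsa, p=cfg.dose_regimen_probs)
        dose = float(np.clip(round(rate * cov["bsa"] / 10.0) * 10.0,
                             *cfg.dose_range))
        if 4 <= i <= 7:
            dose = 4000.0    # clearance-rule violators carry the median dose
        eta = rng.normal(0.0, cfg.omega)
        cl = (cfg.tv_cl + cfg.bsa_slope * (cov["bsa"] - cfg.bsa_median)) \
            * math.exp(eta)
        doses, obs = [], []
        for j in range(n_samp):
            t0 = j * cfg.occasion_spacing
            doses.append(DoseEvent(pid, t0, dose, cfg.infusion_duration,
                                   "iv_infusion"))
            t = t0 + rng.uniform(*cfg.sample_window)
            c = css_5fu(dose, cfg.infusion_duration, cl)
            y = c * (1.0 + cfg.error_b * rng.standard_normal())
            # keep regular samples comfortably inside both rules
            y = max(y, dose / (cfg.infusion_duration * 1300.0))
            obs.append(ObservationRecord(pid, t, y, "parent"))
        patients.append(PatientRecord(pid, cov, doses, obs))

    def replace_first_obs(p, value):
        o = p.observations[0]
        p.observations[0] = ObservationRecord(
            p.patient_id, o.time, value, "parent",
            blq_flag=value < BLQ_5FU_MG_L)

    for i in range(0, 4):                    # BLQ violations (< 0.8 * 0.052)
        replace_first_obs(patients[i], 0.03)
    for i in range(4, 8):                    # implied CL = 4000/(24*c) = 1900 L/h
        replace_first_obs(patients[i], 4000.0 / (24.0 * 1900.0))
    return Dataset(patients, "fu5", provenance="deterministic 5FU fixture")


def generate_acceptance_fixture_sunitinib():
    """47 patients, 308 parent + 308 paired metabolite observations, exactly
    6 BLQ parent samples on 5 distinct patients.  Deterministic."""
    cfg = CohortConfigSunitinib()
    rng = np.random.default_rng(_FIXTURE_SEED_SUN)
    base_counts = [int(round(_truncnorm(rng, cfg.samples_mean, cfg.samples_sd,
                                        3, cfg.samples_max)))
                   for _ in range(cfg.n_patients)]
    counts = _adjust_counts(base_counts, 308, 3, cfg.samples_max, rng)
    assert sum(counts) == 308 and min(counts) >= 3
    spec = model_spec("sunitinib")
    patients = []
    for i, n_samp in enumerate(counts):
        pid = f"s{i + 1:03d}"
        cov = _sun_covariates(rng, cfg)
        dose = float(rng.choice(cfg.doses_mg, p=cfg.dose_probs))
        regimen = _sun_schedule(cfg, cfg.max_cycles, dose, pid)
        eta = {k: rng.normal(0.0, sd) for k, sd in cfg.iiv_sd.items()}
        params = {n: tv * math.exp(eta.get(n, 0.0)) for n, tv in cfg.tv.items()}
        theta = allometric_scale(theta_from_params("sunitinib", params),
                                 cov["weight"])
        on_days = [d for cyc in range(cfg.max_cycles)
                   for d in range(cyc * 42 + 1, cyc * 42 + cfg.days_on)]
        days = sorted(rng.choice(on_days, size=n_samp, replace=False))
        times = np.array([24.0 * d - cfg.trough_lead for d in days])
        prof = solve_profile(spec, theta, regimen, times)
        obs = []
        for t, cp, cm in zip(times, prof["parent"], prof["metab"]):
            yp = max(cp * (1.0 + cfg.error_b_parent * rng.standard_normal()),
                     2.0 * cfg.blq_threshold)
            ym = max(cm * (1.0 + cfg.error_b_metab * rng.standard_normal()),
                     2.0 * cfg.blq_threshold)
            obs.append(ObservationRecord(pid, t, yp, "parent"))
            obs.append(ObservationRecord(pid, t, ym, "metab"))
        patients.append(PatientRecord(pid, cov, regimen, obs))
    # six BLQ parent values (< 0.8 * threshold) across five patients
    blq_value = 0.04
    placements = [(0, 0), (0, 1), (1, 0), (2, 0), (3, 0), (4, 0)]
    for pat_ix, obs_rank in placements:
        p = patients[pat_ix]
        parent_positions = [k for k, o in enumerate(p.observations)
                            if o.analyte == "parent"]
        k = parent_positions[obs_rank]
        o = p.observations[k]
        p.observations[k] = ObservationRecord(p.patient_id, o.time, blq_value,
                                              "parent", blq_flag=True)
    return Dataset(patients, "sunitinib",
                   provenance="deterministic sunitinib fixture")
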