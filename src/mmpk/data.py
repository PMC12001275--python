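"""Event-record data model, readers/writers, exclusion filters and CV splitting.

The on-disk dialect is a comma-separated table with one row per event and a
mandatory header::

    ID,TIME,EVT,AMT,DUR,DV,ANALYTE,BLQ,SEX,AGE,WT,HT,BSA,LBM,FM

``EVT`` is ``dose`` or ``obs``.  Dose rows carry ``AMT`` (mg) and ``DUR``
(infusion duration in hours; 0 for an oral bolus).  Observation rows carry
``DV`` (concentration; mg/L for 5FU, ng/mL for sunitinib and its
metabolite), ``ANALYTE`` (``parent``/``metab``) and a ``BLQ`` 0/1 flag.
Static covariates repeat on every row of a patient; missing numeric values
are empty cells, never sentinels.  ``TIME`` is hours since the patient's
first dose.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

COVARIATE_NAMES = ("sex", "age", "weight", "height", "bsa", "lbm", "fm")

_COLUMNS = ["ID", "TIME", "EVT", "AMT", "DUR", "DV", "ANALYTE", "BLQ",
            "SEX", "AGE", "WT", "HT", "BSA", "LBM", "FM"]
_COV_COLS = {"sex": "SEX", "age": "AGE", "weight": "WT", "height": "HT",
             "bsa": "BSA", "lbm": "LBM", "fm": "FM"}

#: 5FU BLQ threshold in dataset units (mg/L); the assay limit is 52 ng/mL.
BLQ_5FU_MG_L = 0.052
#: Implausible-clearance cutoff for 5FU, L/h (739 L/h/m^2 at BSA 2 m^2).
CL_5FU_MAX_L_H = 1478.0
#: Sunitinib BLQ threshold, ng/mL.
BLQ_SUNITINIB_NG_ML = 0.06


class SchemaError(ValueError):
    """A mandatory column is missing or an enum value is unrecognized."""


class ParseError(ValueError):
    """A numeric field failed to parse; carries the offending row index."""


@dataclass(frozen=True)
class ObservationRecord:
    patient_id: str
    time: float                 # hours since first dose
    value: float                # concentration
    analyte: str = "parent"     # "parent" | "metab"
    blq_flag: bool = False
    excluded_flag: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not math.isnan(self.value) and self.value < 0:
            raise ValueError(f"concentration must be >= 0, got {self.value}")
        if self.analyte not in ("parent", "metab"):
            raise ValueError(f"unknown analyte {self.analyte!r}")


@dataclass(frozen=True)
class DoseEvent:
    patient_id: str
    time: float                 # hours
    amount: float               # mg
    infusion_duration: float = 0.0   # hours; 0 for oral bolus
    route: str = "iv_infusion"  # "iv_infusion" | "oral"

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.infusion_duration < 0:
            raise ValueError("infusion duration must be >= 0")
        if self.route == "iv_infusion" and self.infusion_duration <= 0:
            raise ValueError("iv infusion requires infusion_duration > 0")
        if self.route not in ("iv_infusion", "oral"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass
class PatientRecord:
    """One subject: dose events, observations and static covariates.

    ``covariates`` maps names in :data:`COVARIATE_NAMES` to floats; missing
    entries are ``None`` (the missing mask).  Units: sex 0=female/1=male,
    age years, weight kg, height cm, BSA m^2, LBM kg, FM kg.
    """

    patient_id: str
    covariates: dict = field(default_factory=dict)
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)

    def covariate_vector(self):
        """(values, mask) arrays in COVARIATE_NAMES order; missing -> 0.0, mask 0."""
        vals = np.zeros(len(COVARIATE_NAMES))
        mask = np.zeros(len(COVARIATE_NAMES))
        for j, name in enumerate(COVARIATE_NAMES):
            v = self.covariates.get(name)
            if v is not None:
                vals[j] = float(v)
                mask[j] = 1.0
        return vals, mask


@dataclass
class Dataset:
    patients: list
    drug_type: str              # "fu5" | "sunitinib"
    provenance: str = ""

    def __post_init__(self):
        if self.drug_type not in ("fu5", "sunitinib"):
            raise ValueError(f"unknown drug_type {self.drug_type!r}")
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids must be unique")

    @property
    def n_patients(self):
        return len(self.patients)

    def n_observations(self, analyte=None):
        return sum(1 for p in self.patients for o in p.observations
                   if analyte is None or o.analyte == analyte)

    def patient(self, patient_id):
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def subset(self, patient_ids):
        keep = set(patient_ids)
        return Dataset([p for p in self.patients if p.patient_id in keep],
                       self.drug_type, self.provenance)


@dataclass(frozen=True)
class CVSplit:
    repeat_index: int
    fold_index: int
    train_patient_ids: tuple
    test_patient_ids: tuple


@dataclass
class ExclusionReport:
    raw_observations: dict          # analyte -> count before filtering
    kept_observations: dict         # analyte -> count after filtering
    excluded_by_reason: dict        # reason -> count
    raw_patients: int
    kept_patients: int
    removed_patient_ids: tuple = ()

    @property
    def n_excluded(self):
        return sum(self.excluded_by_reason.values())

    def excluded_fraction(self, analyte="parent"):
        raw = self.raw_observations.get(analyte, 0)
        excl = raw - self.kept_observations.get(analyte, 0)
        return excl / raw if raw else 0.0


# ---------------------------------------------------------------------------
# reading / writing

def _parse_float(cell, col, idx):
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {idx}: non-numeric value {cell!r} in column {col}") from None


def read_dataset(path, drug_type, provenance=None):
    """Read the comma-separated event-record dialect into a :class:`Dataset`.

    Dose and observation rows are distinguished by ``EVT``; missing
    covariates become ``None`` entries (the missing mask), never sentinels.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, newline="") as fh:
            text = fh.read()
    reader = csv.reader(io.StringIO(text))
    rows = list(reader)
    if not rows:
        raise SchemaError("empty file")
    header = [h.strip() for h in rows[0]]
    for col in _COLUMNS:
        if col not in header:
            raise SchemaError(f"missing mandatory column {col!r}")
    ix = {c: header.index(c) for c in header}
    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(rows[1:], start=1):
        if not any(c.strip() for c in row):
            continue
        pid = row[ix["ID"]].strip()
        if pid == "":
            raise ParseError(f"row {i}: empty patient ID")
        if pid not in patients:
            cov = {}
            for name, col in _COV_COLS.items():
                cov[name] = _parse_float(row[ix[col]], col, i)
            patients[pid] = PatientRecord(pid, cov)
        p = patients[pid]
        evt = row[ix["EVT"]].strip().lower()
        t = _parse_float(row[ix["TIME"]], "TIME", i)
        if t is None:
            raise ParseError(f"row {i}: TIME is mandatory")
        if evt == "dose":
            amt = _parse_float(row[ix["AMT"]], "AMT", i)
            dur = _parse_float(row[ix["DUR"]], "DUR", i) or 0.0
            if amt is None:
                raise ParseError(f"row {i}: dose row lacks AMT")
            route = "iv_infusion" if dur > 0 else "oral"
            p.doses.append(DoseEvent(pid, t, amt, dur, route))
        elif evt == "obs":
            dv = _parse_float(row[ix["DV"]], "DV", i)
            if dv is None:
                raise ParseError(f"row {i}: observation row lacks DV")
            analyte = row[ix["ANALYTE"]].strip().lower() or "parent"
            if analyte not in ("parent", "metab"):
                raise SchemaError(f"row {i}: unknown ANALYTE {analyte!r}")
            blq = row[ix["BLQ"]].strip() in ("1", "1.0", "true", "True")
            p.observations.append(ObservationRecord(pid, t, dv, analyte, blq))
        else:
            raise SchemaError(f"row {i}: unknown EVT {evt!r}")
    ds = Dataset(list(patients.values()), drug_type,
                 provenance if provenance is not None else str(path))
    for p in ds.patients:
        if not p.doses:
            raise SchemaError(f"patient {p.patient_id} has no dose event")
    return ds


def _fmt(v):
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_dataset(ds, path):
    """Write a :class:`Dataset` in the same dialect; numeric round-trip exact."""
    rows = []
    for p in ds.patients:
        cov = [_fmt(p.covariates.get(n)) for n in COVARIATE_NAMES]
        events = ([("dose", d) for d in p.doses] +
                  [("obs", o) for o in p.observations])
        events.sort(key=lambda e: (e[1].time, 0 if e[0] == "dose" else 1))
        for kind, ev in events:
            if kind == "dose":
                rows.append([p.patient_id, _fmt(ev.time), "dose", _fmt(ev.amount),
                             _fmt(ev.infusion_duration), "", "", ""] + cov)
            else:
                rows.append([p.patient_id, _fmt(ev.time), "obs", "", "",
                             _fmt(ev.value), ev.analyte,
                             "1" if ev.blq_flag else "0"] + cov)
    if hasattr(path, "write"):
        w = csv.writer(path, lineterminator="\n")
        w.writerow(_COLUMNS)
        w.writerows(rows)
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(_COLUMNS)
            w.writerows(rows)


# ---------------------------------------------------------------------------
# exclusion filters

def governing_dose(patient, obs):
    """Most recent dose event at or before the observation time."""
    cand = [d for d in patient.doses if d.time <= obs.time]
    if not cand:
        raise ValueError(
            f"observation at t={obs.time} for patient {patient.patient_id} "
            "has no governing dose")
    return max(cand, key=lambda d: d.time)


def implied_clearance(dose, concentration):
    """Steady-state clearance D/(IT*C) in L/h (D mg, IT h, C mg/L)."""
    if dose.infusion_duration <= 0:
        raise ValueError("implied clearance requires an infusion dose")
    return dose.amount / (dose.infusion_duration * concentration)


def apply_exclusions_5fu(ds, blq_threshold=BLQ_5FU_MG_L,
                         cl_threshold=CL_5FU_MAX_L_H):
    """Remove implausible 5FU samples: BLQ or implied clearance above cutoff.

    An observation is dropped when its value is below ``blq_threshold``
    (mg/L) or when the steady-state clearance D/(IT*C) implied by its
    governing infusion exceeds ``cl_threshold`` (L/h).  Patients left with
    no observations are removed.  Idempotent.
    """
    if ds.drug_type != "fu5":
        raise ValueError("apply_exclusions_5fu requires a 5FU dataset")
    reasons = {"blq": 0, "clearance": 0}
    raw_obs = ds.n_observations()
    kept_patients = []
    removed = []
    for p in ds.patients:
        kept = []
        for o in p.observations:
            if o.value < blq_threshold:
                reasons["blq"] += 1
            elif implied_clearance(governing_dose(p, o), o.value) > cl_threshold:
                reasons["clearance"] += 1
            else:
                kept.append(o)
        if kept:
            kept_patients.append(PatientRecord(p.patient_id, dict(p.covariates),
                                               list(p.doses), kept))
        else:
            removed.append(p.patient_id)
    out = Dataset(kept_patients, ds.drug_type, ds.provenance)
    report = ExclusionReport(
        raw_observations={"parent": raw_obs},
        kept_observations={"parent": out.n_observations()},
        excluded_by_reason=reasons,
        raw_patients=ds.n_patients,
        kept_patients=out.n_patients,
        removed_patient_ids=tuple(removed),
    )
    return out, report


def apply_exclusions_sunitinib(ds, blq_threshold=BLQ_SUNITINIB_NG_ML):
    """Remove BLQ parent samples and their paired metabolite records.

    Parent observations below ``blq_threshold`` (ng/mL) are dropped together
    with the metabolite observation at the same (patient, time), keeping the
    parent and metabolite counts equal.  Idempotent.
    """
    if ds.drug_type != "sunitinib":
        raise ValueError("apply_exclusions_sunitinib requires a sunitinib dataset")
    raw_parent = ds.n_observations("parent")
    raw_metab = ds.n_observations("metab")
    n_blq = 0
    kept_patients = []
    removed = []
    for p in ds.patients:
        blq_times = {o.time for o in p.observations
                     if o.analyte == "parent" and o.value < blq_threshold}
        n_blq += sum(1 for o in p.observations
                     if o.analyte == "parent" and o.value < blq_threshold)
        kept = [o for o in p.observations if o.time not in blq_times]
        if kept:
            kept_patients.append(PatientRecord(p.patient_id, dict(p.covariates),
                                               list(p.doses), kept))
        else:
            removed.append(p.patient_id)
    out = Dataset(kept_patients, ds.drug_type, ds.provenance)
    report = ExclusionReport(
        raw_observations={"parent": raw_parent, "metab": raw_metab},
        kept_observations={"parent": out.n_observations("parent"),
                           "metab": out.n_observations("metab")},
        excluded_by_reason={"blq": n_blq,
                            "paired_metab": raw_metab - out.n_observations("metab")},
        raw_patients=ds.n_patients,
        kept_patients=out.n_patients,
        removed_patient_ids=tuple(removed),
    )
    return out, report


# ---------------------------------------------------------------------------
# splitting / imputation

def split_cv(ds, n_repeats=10, n_folds=5, seed=0):
    """Patient-level repeated k-fold splits; RNG fully determined by seed.

    Within each repeat the test folds partition the patients; each patient
    appears in a test fold exactly ``n_repeats`` times overall.
    """
    ids = np.array(sorted(p.patient_id for p in ds.patients))
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, have {len(ids)}")
    rng = np.random.default_rng(seed)
    splits = []
    for r in range(n_repeats):
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, n_folds)
        for f, test_ix in enumerate(folds):
            test = set(ids[test_ix])
            train = tuple(i for i in ids if i not in test)
            splits.append(CVSplit(r, f, train, tuple(sorted(test))))
    return splits


def impute_weight_by_sex(train, target):
    """Fill missing weights in ``target`` with train-set mean weight per sex.

    Statistics come from the training dataset only; ``train`` is never
    modified and ``target`` values never enter the means (leakage guard).
    """
    sums, counts = {}, {}
    for p in train.patients:
        sex, wt = p.covariates.get("sex"), p.covariates.get("weight")
        if sex is not None and wt is not None:
            sums[sex] = sums.get(sex, 0.0) + wt
            counts[sex] = counts.get(sex, 0) + 1
    means = {s: sums[s] / counts[s] for s in sums}
    out_patients = []
    for p in target.patients:
        cov = dict(p.covariates)
        if cov.get("weight") is None:
            sex = cov.get("sex")
            if sex is None:
                raise ValueError(
                    f"patient {p.patient_id}: cannot impute weight without sex")
            if sex not in means:
                label = "male" if sex == 1 else "female"
                raise ValueError(f"no observed training weights for sex {label!r}")
            cov["weight"] = means[sex]
        out_patients.append(PatientRecord(p.patient_id, cov,
                                          list(p.doses), list(p.observations)))
    return Dataset(out_patients, target.drug_type, target.provenance)
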