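"""Predictive metrics, prediction-corrected VPC and cross-validation orchestration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mmpk.data import split_cv, impute_weight_by_sex
from mmpk.training import TrainConfig, fit, predict_individual


@dataclass
class MetricReport:
    """Per-fold MAE/RMSE with mean +/- sample SD aggregation."""
    folds: list = field(default_factory=list)   # dicts: repeat, fold, mae, rmse, n

    def add(self, repeat, fold, mae, rmse, n):
        if not rmse >= mae >= 0:
            raise ValueError("expected RMSE >= MAE >= 0")
        self.folds.append({"repeat": repeat, "fold": fold,
                           "mae": mae, "rmse": rmse, "n": n})

    def aggregate(self, metric="mae", by="fold"):
        """Mean and sample SD of a metric across folds (or repeat averages)."""
        if by == "repeat":
            df = pd.DataFrame(self.folds).groupby("repeat")[metric].mean()
            vals = df.to_numpy()
        else:
            vals = np.array([f[metric] for f in self.folds])
        return aggregate_metrics(vals)

    def to_frame(self):
        return pd.DataFrame(self.folds)


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    percentiles: tuple
    observed: dict        # percentile -> per-bin observed pc statistic
    ci_lower: dict        # percentile -> per-bin lower CI bound (simulations)
    ci_upper: dict

    def median_within_ci(self):
        """Fraction of bins whose observed median lies inside its 90% CI."""
        lo, hi = self.ci_lower[50], self.ci_upper[50]
        ok = (self.observed[50] >= lo) & (self.observed[50] <= hi)
        return float(ok.mean()) if len(ok) else float("nan")


def compute_metrics(observed, predicted):
    """MAE and RMSE of predictions; RMSE >= MAE always (Jensen)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0 or observed.shape != predicted.shape:
        raise ValueError("inputs must be equal-length and nonempty")
    err = observed - predicted
    return {"mae": float(np.abs(err).mean()),
            "rmse": float(np.sqrt((err ** 2).mean()))}


def aggregate_metrics(values):
    """(mean, sample SD) with the n-1 denominator; SD is nan for a single value."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


# ---------------------------------------------------------------------------
# prediction-corrected VPC

def pcvpc(times, observed, pred_typical, sims, bin_edges=None, n_bins=8,
          percentiles=(5, 50, 95), ci=90.0):
    """Prediction-corrected visual predictive check.

    Each observation (and each simulated value at the same design point) is
    corrected by ``median(PRED in bin) / PRED_ij`` where PRED is the
    typical-value (eta = 0) prediction; observed 5/50/95 percentiles per bin
    are compared with the ``ci``% interval of the same statistic across
    simulated replicates.  ``bin_edges=None`` uses equal-count (quantile)
    edges; ``n_bins=1`` pools everything in a single bin.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=float)
    pred = np.asarray(pred_typical, dtype=float)
    sims = np.atleast_2d(np.asarray(sims, dtype=float))
    if np.any(pred <= 0):
        raise ValueError("typical predictions must be strictly positive")
    if sims.shape[1] != observed.size:
        raise ValueError("replicates must align with the observations")
    if bin_edges is None:
        if n_bins == 1:
            bin_edges = np.array([times.min(), times.max()])
        else:
            qs = np.linspace(0, 1, n_bins + 1)
            bin_edges = np.unique(np.quantile(times, qs))
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = len(bin_edges) - 1
    assign = np.clip(np.searchsorted(bin_edges, times, side="right") - 1, 0, nb - 1)
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0

    keep, mids, counts = [], [], []
    obs_stats = {p: [] for p in percentiles}
    lo_stats = {p: [] for p in percentiles}
    hi_stats = {p: [] for p in percentiles}
    for b in range(nb):
        ix = np.where(assign == b)[0]
        if ix.size == 0:
            warnings.warn(f"empty VPC bin {b}; dropped")
            continue
        med_pred = np.median(pred[ix])
        corr = med_pred / pred[ix]
        pc_obs = observed[ix] * corr
        pc_sim = sims[:, ix] * corr
        for p in percentiles:
            o = np.percentile(pc_obs, p)
            rep_stat = np.percentile(pc_sim, p, axis=1)
            obs_stats[p].append(o)
            lo_stats[p].append(np.percentile(rep_stat, lo_q))
            hi_stats[p].append(np.percentile(rep_stat, hi_q))
        keep.append(b)
        mids.append(0.5 * (bin_edges[b] + bin_edges[b + 1]))
        counts.append(ix.size)
    return VPCResult(
        bin_edges=bin_edges, bin_mid=np.array(mids), n_per_bin=np.array(counts),
        percentiles=tuple(percentiles),
        observed={p: np.array(v) for p, v in obs_stats.items()},
        ci_lower={p: np.array(v) for p, v in lo_stats.items()},
        ci_upper={p: np.array(v) for p, v in hi_stats.items()})


def gof_export(patient_ids, times, observed, predicted, path=None, fold=None):
    """Tidy observed-vs-predicted table plus identity-line summary statistics.

    Returns (DataFrame, stats) where stats holds the slope, intercept and
    Pearson R of the obs ~ pred regression; writes CSV when ``path`` given.
    """
    df = pd.DataFrame({
        "patient": list(patient_ids), "time": np.asarray(times, dtype=float),
        "observed": np.asarray(observed, dtype=float),
        "predicted": np.asarray(predicted, dtype=float),
    })
    if fold is not None:
        df["fold"] = fold
    if df["predicted"].nunique() > 1:
        reg = stats.linregress(df["predicted"], df["observed"])
        summary = {"slope": float(reg.slope), "intercept": float(reg.intercept),
                   "r": float(reg.rvalue)}
    else:
        summary = {"slope": float("nan"), "intercept": float("nan"),
                   "r": float("nan")}
    if path is not None:
        df.to_csv(path, index=False)
    return df, summary


# ---------------------------------------------------------------------------
# cross-validation

def _test_predictions(fit_result, test_ds, predict_mode):
    rows = []
    for p in test_ds.patients:
        if fit_result.drug_type == "fu5":
            pred = predict_individual(fit_result, p, mode=predict_mode)
            obs = [o for o in p.observations]
            for o, yh in zip(obs, pred):
                rows.append((p.patient_id, o.time, o.value, yh))
        else:
            prof = predict_individual(fit_result, p)
            for analyte in ("parent", "metab"):
                obs = sorted((o for o in p.observations if o.analyte == analyte),
                             key=lambda o: o.time)
                for o, yh in zip(obs, prof[analyte]):
                    rows.append((p.patient_id, o.time, o.value, yh))
    return rows


def run_cv(ds, drug_type=None, cfg=None, seed=0, n_repeats=10, n_folds=5,
           predict_mode="paper", impute=True, scheme="kfold"):
    """Repeated patient-stratified CV: fit on train, posterior-mean predict on test.

    Imputation and input-normalization statistics are computed inside each
    fold from its training patients only.  Fold seeds derive from the master
    seed.  ``scheme="random_split"`` keeps one fold per repeat, i.e.
    ``n_repeats`` independent random 80/20 splits instead of full k-fold.
    Returns (MetricReport, fits, gof DataFrame).
    """
    drug_type = drug_type or ds.drug_type
    cfg = cfg or TrainConfig()
    splits = split_cv(ds, n_repeats, n_folds, seed)
    if scheme == "random_split":
        splits = [s for s in splits if s.fold_index == 0]
    elif scheme != "kfold":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    seed_rng = np.random.default_rng(seed)
    fold_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=len(splits))
    report = MetricReport()
    fits, gof_frames = [], []
    for s, fseed in zip(splits, fold_seeds):
        train = ds.subset(s.train_patient_ids)
        test = ds.subset(s.test_patient_ids)
        if impute:
            try:
                test = impute_weight_by_sex(train, test)
                train = impute_weight_by_sex(train, train)
            except ValueError:
                pass    # no weights to impute from; encoder masks handle it
        try:
            fr = fit(train, drug_type, cfg, seed=int(fseed))
        except RuntimeError as e:
            raise RuntimeError(
                f"fold fit failed (repeat {s.repeat_index}, fold "
                f"{s.fold_index}): {e}") from e
        rows = _test_predictions(fr, test, predict_mode)
        obs = np.array([r[2] for r in rows])
        pred = np.array([r[3] for r in rows])
        m = compute_metrics(obs, pred)
        report.add(s.repeat_index, s.fold_index, m["mae"], m["rmse"], len(rows))
        df, _ = gof_export([r[0] for r in rows], [r[1] for r in rows], obs, pred,
                           fold=f"{s.repeat_index}.{s.fold_index}")
        gof_frames.append(df)
        fits.append(fr)
    gof = pd.concat(gof_frames, ignore_index=True) if gof_frames else pd.DataFrame()
    return report, fits, gof
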