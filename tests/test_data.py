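"""Event-record IO, exclusion filters, CV splitting and imputation."""

import io

import numpy as np
import pytest

from mmpk.data import (Dataset, DoseEvent, ObservationRecord, PatientRecord,
                       SchemaError, apply_exclusions_5fu,
                       apply_exclusions_sunitinib, implied_clearance,
                       impute_weight_by_sex, read_dataset, split_cv,
                       write_dataset)

CSV_HEADER = "ID,TIME,EVT,AMT,DUR,DV,ANALYTE,BLQ,SEX,AGE,WT,HT,BSA,LBM,FM"


def _make_fu5(values_by_patient, dose=4000.0, duration=24.0):
    patients = []
    for pid, values in values_by_patient.items():
        doses = [DoseEvent(pid, 0.0, dose, duration, "iv_infusion")]
        obs = [ObservationRecord(pid, 18.0 + j, v) for j, v in enumerate(values)]
        patients.append(PatientRecord(pid, {"sex": 1.0}, doses, obs))
    return Dataset(patients, "fu5")


class TestReadWrite:
    def test_three_row_file_parses_to_one_patient(self):
        text = (CSV_HEADER + "\n"
                "a,0,dose,4000,24,,,,1,60,70,170,1.9,55,15\n"
                "a,18,obs,,,0.7,parent,0,1,60,70,170,1.9,55,15\n"
                "a,20,obs,,,0.8,parent,0,1,60,70,170,1.9,55,15\n")
        ds = read_dataset(io.StringIO(text), "fu5")
        assert ds.n_patients == 1
        p = ds.patients[0]
        assert len(p.doses) == 1 and len(p.observations) == 2
        assert p.doses[0].amount == 4000.0
        assert p.doses[0].infusion_duration == 24.0

    def test_missing_id_column_raises_schema_error(self):
        text = CSV_HEADER.replace("ID,", "") + "\n"
        with pytest.raises(SchemaError, match="ID"):
            read_dataset(io.StringIO(text), "fu5")

    def test_missing_covariates_become_mask_not_sentinels(self):
        text = (CSV_HEADER + "\n"
                "a,0,dose,4000,24,,,,1,60,,,1.9,,\n"
                "a,18,obs,,,0.7,parent,0,1,60,,,1.9,,\n")
        ds = read_dataset(io.StringIO(text), "fu5")
        cov = ds.patients[0].covariates
        assert cov["weight"] is None and cov["height"] is None
        assert cov["bsa"] == 1.9
        vals, mask = ds.patients[0].covariate_vector()
        assert mask.sum() == 3  # sex, age, bsa observed

    def test_roundtrip_preserves_numeric_fields_exactly(self, toy_fu5_dataset):
        buf = io.StringIO()
        write_dataset(toy_fu5_dataset, buf)
        buf.seek(0)
        ds2 = read_dataset(buf, "fu5")
        for p1, p2 in zip(toy_fu5_dataset.patients, ds2.patients):
            assert p1.covariates == p2.covariates
            for d1, d2 in zip(p1.doses, p2.doses):
                assert (d1.time, d1.amount, d1.infusion_duration) == \
                    (d2.time, d2.amount, d2.infusion_duration)
            for o1, o2 in zip(p1.observations, p2.observations):
                assert (o1.time, o1.value, o1.analyte) == \
                    (o2.time, o2.value, o2.analyte)


class TestExclusions5FU:
    def test_implied_clearance_examples(self):
        d = DoseEvent("a", 0.0, 4000.0, 24.0, "iv_infusion")
        assert implied_clearance(d, 0.70) == pytest.approx(238.0952, abs=1e-3)
        assert implied_clearance(d, 0.10) == pytest.approx(1666.6667, abs=1e-3)

    def test_kept_and_excluded_by_rule(self):
        # 0.70 mg/L -> CL 238 kept; 0.10 -> CL 1667 excluded; 0.03 -> BLQ
        ds = _make_fu5({"a": [0.70, 0.10], "b": [0.03, 0.70]})
        out, rep = apply_exclusions_5fu(ds)
        assert out.n_observations() == 2
        assert rep.excluded_by_reason == {"blq": 1, "clearance": 1}

    def test_patient_with_no_remaining_observations_is_removed(self):
        ds = _make_fu5({"a": [0.03], "b": [0.70]})
        out, rep = apply_exclusions_5fu(ds)
        assert out.n_patients == 1
        assert rep.removed_patient_ids == ("a",)

    def test_filter_is_idempotent_and_counts_balance(self):
        ds = _make_fu5({"a": [0.70, 0.10, 0.03], "b": [0.70]})
        once, rep1 = apply_exclusions_5fu(ds)
        twice, rep2 = apply_exclusions_5fu(once)
        assert twice.n_observations() == once.n_observations()
        assert rep2.n_excluded == 0
        assert rep1.n_excluded + once.n_observations() == ds.n_observations()


class TestExclusionsSunitinib:
    def _ds(self, parent_values):
        pid = "s1"
        doses = [DoseEvent(pid, 24.0 * d, 37.5, 0.0, "oral") for d in range(3)]
        obs = []
        for j, v in enumerate(parent_values):
            t = 24.0 * (j + 1) - 0.5
            obs.append(ObservationRecord(pid, t, v, "parent"))
            obs.append(ObservationRecord(pid, t, v * 0.4, "metab"))
        return Dataset([PatientRecord(pid, {}, doses, obs)], "sunitinib")

    def test_blq_parent_removes_paired_metabolite(self):
        ds = self._ds([0.05, 0.07, 30.0])
        out, rep = apply_exclusions_sunitinib(ds)
        assert out.n_observations("parent") == 2
        assert out.n_observations("metab") == 2
        assert rep.excluded_by_reason["blq"] == 1

    def test_above_threshold_kept(self):
        ds = self._ds([0.07])
        out, _ = apply_exclusions_sunitinib(ds)
        assert out.n_observations("parent") == 1

    def test_counts_stay_paired(self):
        ds = self._ds([0.05, 0.01, 20.0, 30.0])
        out, _ = apply_exclusions_sunitinib(ds)
        assert out.n_observations("parent") == out.n_observations("metab")


class TestSplitCV:
    def test_one_repeat_partitions_patients(self):
        ds = _make_fu5({f"p{i}": [0.7] for i in range(10)})
        splits = split_cv(ds, n_repeats=1, n_folds=5, seed=0)
        assert len(splits) == 5
        all_test = [pid for s in splits for pid in s.test_patient_ids]
        assert sorted(all_test) == sorted(p.patient_id for p in ds.patients)
        for s in splits:
            assert len(s.test_patient_ids) == 2
            assert not set(s.train_patient_ids) & set(s.test_patient_ids)

    def test_each_patient_tested_n_repeats_times(self):
        ds = _make_fu5({f"p{i}": [0.7] for i in range(11)})
        splits = split_cv(ds, n_repeats=4, n_folds=5, seed=1)
        from collections import Counter
        c = Counter(pid for s in splits for pid in s.test_patient_ids)
        assert set(c.values()) == {4}

    def test_same_seed_reproduces_splits(self):
        ds = _make_fu5({f"p{i}": [0.7] for i in range(10)})
        assert split_cv(ds, 2, 5, seed=42) == split_cv(ds, 2, 5, seed=42)

    def test_too_few_patients_raises(self):
        ds = _make_fu5({"a": [0.7], "b": [0.7]})
        with pytest.raises(ValueError):
            split_cv(ds, 1, 5, seed=0)


class TestImputation:
    def _patient(self, pid, sex, weight):
        return PatientRecord(pid, {"sex": sex, "weight": weight},
                             [DoseEvent(pid, 0.0, 4000.0, 24.0)],
                             [ObservationRecord(pid, 18.0, 0.7)])

    def test_mean_by_sex(self):
        train = Dataset([self._patient("a", 1.0, 70.0),
                         self._patient("b", 1.0, 90.0),
                         self._patient("c", 0.0, 60.0)], "fu5")
        target = Dataset([self._patient("x", 1.0, None)], "fu5")
        out = impute_weight_by_sex(train, target)
        assert out.patients[0].covariates["weight"] == pytest.approx(80.0)

    def test_no_missing_weights_returns_unchanged_values(self):
        train = Dataset([self._patient("a", 1.0, 70.0)], "fu5")
        target = Dataset([self._patient("x", 1.0, 85.0)], "fu5")
        out = impute_weight_by_sex(train, target)
        assert out.patients[0].covariates["weight"] == 85.0

    def test_statistics_come_from_train_only(self):
        train = Dataset([self._patient("a", 1.0, 70.0),
                         self._patient("b", 1.0, 90.0)], "fu5")
        # the target's own observed weight (200) must not shift the mean
        target = Dataset([self._patient("x", 1.0, 200.0),
                          self._patient("y", 1.0, None)], "fu5")
        out = impute_weight_by_sex(train, target)
        assert out.patient("y").covariates["weight"] == pytest.approx(80.0)
        assert train.patient("a").covariates["weight"] == 70.0

    def test_missing_sex_group_raises(self):
        train = Dataset([self._patient("a", 1.0, 70.0)], "fu5")
        target = Dataset([self._patient("x", 0.0, None)], "fu5")
        with pytest.raises(ValueError, match="female"):
            impute_weight_by_sex(train, target)
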