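"""Cohort generators: degenerate limits, statistical targets, fixtures."""

import io

import numpy as np
import pytest

from mmpk.data import (apply_exclusions_5fu, apply_exclusions_sunitinib,
                       write_dataset)
from mmpk.odes import css_5fu
from mmpk.synthetic import (CohortConfig5FU, CohortConfigSunitinib,
                            du_bois_bsa, generate_5fu_cohort,
                            generate_acceptance_fixture_5fu,
                            generate_acceptance_fixture_sunitinib,
                            generate_sunitinib_cohort, james_lbm)


def _as_text(ds):
    buf = io.StringIO()
    write_dataset(ds, buf)
    return buf.getvalue()


class TestGenerator5FU:
    def test_degenerate_generator_reproduces_closed_form(self):
        cfg = CohortConfig5FU(n_patients=10, omega=0.0, error_b=1e-12,
                              bsa_slope=0.0)
        ds, gt = generate_5fu_cohort(cfg, seed=0)
        for p in ds.patients:
            d = p.doses[0]
            expected = css_5fu(d.amount, d.infusion_duration, cfg.tv_cl)
            for o in p.observations:
                assert o.value == pytest.approx(expected, rel=1e-9)

    def test_iiv_spread_matches_omega_at_large_n(self):
        cfg = CohortConfig5FU(n_patients=5000, bsa_slope=0.0)
        _, gt = generate_5fu_cohort(cfg, seed=1)
        log_cl = np.log([v["CL"] for v in gt.theta.values()])
        assert 0.29 <= np.std(log_cl) <= 0.31

    def test_bsa_effect_recoverable_by_regression(self):
        cfg = CohortConfig5FU(n_patients=2000, bsa_slope=80.0)
        ds, gt = generate_5fu_cohort(cfg, seed=2)
        bsa = np.array([p.covariates["bsa"] for p in ds.patients])
        log_cl = np.log([gt.theta[p.patient_id]["CL"] for p in ds.patients])
        slope = np.polyfit(bsa, log_cl, 1)[0]
        assert slope > 0.1

    def test_covariates_consistent_with_du_bois_and_james(self):
        ds, _ = generate_5fu_cohort(CohortConfig5FU(n_patients=50), seed=3)
        for p in ds.patients:
            c = p.covariates
            assert c["bsa"] == pytest.approx(
                du_bois_bsa(c["weight"], c["height"]), rel=1e-9)
            assert c["lbm"] == pytest.approx(
                james_lbm(c["weight"], c["height"], c["sex"]), rel=1e-9)
            assert c["fm"] == pytest.approx(c["weight"] - c["lbm"], rel=1e-9)

    def test_sampling_times_inside_window(self):
        cfg = CohortConfig5FU(n_patients=100)
        ds, _ = generate_5fu_cohort(cfg, seed=4)
        for p in ds.patients:
            for o in p.observations:
                within = o.time % cfg.occasion_spacing
                assert cfg.sample_window[0] <= within <= cfg.sample_window[1]

    def test_noise_free_values_consistent_with_emitted_data(self):
        cfg = CohortConfig5FU(n_patients=20)
        ds, gt = generate_5fu_cohort(cfg, seed=5)
        for p in ds.patients:
            times, clean = gt.clean[p.patient_id]["parent"]
            obs = np.array([o.value for o in p.observations])
            # proportional error: |y - c| plausible under 5 sigma
            assert np.all(np.abs(obs - clean) <= 5.5 * cfg.error_b * clean + 1e-5)


class TestGeneratorSunitinib:
    def test_no_iiv_no_noise_gives_identical_profiles_at_equal_weight(self):
        cfg = CohortConfigSunitinib(
            n_patients=2, iiv_sd={"CLS": 0.0, "V2S": 0.0, "FM": 0.0, "V2M": 0.0},
            error_b_parent=1e-12, error_b_metab=1e-12, max_cycles=2,
            doses_mg=(37.5,), dose_probs=(1.0,),
            missing_weight=0.0, missing_height=0.0, missing_bsa=0.0)
        ds, gt = generate_sunitinib_cohort(cfg, seed=6, n_samples_override=4)
        p1, p2 = ds.patients
        # equalize weight through ground truth comparison at same times
        c1 = gt.clean[p1.patient_id]["parent"][1]
        assert np.all(c1 > 0)
        if p1.covariates["weight"] == p2.covariates["weight"]:
            assert np.allclose(c1, gt.clean[p2.patient_id]["parent"][1])

    def test_trough_times_strictly_before_daily_dose(self):
        ds, _ = generate_sunitinib_cohort(
            CohortConfigSunitinib(n_patients=20), seed=7)
        for p in ds.patients:
            dose_times = {d.time for d in p.doses}
            for o in p.observations:
                next_dose = min((t for t in dose_times if t >= o.time),
                                default=None)
                assert next_dose is not None and next_dose > o.time

    def test_missingness_rates_near_configured_values(self):
        cfg = CohortConfigSunitinib(n_patients=5000, max_cycles=2)
        ds, _ = generate_sunitinib_cohort(cfg, seed=8, n_samples_override=1)
        missing = {"weight": 0, "height": 0, "bsa": 0}
        for p in ds.patients:
            for k in missing:
                missing[k] += p.covariates[k] is None
        n = ds.n_patients
        assert abs(missing["weight"] / n - 0.129) < 0.02
        assert abs(missing["height"] / n - 0.109) < 0.02
        assert abs(missing["bsa"] / n - 0.066) < 0.02

    def test_parent_and_metabolite_paired_by_time(self):
        ds, _ = generate_sunitinib_cohort(
            CohortConfigSunitinib(n_patients=10), seed=9)
        for p in ds.patients:
            t_parent = sorted(o.time for o in p.observations
                              if o.analyte == "parent")
            t_metab = sorted(o.time for o in p.observations
                             if o.analyte == "metab")
            assert t_parent == t_metab


class TestFixtures:
    def test_5fu_fixture_counts_and_filtering(self):
        ds = generate_acceptance_fixture_5fu()
        assert ds.n_patients == 157
        assert ds.n_observations() == 549
        out, rep = apply_exclusions_5fu(ds)
        assert rep.n_excluded == 8
        assert out.n_observations() == 541
        assert out.n_patients == 156

    def test_5fu_fixture_violations_on_distinct_patients(self):
        ds = generate_acceptance_fixture_5fu()
        _, rep = apply_exclusions_5fu(ds)
        assert len(rep.removed_patient_ids) == 1
        # the removed patient had a single observation
        removed = ds.patient(rep.removed_patient_ids[0])
        assert len(removed.observations) == 1

    def test_sunitinib_fixture_counts_and_filtering(self):
        ds = generate_acceptance_fixture_sunitinib()
        assert ds.n_patients == 47
        assert ds.n_observations("parent") == 308
        assert ds.n_observations("metab") == 308
        out, rep = apply_exclusions_sunitinib(ds)
        assert out.n_observations("parent") == 302
        assert out.n_observations("metab") == 302
        assert out.n_patients == 47
        assert rep.excluded_by_reason["blq"] == 6
        assert rep.excluded_fraction("parent") == pytest.approx(6 / 308)

    def test_sunitinib_blq_spread_over_five_patients(self):
        ds = generate_acceptance_fixture_sunitinib()
        carriers = {p.patient_id for p in ds.patients
                    for o in p.observations
                    if o.analyte == "parent" and o.value < 0.06}
        assert len(carriers) == 5

    def test_fixtures_are_byte_identical_across_calls(self):
        assert _as_text(generate_acceptance_fixture_5fu()) == \
            _as_text(generate_acceptance_fixture_5fu())
        assert _as_text(generate_acceptance_fixture_sunitinib()) == \
            _as_text(generate_acceptance_fixture_sunitinib())
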