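"""Full-protocol orchestration: induction, twin simulation, sampling."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rocoloop import (
    PatientCovariates,
    TrialConfig,
    VariabilityConfig,
    default_pd,
    ideal_body_weight,
    nominal_pk_for_weight,
    sample_patient,
    simulate_schedule,
)
from rocoloop.trial import run_case, run_cohort

COV = PatientCovariates(height_m=1.61, weight_kg=63.0, sex="F", age_y=59.0)
NOM = nominal_pk_for_weight(63.0)


def nominal_case(seed=1, **case_kwargs):
    """Noise-free patient identical to the nominal model."""
    pd_clean = default_pd(noise_sd=0.0)
    pat = sample_patient(COV, NOM, pd_clean, VariabilityConfig.none(), 0)
    return run_case(pat, NOM, pd_clean, seed=seed, **case_kwargs)


class TestNullCase:
    def test_measured_equals_predicted_before_reversal(self):
        case = nominal_case()
        frame = case.records_frame()
        pre = frame[frame.condition != "post_sugammadex_5min"]
        assert len(pre) == 3
        np.testing.assert_array_equal(
            pre.measured_cp_ug_ml.to_numpy(), pre.predicted_cp_ug_ml.to_numpy())

    def test_all_four_conditions_sampled(self):
        case = nominal_case()
        assert [r.condition for r in case.records] == [
            "recovery_3pct", "stable_period", "cessation", "post_sugammadex_5min"]
        assert case.flags == []


class TestInduction:
    def test_nominal_patient_needs_no_rescue(self):
        case = nominal_case()
        ibw = ideal_body_weight(COV.height_m)
        assert case.induction_dose_mg == pytest.approx(0.6 * ibw)
        assert "rescue_bolus" not in case.events

    def test_resistant_patient_gets_exactly_one_rescue_capped_at_0_9(self):
        pd_clean = default_pd(noise_sd=0.0)
        pat = sample_patient(COV, NOM, pd_clean, VariabilityConfig.none(), 0)
        resistant = replace(pat, true_pd=replace(pat.true_pd, ec50=3.0))
        case = run_case(resistant, NOM, pd_clean, seed=1)
        ibw = ideal_body_weight(COV.height_m)
        assert "rescue_bolus" in case.events
        assert case.events["rescue_bolus"] == pytest.approx(1.0)
        assert case.induction_dose_mg == pytest.approx(0.9 * ibw)
        boluses = [e for e in case.schedule.events if e.kind == "bolus"]
        assert len(boluses) == 2
        assert sum(b.value for b in boluses) <= 0.9 * ibw + 1e-9

    def test_induction_cap_never_exceeded_across_cohort(self):
        cohort = run_cohort(6, 42)
        for _, row in cohort.patients.iterrows():
            assert row.induction_dose_mg <= 0.9 * row.ibw_kg + 1e-9


class TestProtocolTiming:
    def test_stable_sample_respects_window_and_earliest_time(self):
        case = nominal_case()
        t_stable = case.events["stable_period"]
        t_start = case.events["infusion_start"]
        assert t_stable - t_start >= 60.0 + 15.0 - 1e-9
        tw = case.twitch
        window = tw[(tw.time_min >= t_stable - 15.0) & (tw.time_min <= t_stable)]
        assert ((window.t1_percent >= 3.0) & (window.t1_percent <= 10.0)).all()

    def test_cessation_follows_maintenance_duration_in_band(self):
        case = nominal_case()
        t_cess = case.events["cessation"]
        assert t_cess >= case.events["infusion_start"] + 150.0 - 1e-9
        assert case.events["sugammadex"] == t_cess
        final = case.records[-1]
        assert final.t == pytest.approx(t_cess + 5.0, abs=0.05)

    def test_recovery_event_precedes_infusion_start(self):
        case = nominal_case()
        assert case.events["tofc1"] <= case.events["recovery_3pct"]
        assert case.events["recovery_3pct"] <= case.events["infusion_start"]


class TestTwinSimulation:
    def test_predicted_track_replays_from_dose_schedule(self):
        # the central design: predictions depend only on the shared dose history
        case = nominal_case()
        times = case.series_nominal.times
        replay = simulate_schedule(case.schedule, NOM, grid_dt=1.0, t_end=times[-1])
        # match replay grid points to the nearest in-case sample (grids differ)
        idx = np.abs(times[None, :] - replay.times[:, None]).argmin(axis=1)
        close = np.abs(times[idx] - replay.times) < 1e-6
        assert close.sum() > 100
        np.testing.assert_allclose(
            replay.cp[close], case.series_nominal.cp[idx[close]],
            rtol=1e-9, atol=1e-12)

    def test_post_reversal_measured_exceeds_predicted_with_inflation(self):
        pd_clean = default_pd(noise_sd=0.0)
        var = VariabilityConfig(pk_cv=0, ec50_cv=0, gamma_cv=0, assay_cv=0,
                                post_reversal_inflation=1.47)
        pat = sample_patient(COV, NOM, pd_clean, var, 0)
        case = run_case(pat, NOM, pd_clean, seed=1)
        rec = {r.condition: r for r in case.records}
        post = rec["post_sugammadex_5min"]
        assert post.measured_cp / post.predicted_cp == pytest.approx(1.47)

    def test_tof_recovery_checked_and_reached(self):
        case = nominal_case()
        assert case.recovery_time_min is not None
        assert case.recovery_time_min <= 3.0
        assert len(case.sugammadex_doses_mg) == 1
        assert case.sugammadex_doses_mg[0] == pytest.approx(2.0 * COV.weight_kg)

    def test_slow_reversal_triggers_rescue_sugammadex(self):
        cfg = TrialConfig(reversal_tau=60.0)  # washout too slow to recover by 3 min
        case = nominal_case(trial=cfg)
        assert "sugammadex_rescue" in case.flags
        assert len(case.sugammadex_doses_mg) == 2


class TestCohort:
    def test_single_patient_null_cohort_zero_errors(self):
        coh = run_cohort(1, 5, VariabilityConfig.none(), default_pd(noise_sd=0.0))
        m = coh.metrics.set_index("condition")
        for cond in ("recovery_3pct", "stable_period", "cessation"):
            assert m.loc[cond, "mdpe_pct"] == 0.0
            assert m.loc[cond, "mdape_pct"] == 0.0

    def test_default_cohort_runs_to_completion(self):
        coh = run_cohort(5, 7)
        counts = coh.records.groupby("patient_id").size()
        assert (counts >= 3).all()  # stable window may be flagged incomplete
        assert (counts <= 4).all()

    def test_same_master_seed_identical_tables(self):
        a = run_cohort(3, 99)
        b = run_cohort(3, 99)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_invalid_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            run_cohort(0, 1)
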