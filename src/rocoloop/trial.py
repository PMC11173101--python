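"""In-silico study protocol: induction, closed-loop maintenance, reversal.

One case runs a *twin* simulation on a shared administration history:

* the patient's **true** PK/PD generates the monitor readings and the
  synthetic "measured" blood concentrations;
* the **nominal** (population) PK generates the predicted concentrations
  the controller and the TCI engine act on.

Protocol per case (times in minutes, t = 0 at the first bolus):

1. Induction: 0.6 mg·kg⁻¹ of ideal body weight as a bolus; if a twitch is
   still detectable at 1 min, one rescue bolus of 0.3 mg·kg⁻¹ (cumulative
   induction capped at 0.9 mg·kg⁻¹ IBW).
2. When the first twitch reappears (TOFC = 1) the nominal effect-site
   concentration at that event becomes the initial target.  When %T1
   recovers to ≥ 3 % the first blood sample is drawn, the target is
   revised to the concentration giving %T1 = 5 under the population PD
   model, and continuous infusion starts under the 12-s feedback rules.
3. A stable-period sample is drawn once %T1 (5-min moving average) has
   stayed in the 3–10 % band for 15 continuous minutes beginning at least
   60 min after the infusion started.
4. After the configured maintenance duration, once %T1 is in-band, the
   infusion stops, a cessation sample is drawn, and sugammadex
   (2 mg·kg⁻¹) is given.  Reversal is represented by an exponential
   washout of the *effective* Ce seen by the PD model (an empirical
   surrogate — encapsulation kinetics are out of scope), the TOF-ratio
   ≥ 0.9 criterion is checked at 3 min (one 0.5 mg·kg⁻¹ rescue dose
   otherwise), and the final sample is drawn at 5 min, where the measured
   value carries the post-reversal inflation factor.

Monitor readings are generated every 10 s and carried forward to the
controller's 12-s grid; event detection is debounced (see docs/methods).
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import controller as ctl
from .cohort import (
    VariabilityConfig,
    VirtualPatient,
    cohort_frame,
    ideal_body_weight,
    measure_concentration,
    sample_covariates,
    sample_patient,
)
from .config import default_pd, nominal_pk_for_weight
from .metrics import evaluate_records
from .pd_model import PDParameterSet, reading_from_ce
from .pk import ConcentrationSeries, DoseEvent, DoseSchedule, PKParameterSet, discretize
from .tci import PumpLimits, rate_from_vector

__all__ = [
    "TrialConfig",
    "SamplingRecord",
    "CaseResult",
    "CohortResult",
    "CONDITIONS",
    "run_case",
    "run_cohort",
]

#: simulation grid: 2-s steps; readings every 5 steps, controller every 6
STEP_MIN = 1.0 / 30.0
READ_EVERY = 5
TICK_EVERY = 6

CONDITIONS = (
    "recovery_3pct",
    "stable_period",
    "cessation",
    "post_sugammadex_5min",
)


@dataclass(frozen=True)
class TrialConfig:
    """Protocol constants of one simulated case (doses per kg of IBW)."""

    induction_dose_per_kg: float = 0.6
    rescue_dose_per_kg: float = 0.3
    induction_cap_per_kg: float = 0.9
    rescue_check_time: float = 1.0
    stable_window: float = 15.0
    stable_earliest: float = 60.0
    stable_smooth: float = 5.0
    maintenance_duration: float = 150.0
    max_case_duration: float = 360.0
    sugammadex_dose_per_kg: float = 2.0
    sugammadex_rescue_per_kg: float = 0.5
    sugammadex_rescue_check: float = 3.0
    tof_recovery_threshold: float = 0.9
    post_reversal_sample_delay: float = 5.0
    reversal_tau: float = 1.5
    debounce_tofc: int = 6
    debounce_t1: int = 3

    def __post_init__(self) -> None:
        for f_ in (
            "induction_dose_per_kg", "rescue_dose_per_kg", "induction_cap_per_kg",
            "rescue_check_time", "stable_window", "stable_earliest", "stable_smooth",
            "maintenance_duration", "max_case_duration", "sugammadex_dose_per_kg",
            "sugammadex_rescue_per_kg", "sugammadex_rescue_check",
            "post_reversal_sample_delay", "reversal_tau",
        ):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")
        if self.induction_cap_per_kg < self.induction_dose_per_kg + self.rescue_dose_per_kg:
            raise ValueError("induction cap must cover initial + rescue dose")
        if not (0 < self.tof_recovery_threshold <= 1):
            raise ValueError("tof_recovery_threshold must be in (0, 1]")
        if min(self.debounce_tofc, self.debounce_t1) < 1:
            raise ValueError("debounce counts must be >= 1")


@dataclass(frozen=True)
class SamplingRecord:
    """Predicted/measured concentration pair at one protocol time point."""

    patient_id: int
    condition: str
    t: float
    predicted_cp: float
    measured_cp: float
    predicted_ce: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if min(self.predicted_cp, self.measured_cp, self.predicted_ce) < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class CaseResult:
    patient: VirtualPatient
    patient_id: int
    schedule: DoseSchedule
    records: list[SamplingRecord]
    events: dict[str, float]
    flags: list[str]
    induction_dose_mg: float
    in_band_fraction: float
    recovery_time_min: Optional[float]
    sugammadex_doses_mg: list[float]
    twitch: Optional[pd.DataFrame] = None
    controller_log: Optional[pd.DataFrame] = None
    series_nominal: Optional[ConcentrationSeries] = None
    series_true: Optional[ConcentrationSeries] = None

    def records_frame(self) -> pd.DataFrame:
        return records_frame(self.records)


def records_frame(records: list[SamplingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "condition": r.condition,
                "time_min": r.t,
                "predicted_cp_ug_ml": r.predicted_cp,
                "measured_cp_ug_ml": r.measured_cp,
                "predicted_ce_ug_ml": r.predicted_ce,
            }
            for r in records
        ],
        columns=[
            "patient_id", "condition", "time_min",
            "predicted_cp_ug_ml", "measured_cp_ug_ml", "predicted_ce_ug_ml",
        ],
    )


def run_case(
    patient: VirtualPatient,
    nominal_pk: PKParameterSet,
    nominal_pd: PDParameterSet,
    trial: TrialConfig | None = None,
    controller_cfg: ctl.ControllerConfig | None = None,
    limits: PumpLimits | None = None,
    seed: int = 0,
    patient_id: int = 0,
    keep_series: bool = True,
) -> CaseResult:
    """Simulate one full case; see the module docstring for the protocol."""
    trial = trial or TrialConfig()
    cfg = controller_cfg or ctl.ControllerConfig()
    limits = limits or PumpLimits()

    root = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(root.integers(2**31))
    rng_assay = np.random.default_rng(root.integers(2**31))

    Et, st = discretize(patient.true_pk, STEP_MIN)
    En, sn = discretize(nominal_pk, STEP_MIN)
    v_true, v_nom = patient.true_pk.v1, nominal_pk.v1
    x_t = np.zeros(5)
    x_n = np.zeros(5)

    ibw = ideal_body_weight(patient.covariates.height_m)
    cap_mg = trial.induction_cap_per_kg * ibw
    d0 = trial.induction_dose_per_kg * ibw
    schedule = DoseSchedule([DoseEvent(0.0, "bolus", d0)])
    x_t[0] += d0
    x_n[0] += d0
    induction_given = d0

    # per-reading logs (10-s cadence)
    r_t: list[float] = []
    r_t1: list[float] = []
    r_count: list[int] = []
    r_ratio: list[Optional[float]] = []
    r_cpn: list[float] = []
    r_cen: list[float] = []
    r_cpt: list[float] = []
    ctrl_rows: list[tuple] = []
    ser_rows: list[tuple] = [] if keep_series else None  # type: ignore[assignment]

    records: list[SamplingRecord] = []
    flags: list[str] = []
    events: dict[str, float] = {}
    sugammadex_doses: list[float] = []

    phase = "induction"
    rate = 0.0
    cstate: Optional[ctl.ControllerState] = None
    latest = None
    block_seen = False
    rescued = False
    run_count = 0          # consecutive detectable-twitch readings (TOFC event)
    run_count_start = -1
    run_t1 = 0             # consecutive readings with %T1 >= band_low
    run_t1_start = -1
    smooth_n = max(1, int(round(trial.stable_smooth / (STEP_MIN * READ_EVERY))))
    stable_run_start: Optional[float] = None
    stable_done = False
    infusion_start = math.nan
    t_cess = math.nan
    recovery_time: Optional[float] = None
    recovery_checked = False

    rescue_step = int(round(trial.rescue_check_time / STEP_MIN))
    max_steps = int(round(trial.max_case_duration / STEP_MIN)) + int(round(10 / STEP_MIN))
    cess_step = -1

    i = 0
    while True:
        i += 1
        if i > max_steps:
            flags.append("incomplete_timeout")
            break
        x_t = Et @ x_t + st * rate
        x_n = En @ x_n + sn * rate
        t = i * STEP_MIN

        if keep_series:
            ser_rows.append((t, x_n[0] / v_nom, x_n[3], x_t[0] / v_true, x_t[3]))

        new_reading = i % READ_EVERY == 0
        if new_reading:
            ce_eff = x_t[3]
            if phase == "reversal":
                ce_eff *= math.exp(-(t - t_cess) / trial.reversal_tau)
            latest = reading_from_ce(ce_eff, patient.true_pd, rng_noise, t=t)
            r_t.append(t)
            r_t1.append(latest.t1_percent)
            r_count.append(latest.tof_count)
            r_ratio.append(latest.tof_ratio)
            r_cpn.append(x_n[0] / v_nom)
            r_cen.append(x_n[3])
            r_cpt.append(x_t[0] / v_true)

        if phase == "induction":
            if i == rescue_step and not rescued:
                rescued = True
                if latest is not None and latest.tof_count >= 1:
                    extra = min(trial.rescue_dose_per_kg * ibw, cap_mg - induction_given)
                    if extra > 0:
                        schedule.append(DoseEvent(t, "bolus", extra))
                        x_t[0] += extra
                        x_n[0] += extra
                        induction_given += extra
                        events["rescue_bolus"] = t
            if new_reading:
                idx = len(r_t) - 1
                if latest.tof_count == 0:
                    block_seen = True
                    run_count = 0
                elif block_seen:
                    if run_count == 0:
                        run_count_start = idx
                    run_count += 1
                    if run_count >= trial.debounce_tofc and cstate is None:
                        j = run_count_start
                        events["tofc1"] = r_t[j]
                        cstate = ctl.initialize_target(max(r_cen[j], 1e-9))
                if cstate is not None:
                    if latest.t1_percent >= cfg.band_low:
                        if run_t1 == 0:
                            run_t1_start = idx
                        run_t1 += 1
                        if run_t1 >= trial.debounce_t1:
                            j = run_t1_start
                            events["recovery_3pct"] = r_t[j]
                            records.append(SamplingRecord(
                                patient_id, "recovery_3pct", r_t[j],
                                predicted_cp=r_cpn[j],
                                measured_cp=measure_concentration(
                                    r_cpt[j], patient, "pre", rng_assay),
                                predicted_ce=r_cen[j],
                            ))
                            cstate = ctl.revise_target_for_t1(cstate, nominal_pd, cfg)
                            infusion_start = t
                            events["infusion_start"] = t
                            phase = "maintenance"
                    else:
                        run_t1 = 0

        elif phase == "maintenance":
            if i % TICK_EVERY == 0 and latest is not None:
                cstate, target, fired = ctl.tick(cstate, latest, t, cfg)
                new_rate = rate_from_vector(x_n, target, cfg.tick, nominal_pk, limits)
                if new_rate != rate:
                    schedule.append(DoseEvent(t, "rate", new_rate))
                    rate = new_rate
                ctrl_rows.append((t, latest.t1_percent, fired, target, rate))
            if new_reading and not stable_done:
                if len(r_t1) >= smooth_n:
                    smoothed = float(np.mean(r_t1[-smooth_n:]))
                    if cfg.band_low <= smoothed <= cfg.band_high:
                        if stable_run_start is None:
                            stable_run_start = t
                        eligible = max(stable_run_start, infusion_start + trial.stable_earliest)
                        if t - eligible >= trial.stable_window:
                            events["stable_period"] = t
                            records.append(SamplingRecord(
                                patient_id, "stable_period", t,
                                predicted_cp=x_n[0] / v_nom,
                                measured_cp=measure_concentration(
                                    x_t[0] / v_true, patient, "pre", rng_assay),
                                predicted_ce=x_n[3],
                            ))
                            stable_done = True
                    else:
                        stable_run_start = None
            due = t >= infusion_start + trial.maintenance_duration
            forced = t >= trial.max_case_duration - trial.post_reversal_sample_delay - 1.0
            if (due and latest is not None
                    and cfg.band_low <= latest.t1_percent <= cfg.band_high) or forced:
                if forced and not due:
                    flags.append("forced_cessation")
                if not stable_done:
                    flags.append("incomplete_stable_window")
                if rate > 0:
                    schedule.append(DoseEvent(t, "rate", 0.0))
                    rate = 0.0
                t_cess = t
                cess_step = i
                events["cessation"] = t
                records.append(SamplingRecord(
                    patient_id, "cessation", t,
                    predicted_cp=x_n[0] / v_nom,
                    measured_cp=measure_concentration(
                        x_t[0] / v_true, patient, "pre", rng_assay),
                    predicted_ce=x_n[3],
                ))
                sugammadex_doses.append(
                    trial.sugammadex_dose_per_kg * patient.covariates.weight_kg)
                events["sugammadex"] = t
                phase = "reversal"

        elif phase == "reversal":
            if new_reading and recovery_time is None:
                if latest.tof_ratio is not None and latest.tof_ratio >= trial.tof_recovery_threshold:
                    recovery_time = t - t_cess
                    events["tof_recovery"] = t
            if (not recovery_checked
                    and i >= cess_step + int(round(trial.sugammadex_rescue_check / STEP_MIN))):
                recovery_checked = True
                if recovery_time is None:
                    sugammadex_doses.append(
                        trial.sugammadex_rescue_per_kg * patient.covariates.weight_kg)
                    events["sugammadex_rescue"] = t
                    flags.append("sugammadex_rescue")
            if i == cess_step + int(round(trial.post_reversal_sample_delay / STEP_MIN)):
                records.append(SamplingRecord(
                    patient_id, "post_sugammadex_5min", t,
                    predicted_cp=x_n[0] / v_nom,
                    measured_cp=measure_concentration(
                        x_t[0] / v_true, patient, "post_reversal", rng_assay),
                    predicted_ce=x_n[3],
                ))
            if t >= t_cess + trial.post_reversal_sample_delay + 1.0:
                break

    # maintenance in-band fraction from the twitch log
    in_band = 0
    n_maint = 0
    if not math.isnan(infusion_start):
        end = t_cess if not math.isnan(t_cess) else r_t[-1]
        for tt, t1 in zip(r_t, r_t1):
            if infusion_start <= tt <= end:
                n_maint += 1
                if cfg.band_low <= t1 <= cfg.band_high:
                    in_band += 1
    in_band_fraction = in_band / n_maint if n_maint else math.nan

    twitch = pd.DataFrame({
        "time_min": r_t,
        "t1_percent": r_t1,
        "tof_count": r_count,
        "tof_ratio": [np.nan if v is None else v for v in r_ratio],
    })
    controller_log = pd.DataFrame(
        ctrl_rows,
        columns=["time_min", "t1_percent", "rule_fired", "target_ug_ml",
                 "commanded_rate_mg_min"],
    )
    series_nominal = series_true = None
    if keep_series:
        arr = np.array(ser_rows)
        series_nominal = ConcentrationSeries(arr[:, 0], arr[:, 1], arr[:, 2])
        series_true = ConcentrationSeries(arr[:, 0], arr[:, 3], arr[:, 4])

    return CaseResult(
        patient=patient,
        patient_id=patient_id,
        schedule=schedule,
        records=records,
        events=events,
        flags=flags,
        induction_dose_mg=induction_given,
        in_band_fraction=in_band_fraction,
        recovery_time_min=recovery_time,
        sugammadex_doses_mg=sugammadex_doses,
        twitch=twitch,
        controller_log=controller_log,
        series_nominal=series_nominal,
        series_true=series_true,
    )


@dataclass
class CohortResult:
    records: pd.DataFrame
    metrics: pd.DataFrame
    patients: pd.DataFrame
    cases: list[CaseResult]
    master_seed: int

    @property
    def ce_spread_fold(self) -> float:
        """Max/min nominal Ce at the %T1 = 3 % recovery event."""
        ce = self.records.loc[
            self.records["condition"] == "recovery_3pct", "predicted_ce_ug_ml"
        ].to_numpy()
        ce = ce[ce > 0]
        if ce.size < 2:
            return math.nan
        return float(ce.max() / ce.min())


def run_cohort(
    n: int,
    master_seed: int,
    variability: VariabilityConfig | None = None,
    nominal_pd: PDParameterSet | None = None,
    trial: TrialConfig | None = None,
    controller_cfg: ctl.ControllerConfig | None = None,
    limits: PumpLimits | None = None,
    pk_per_kg: dict | None = None,
    ke0: float | None = None,
    ci_method: str = "t",
    keep_series: bool = False,
) -> CohortResult:
    """Simulate ``n`` independent virtual patients through the protocol.

    Per-patient seeds are derived deterministically from ``master_seed``;
    two runs with the same master seed produce identical tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    variability = variability if variability is not None else VariabilityConfig()
    nominal_pd = nominal_pd or default_pd()
    kw = {} if pk_per_kg is None else {"per_kg": pk_per_kg}
    if ke0 is not None:
        kw["ke0"] = ke0

    ss = np.random.SeedSequence(master_seed)
    words = ss.generate_state(2 * n, dtype=np.uint32)
    cases: list[CaseResult] = []
    patients = []
    seeds = []
    for pid in range(n):
        sample_seed = int(words[2 * pid])
        trial_seed = int(words[2 * pid + 1])
        rng = np.random.default_rng(sample_seed)
        cov = sample_covariates(rng)
        nom_pk = nominal_pk_for_weight(cov.weight_kg, **kw)
        pat = sample_patient(cov, nom_pk, nominal_pd, variability, rng)
        case = run_case(
            pat, nom_pk, nominal_pd, trial, controller_cfg, limits,
            seed=trial_seed, patient_id=pid, keep_series=keep_series,
        )
        cases.append(case)
        patients.append(pat)
        seeds.append(sample_seed)

    records = pd.concat(
        [c.records_frame() for c in cases], ignore_index=True
    ) if cases else records_frame([])
    metrics = evaluate_records(records, ci_method=ci_method)
    ptable = cohort_frame(patients, seeds)
    ptable["trial_seed"] = [int(words[2 * p + 1]) for p in range(n)]
    ptable["case_flags"] = ["|".join(c.flags) for c in cases]
    ptable["induction_dose_mg"] = [c.induction_dose_mg for c in cases]
    ptable["in_band_fraction"] = [c.in_band_fraction for c in cases]
    ptable["recovery_time_min"] = [
        math.nan if c.recovery_time_min is None else c.recovery_time_min for c in cases
    ]
    return CohortResult(records, metrics, ptable, cases, master_seed)
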