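"""Virtual-patient generation: the synthetic study population.

Each virtual patient carries a *true* PK/PD parameter set drawn around
the nominal (population) model with independent log-normal deviates, so
the controller — which only ever sees the nominal model — faces realistic
model mismatch.  The generator also emulates the assay: measured plasma
concentrations are the true concentration perturbed by log-normal assay
noise, and after reversal they are additionally inflated by a
multiplicative factor that stands in for drug returning from tissue under
sugammadex encapsulation (an empirical surrogate, not a mechanistic
model; the default 1.47 is the observed measured-vs-predicted slope at
the post-reversal sampling point).

Covariates are sampled to match the reported study population: height
1.50–1.75 m, BMI 20–27 kg·m⁻² (weight derived as BMI·height², which keeps
every subject inside the study's own BMI inclusion window), age 35–81 y,
10/15 female.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .pd_model import PDParameterSet
from .pk import PKParameterSet

__all__ = [
    "PatientCovariates",
    "VariabilityConfig",
    "VirtualPatient",
    "ideal_body_weight",
    "sample_covariates",
    "sample_patient",
    "measure_concentration",
    "cohort_frame",
]

#: IBW convention: the body weight at BMI = 22 kg·m⁻².
IBW_BMI = 22.0

HEIGHT_RANGE_M = (1.50, 1.75)
BMI_RANGE = (20.0, 27.0)
AGE_RANGE_Y = (35.0, 81.0)
FEMALE_FRACTION = 10.0 / 15.0


@dataclass(frozen=True)
class PatientCovariates:
    height_m: float
    weight_kg: float
    sex: str  # "F" | "M"
    age_y: float

    def __post_init__(self) -> None:
        if not (0.5 < self.height_m < 2.5):
            raise ValueError(f"implausible height: {self.height_m} m")
        if not (20.0 < self.weight_kg < 250.0):
            raise ValueError(f"implausible weight: {self.weight_kg} kg")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if not (0 < self.age_y < 120):
            raise ValueError(f"implausible age: {self.age_y}")


@dataclass(frozen=True)
class VariabilityConfig:
    """Inter-individual and measurement variability magnitudes.

    All coefficients of variation are for independent log-normal deviates
    with mean 1.  The magnitudes are synthetic defaults — only the
    *resulting* spread in effect-site concentration at recovery is
    clinically constrained (a few-fold across patients).
    """

    pk_cv: float = 0.25
    ec50_cv: float = 0.2
    gamma_cv: float = 0.1
    assay_cv: float = 0.07
    post_reversal_inflation: float = 1.47

    def __post_init__(self) -> None:
        for name in ("pk_cv", "ec50_cv", "gamma_cv", "assay_cv"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite CV >= 0, got {v}")
        if self.post_reversal_inflation < 1:
            raise ValueError("post_reversal_inflation must be >= 1")

    @classmethod
    def none(cls) -> "VariabilityConfig":
        """All variability and noise disabled (the null configuration)."""
        return cls(pk_cv=0.0, ec50_cv=0.0, gamma_cv=0.0, assay_cv=0.0,
                   post_reversal_inflation=1.0)


@dataclass(frozen=True)
class VirtualPatient:
    covariates: PatientCovariates
    true_pk: PKParameterSet
    true_pd: PDParameterSet
    assay_cv: float = 0.07
    post_reversal_inflation: float = 1.47

    def __post_init__(self) -> None:
        if self.assay_cv < 0:
            raise ValueError("assay_cv must be >= 0")
        if self.post_reversal_inflation < 1:
            raise ValueError("post_reversal_inflation must be >= 1")


def ideal_body_weight(height_m: float) -> float:
    """IBW in kg at BMI 22 kg·m⁻²: 22 · height²."""
    if height_m <= 0:
        raise ValueError(f"height must be > 0, got {height_m}")
    return IBW_BMI * height_m**2


def _as_rng(rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _lognormal_deviate(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with the given CV (1.0 when cv=0)."""
    if cv == 0.0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def sample_covariates(
    rng: Union[int, np.random.Generator, None] = None
) -> PatientCovariates:
    """Draw covariates uniformly within the study population's ranges."""
    gen = _as_rng(rng)
    height = float(gen.uniform(*HEIGHT_RANGE_M))
    bmi = float(gen.uniform(*BMI_RANGE))
    age = float(gen.uniform(*AGE_RANGE_Y))
    sex = "F" if gen.random() < FEMALE_FRACTION else "M"
    return PatientCovariates(height, bmi * height**2, sex, age)


def sample_patient(
    covariates: PatientCovariates,
    nominal_pk: PKParameterSet,
    nominal_pd: PDParameterSet,
    variability: VariabilityConfig,
    rng: Union[int, np.random.Generator, None] = None,
) -> VirtualPatient:
    """Draw one virtual patient around the nominal model.

    Every PK rate constant and the central volume get independent
    unit-mean log-normal deviates at ``pk_cv``; ec50 and γ get their own
    deviates.  With all CVs zero the true parameters equal the nominal
    ones exactly.  Reproducible under a fixed seed / generator state.
    """
    gen = _as_rng(rng)
    cv = variability.pk_cv
    true_pk = PKParameterSet(
        v1=nominal_pk.v1 * _lognormal_deviate(gen, cv),
        k10=nominal_pk.k10 * _lognormal_deviate(gen, cv),
        k12=nominal_pk.k12 * _lognormal_deviate(gen, cv),
        k21=nominal_pk.k21 * _lognormal_deviate(gen, cv),
        k13=nominal_pk.k13 * _lognormal_deviate(gen, cv),
        k31=nominal_pk.k31 * _lognormal_deviate(gen, cv),
        ke0=nominal_pk.ke0 * _lognormal_deviate(gen, cv),
        label="true (perturbed)",
    )
    true_pd = replace(
        nominal_pd,
        ec50=nominal_pd.ec50 * _lognormal_deviate(gen, variability.ec50_cv),
        gamma=nominal_pd.gamma * _lognormal_deviate(gen, variability.gamma_cv),
    )
    return VirtualPatient(
        covariates=covariates,
        true_pk=true_pk,
        true_pd=true_pd,
        assay_cv=variability.assay_cv,
        post_reversal_inflation=variability.post_reversal_inflation,
    )


def measure_concentration(
    true_cp: float,
    patient: VirtualPatient,
    phase: str = "pre",
    rng: Union[int, np.random.Generator, None] = None,
) -> float:
    """Synthetic assay value for a true plasma concentration.

    Pre-reversal the measurement is the true concentration times a
    unit-mean log-normal assay deviate; post-reversal it is additionally
    multiplied by the patient's inflation factor (total drug returning to
    blood under reversal exceeding the free-drug prediction).
    """
    if true_cp < 0:
        raise ValueError(f"true_cp must be >= 0, got {true_cp}")
    if phase not in ("pre", "post_reversal"):
        raise ValueError("phase must be 'pre' or 'post_reversal'")
    value = true_cp * _lognormal_deviate(_as_rng(rng), patient.assay_cv)
    if phase == "post_reversal":
        value *= patient.post_reversal_inflation
    return value


def cohort_frame(patients: list[VirtualPatient], seeds: list[int] | None = None) -> pd.DataFrame:
    """Provenance table of a sampled cohort (one row per patient)."""
    rows = []
    for i, p in enumerate(patients):
        row = {
            "patient_id": i,
            "height_m": p.covariates.height_m,
            "weight_kg": p.covariates.weight_kg,
            "sex": p.covariates.sex,
            "age_y": p.covariates.age_y,
            "ibw_kg": ideal_body_weight(p.covariates.height_m),
            "v1": p.true_pk.v1,
            "k10": p.true_pk.k10,
            "k12": p.true_pk.k12,
            "k21": p.true_pk.k21,
            "k13": p.true_pk.k13,
            "k31": p.true_pk.k31,
            "ke0": p.true_pk.ke0,
            "ec50": p.true_pd.ec50,
            "gamma": p.true_pd.gamma,
            "assay_cv": p.assay_cv,
            "post_reversal_inflation": p.post_reversal_inflation,
        }
        if seeds is not None:
            row["seed"] = seeds[i]
        rows.append(row)
    return pd.DataFrame(rows)
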