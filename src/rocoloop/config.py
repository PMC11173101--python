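"""Default parameter sets, run configuration, and config file I/O.

All model constants live here rather than inside the engine code: any
parameter set with the right shape is accepted by the PK/PD machinery, and
the shipped defaults are one documented, overridable choice.

Pharmacokinetic defaults
    ``WIERDA_PK_PER_KG`` is the weight-normalised three-compartment
    rocuronium parameter set of Wierda and colleagues as used in
    target-controlled-infusion practice (central volume 0.044 L·kg⁻¹;
    k10 0.10, k12 0.21, k21 0.13, k13 0.028, k31 0.01 min⁻¹, giving a
    plasma clearance of ≈ 4.4 mL·kg⁻¹·min⁻¹).  ``KE0_DEFAULT`` (0.168
    min⁻¹) is the standard literature plasma–effect-site equilibration
    constant for rocuronium at the adductor pollicis; the effect
    compartment is not part of the original plasma model and must be
    supplied separately.

Pharmacodynamic defaults
    No Hill parameters are published for this protocol; ``DEFAULT_PD``
    uses ec50 = 0.6 µg·mL⁻¹ and γ = 4.5, chosen so that the effect-site
    concentration at %T1 = 3 % recovery of the nominal subject
    (≈ 1.3 µg·mL⁻¹) lies in the clinically reported 0.6–2.2 µg·mL⁻¹
    range.  Monitor noise, fade and detectability defaults are synthetic
    (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .pk import PKParameterSet
from .pd_model import PDParameterSet

__all__ = [
    "WIERDA_PK_PER_KG",
    "KE0_DEFAULT",
    "DEFAULT_PD",
    "nominal_pk_for_weight",
    "default_pd",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]

#: Weight-normalised rocuronium PK set (L·kg⁻¹ and min⁻¹); see module docstring.
WIERDA_PK_PER_KG: dict[str, float] = {
    "v1_l_per_kg": 0.044,
    "k10": 0.10,
    "k12": 0.21,
    "k21": 0.13,
    "k13": 0.028,
    "k31": 0.01,
}

#: Plasma–effect-site equilibration constant (min⁻¹), adductor pollicis.
KE0_DEFAULT: float = 0.168

#: Population Hill / monitor defaults (synthetic; see module docstring).
DEFAULT_PD: dict[str, float] = {
    "ec50": 0.6,
    "gamma": 4.5,
    "noise_sd": 1.5,
    "fade": 0.75,
    "detect_threshold": 2.0,
}


def nominal_pk_for_weight(
    weight_kg: float,
    per_kg: Mapping[str, float] | None = None,
    ke0: float = KE0_DEFAULT,
    label: str = "Wierda (weight-scaled)",
) -> PKParameterSet:
    """Absolute PK parameter set for a subject of the given body weight."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    p = dict(per_kg or WIERDA_PK_PER_KG)
    return PKParameterSet(
        v1=p["v1_l_per_kg"] * weight_kg,
        k10=p["k10"],
        k12=p["k12"],
        k21=p["k21"],
        k13=p["k13"],
        k31=p["k31"],
        ke0=ke0,
        label=label,
    )


def default_pd(**overrides: float) -> PDParameterSet:
    """Population PD parameter set, with optional field overrides."""
    return PDParameterSet(**{**DEFAULT_PD, **overrides})


# --------------------------------------------------------------------------
# run configuration


def _build(cls, section: Mapping[str, Any], name: str):
    """Construct a dataclass from a config mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    try:
        return cls(**section)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid '{name}' configuration: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    seed: int
    n: int = 15
    pk_per_kg: dict[str, float] = field(default_factory=lambda: dict(WIERDA_PK_PER_KG))
    ke0: float = KE0_DEFAULT
    pd: "PDParameterSet" = None  # type: ignore[assignment]
    controller: Any = None
    trial: Any = None
    variability: Any = None
    max_rate: float = 200.0

    def __post_init__(self) -> None:
        from .controller import ControllerConfig
        from .trial import TrialConfig
        from .cohort import VariabilityConfig

        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "pk_per_kg", dict(self.pk_per_kg))
        missing = set(WIERDA_PK_PER_KG) - set(self.pk_per_kg)
        if missing:
            raise ValueError(f"pk_per_kg missing key(s): {sorted(missing)}")
        if self.ke0 <= 0:
            raise ValueError("ke0 must be > 0")
        for name, cls, default in (
            ("pd", PDParameterSet, default_pd),
            ("controller", ControllerConfig, ControllerConfig),
            ("trial", TrialConfig, TrialConfig),
            ("variability", VariabilityConfig, VariabilityConfig),
        ):
            value = getattr(self, name)
            if value is None:
                object.__setattr__(self, name, default())
            elif isinstance(value, Mapping):
                object.__setattr__(self, name, _build(cls, value, name))
            elif not isinstance(value, cls):
                raise ValueError(f"'{name}' must be a mapping or {cls.__name__}")
        if self.max_rate <= 0:
            raise ValueError("max_rate must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n": self.n,
            "pk_per_kg": dict(self.pk_per_kg),
            "ke0": self.ke0,
            "pd": dataclasses.asdict(self.pd),
            "controller": dataclasses.asdict(self.controller),
            "trial": dataclasses.asdict(self.trial),
            "variability": dataclasses.asdict(self.variability),
            "max_rate": self.max_rate,
        }


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration.

    Unknown keys are rejected with the offending field named; omitted
    sections fall back to the documented defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return _build(RunConfig, data, "run")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
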