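"""Target-controlled-infusion rate computation.

Over one control epoch of length dt with constant infusion rate r, the
exact propagator of the linear PK system gives

    a1(t + dt) = (E·x)₁ + s₁·r

i.e. the end-of-epoch plasma concentration is *affine* in r.  The rate
that attains a plasma target at the end of the epoch therefore has the
closed form r = (target·V1 − (E·x)₁) / s₁, clamped to the pump's [0,
max_rate] envelope: zero when the zero-rate prediction already overshoots
the target, max_rate when the target is unreachable within the epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pk import CompartmentState, PKParameterSet, discretize, plasma_concentration

__all__ = ["PumpLimits", "rate_for_plasma_target", "bolus_for_plasma_target"]


@dataclass(frozen=True)
class PumpLimits:
    """Infusion-pump rate envelope (mg·min⁻¹); min rate is zero."""

    max_rate: float = 200.0

    def __post_init__(self) -> None:
        if not (self.max_rate > 0 and math.isfinite(self.max_rate)):
            raise ValueError(f"max_rate must be > 0, got {self.max_rate}")


def rate_from_vector(
    x: np.ndarray,
    target: float,
    dt: float,
    params: PKParameterSet,
    limits: PumpLimits,
) -> float:
    """Closed-form epoch rate on the raw state vector (hot-loop variant)."""
    E, s = discretize(params, dt)
    a1_free = float(E[0] @ x)
    r = (target * params.v1 - a1_free) / s[0]
    return min(max(r, 0.0), limits.max_rate)


def rate_for_plasma_target(
    state: CompartmentState,
    target: float,
    dt: float,
    params: PKParameterSet,
    limits: PumpLimits = PumpLimits(),
) -> float:
    """Constant rate attaining plasma ``target`` at the end of the epoch."""
    if target < 0 or not math.isfinite(target):
        raise ValueError(f"target must be finite and >= 0, got {target}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return rate_from_vector(state.as_vector(), target, dt, params, limits)


def bolus_for_plasma_target(
    state: CompartmentState, target: float, params: PKParameterSet
) -> float:
    """Bolus (mg) raising the plasma concentration instantaneously to target."""
    cp = plasma_concentration(state, params)
    if target < cp:
        raise ValueError(f"target {target} below current plasma concentration {cp}")
    return (target - cp) * params.v1
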