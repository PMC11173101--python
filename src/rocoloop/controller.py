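"""Closed-loop %T1 feedback rules driving the concentration target.

The automated adjustment logic reassesses the maintenance target every
12 s (0.2 min) from the latest monitor reading:

* %T1 held at 0 % continuously for 1 min   → target − 0.05 µg·mL⁻¹
* %T1 held at ≥ 5 % continuously for 1 min → target + 0.1  µg·mL⁻¹
* %T1 held at ≥ 8 % continuously for 1 min → target + 0.2  µg·mL⁻¹

with largest-applicable precedence (≥ 8 % wins over ≥ 5 %, increments win
over the decrement), at most one adjustment per firing, and a 2-min hold
after every adjustment during which the target is frozen (the TCI rate
itself keeps recomputing every tick toward the frozen target).  A rule
timer runs while its condition holds continuously and resets when the
condition breaks or any adjustment fires.

The initial target is the effect-site concentration at the reappearance
of the first twitch (TOFC = 1) after induction; at the transition to
maintenance it is revised to the concentration that yields %T1 = 5 under
the population Hill model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

from .pd_model import PDParameterSet, TwitchReading, inverse_ce_at_t1

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "TickResult",
    "initialize_target",
    "tick",
    "revise_target_for_t1",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ControllerConfig:
    """Rule constants of the automated adjustment system.

    Defaults are the protocol values: a 3–10 % %T1 band, a 12-s
    reassessment tick, −0.05/+0.1/+0.2 µg·mL⁻¹ target adjustments after a
    1-min persistent trigger, a 2-min post-adjustment hold, and a %T1 = 5
    set point for the maintenance-target revision.
    """

    tick: float = 0.2
    band_low: float = 3.0
    band_high: float = 10.0
    dec_at_zero: float = 0.05
    inc_at_5: float = 0.1
    inc_at_8: float = 0.2
    t1_trigger_mid: float = 5.0
    t1_trigger_high: float = 8.0
    persistence: float = 1.0
    hold: float = 2.0
    revision_t1: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if min(self.dec_at_zero, self.inc_at_5, self.inc_at_8) <= 0:
            raise ValueError("adjustment increments must be > 0")
        if self.hold < self.persistence:
            raise ValueError("hold must be >= persistence")
        if self.tick <= 0 or self.persistence <= 0:
            raise ValueError("tick and persistence must be > 0")
        if not (0 < self.revision_t1 < 100):
            raise ValueError("revision_t1 must be in (0, 100)")


@dataclass(frozen=True)
class ControllerState:
    """Current target plus rule/hold timers; immutable between ticks."""

    target: float
    hold_until: float = -math.inf
    zero_since: Optional[float] = None
    ge5_since: Optional[float] = None
    ge8_since: Optional[float] = None
    last_now: float = -math.inf
    initialized: bool = False

    def __post_init__(self) -> None:
        if self.target < 0:
            raise ValueError("target must be >= 0")


class TickResult(NamedTuple):
    state: ControllerState
    target: float
    fired: str  # "none" | "dec0" | "inc5" | "inc8"


def initialize_target(ce_at_event: float) -> ControllerState:
    """Start the controller with the Ce recorded at the TOFC = 1 event."""
    if not (ce_at_event > 0 and math.isfinite(ce_at_event)):
        raise ValueError(f"ce_at_event must be > 0, got {ce_at_event}")
    return ControllerState(target=ce_at_event, initialized=True)


def revise_target_for_t1(
    state: ControllerState,
    pd_estimate: PDParameterSet,
    cfg: ControllerConfig = ControllerConfig(),
) -> ControllerState:
    """Set the target to the Ce producing %T1 = ``cfg.revision_t1``.

    Applied once at the transition to maintenance; idempotent.
    """
    if not state.initialized:
        raise ValueError("controller state is not initialized")
    if pd_estimate is None:
        raise ValueError("a PD estimate is required for the revision")
    return replace(state, target=inverse_ce_at_t1(cfg.revision_t1, pd_estimate))


def tick(
    state: ControllerState,
    reading: TwitchReading,
    now: float,
    cfg: ControllerConfig = ControllerConfig(),
) -> TickResult:
    """One 12-s reassessment: update timers, possibly adjust the target."""
    if not state.initialized:
        raise ValueError("controller state is not initialized")
    if now < state.last_now - _EPS:
        raise ValueError("tick times must be non-decreasing")

    t1 = reading.t1_percent
    zero_since = now if t1 <= 0.0 else None
    if t1 <= 0.0 and state.zero_since is not None:
        zero_since = state.zero_since
    ge5_since = now if t1 >= cfg.t1_trigger_mid else None
    if t1 >= cfg.t1_trigger_mid and state.ge5_since is not None:
        ge5_since = state.ge5_since
    ge8_since = now if t1 >= cfg.t1_trigger_high else None
    if t1 >= cfg.t1_trigger_high and state.ge8_since is not None:
        ge8_since = state.ge8_since

    def ripe(since: Optional[float]) -> bool:
        return since is not None and now - since >= cfg.persistence - _EPS

    fired = "none"
    target = state.target
    hold_until = state.hold_until
    if now >= state.hold_until - _EPS:
        if ripe(ge8_since):
            target += cfg.inc_at_8
            fired = "inc8"
        elif ripe(ge5_since):
            target += cfg.inc_at_5
            fired = "inc5"
        elif ripe(zero_since):
            target = max(0.0, target - cfg.dec_at_zero)
            fired = "dec0"
        if fired != "none":
            hold_until = now + cfg.hold
            zero_since = ge5_since = ge8_since = None

    new_state = ControllerState(
        target=target,
        hold_until=hold_until,
        zero_since=zero_since,
        ge5_since=ge5_since,
        ge8_since=ge8_since,
        last_now=now,
        initialized=True,
    )
    return TickResult(new_state, target, fired)
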