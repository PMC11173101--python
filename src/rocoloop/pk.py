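"""Linear three-compartment pharmacokinetics with an effect compartment.

The model is the standard mammillary system used for rocuronium: a central
(plasma) compartment exchanging drug with a shallow and a deep peripheral
compartment by first-order transfer, first-order elimination from the
central compartment, and a hypothetical effect site linked to plasma by the
equilibration constant ke0:

    da1/dt = u(t) − (k10 + k12 + k13)·a1 + k21·a2 + k31·a3
    da2/dt = k12·a1 − k21·a2
    da3/dt = k13·a1 − k31·a3
    dCe/dt = ke0·(a1/V1 − Ce)

with amounts in mg, volumes in L, times in minutes and concentrations in
µg·mL⁻¹ (identically mg·L⁻¹).  The infusion input u(t) is piecewise
constant, so each control epoch can be propagated *exactly* with the matrix
exponential of the augmented system; a fixed-step fourth-order Runge–Kutta
integrator is kept alongside as an independent numerical oracle.

An additional state tracks cumulative eliminated mass (d/dt = k10·a1) so
that mass balance is checkable to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "PKParameterSet",
    "CompartmentState",
    "DoseEvent",
    "DoseSchedule",
    "ConcentrationSeries",
    "plasma_concentration",
    "advance_exact",
    "advance_oracle",
    "simulate_schedule",
]

#: state vector layout used internally: [a1, a2, a3, ce, eliminated]
N_STATE = 5


@dataclass(frozen=True)
class PKParameterSet:
    """Rate constants and central volume of one three-compartment model.

    ``v1`` is the absolute central volume in litres (a weight-normalised
    set is scaled by body weight before constructing this object).  All
    rate constants are first-order, in min⁻¹.  ``label`` records the
    provenance of the set and takes no part in the dynamics.
    """

    v1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("v1", "k10", "k12", "k21", "k13", "k31", "ke0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.v1 <= 0:
            raise ValueError(f"v1 must be > 0, got {self.v1}")
        if self.ke0 <= 0:
            raise ValueError(f"ke0 must be > 0, got {self.ke0}")
        for name in ("k10", "k12", "k21", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CompartmentState:
    """Drug amounts (mg) and effect-site concentration at one time point.

    ``eliminated`` accumulates mass cleared from the central compartment;
    it exists purely so that mass balance is auditable.
    """

    t: float
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    ce: float = 0.0
    eliminated: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t", "a1", "a2", "a3", "ce", "eliminated"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("a1", "a2", "a3", "ce"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.ce, self.eliminated])

    @classmethod
    def from_vector(cls, t: float, x: np.ndarray) -> "CompartmentState":
        # tiny negative round-off from the matrix exponential is clipped
        x = np.where((x < 0) & (x > -1e-12), 0.0, x)
        return cls(t, *map(float, x))


@dataclass(frozen=True)
class DoseEvent:
    """One timestamped administration event.

    ``kind`` is ``"bolus"`` (``value`` in mg, applied instantaneously to
    the central compartment) or ``"rate"`` (``value`` in mg·min⁻¹, the
    infusion rate holding from ``t`` until the next rate event).
    """

    t: float
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "rate"):
            raise ValueError(f"kind must be 'bolus' or 'rate', got {self.kind!r}")
        if not math.isfinite(self.t) or self.t < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.t}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"event value must be finite and >= 0, got {self.value}")


@dataclass
class DoseSchedule:
    """Time-ordered administration history (boluses + rate changes)."""

    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.t for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("DoseSchedule events must be time-ordered")

    def append(self, event: DoseEvent) -> None:
        if self.events and event.t < self.events[-1].t:
            raise ValueError("appended event predates the last event")
        self.events.append(event)

    def scaled(self, factor: float) -> "DoseSchedule":
        """Schedule with every dose and rate multiplied by ``factor``."""
        return DoseSchedule([replace(e, value=e.value * factor) for e in self.events])

    def shifted(self, delta: float) -> "DoseSchedule":
        """Schedule delayed as a whole by ``delta`` minutes."""
        return DoseSchedule([replace(e, t=e.t + delta) for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": [e.t for e in self.events],
                "event_type": [e.kind for e in self.events],
                "value": [e.value for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseSchedule":
        df = pd.read_csv(path)
        required = {"time_min", "event_type", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dose-history CSV missing columns: {sorted(missing)}")
        return cls(
            [
                DoseEvent(float(r.time_min), str(r.event_type), float(r.value))
                for r in df.itertuples()
            ]
        )


@dataclass
class ConcentrationSeries:
    """Plasma and effect-site concentration sampled on a time grid."""

    times: np.ndarray
    cp: np.ndarray
    ce: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        self.ce = np.asarray(self.ce, dtype=float)
        if not (len(self.times) == len(self.cp) == len(self.ce)):
            raise ValueError("times, cp, ce must have equal lengths")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cp < 0) or np.any(self.ce < 0):
            raise ValueError("concentrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "cp_ug_ml": self.cp, "ce_ug_ml": self.ce}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def system_matrix(params: PKParameterSet) -> np.ndarray:
    """Drift matrix A of the 5-state linear system (incl. elimination row)."""
    p = params
    A = np.zeros((N_STATE, N_STATE))
    A[0, 0] = -(p.k10 + p.k12 + p.k13)
    A[0, 1] = p.k21
    A[0, 2] = p.k31
    A[1, 0] = p.k12
    A[1, 1] = -p.k21
    A[2, 0] = p.k13
    A[2, 2] = -p.k31
    A[3, 0] = p.ke0 / p.v1
    A[3, 3] = -p.ke0
    A[4, 0] = p.k10
    return A


@lru_cache(maxsize=256)
def discretize(params: PKParameterSet, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-step propagator for a constant-rate interval of length dt.

    Returns ``(E, s)`` with x(t+dt) = E @ x(t) + s * rate, obtained from the
    matrix exponential of the augmented (state, input) system.  Cached per
    (parameter set, dt) since the controller reuses a fixed tick.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    A = system_matrix(params)
    M = np.zeros((N_STATE + 1, N_STATE + 1))
    M[:N_STATE, :N_STATE] = A
    M[0, N_STATE] = 1.0  # unit infusion enters the central compartment
    Phi = expm(M * dt)
    E = np.ascontiguousarray(Phi[:N_STATE, :N_STATE])
    s = np.ascontiguousarray(Phi[:N_STATE, N_STATE])
    return E, s


def plasma_concentration(state: CompartmentState, params: PKParameterSet) -> float:
    """Central-compartment concentration a1/V1 in µg·mL⁻¹."""
    return state.a1 / params.v1


def advance_exact(
    state: CompartmentState, rate: float, dt: float, params: PKParameterSet
) -> CompartmentState:
    """Propagate the state exactly over ``dt`` minutes at constant ``rate``.

    Closed under composition: advancing dt1 then dt2 equals advancing
    dt1 + dt2 (up to floating point).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if rate < 0 or not math.isfinite(rate):
        raise ValueError(f"rate must be finite and >= 0, got {rate}")
    E, s = discretize(params, dt)
    x = E @ state.as_vector() + s * rate
    return CompartmentState.from_vector(state.t + dt, x)


def advance_oracle(
    state: CompartmentState,
    rate: float,
    dt: float,
    params: PKParameterSet,
    step: float = 1e-3,
) -> CompartmentState:
    """Fixed-step classical RK4 integration of the same ODE system.

    Independent of :func:`advance_exact`; used as the numerical oracle.
    Converges to the exact propagator as ``step`` → 0 (order 4).
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    A = system_matrix(params)
    b = np.zeros(N_STATE)
    b[0] = rate

    def f(x: np.ndarray) -> np.ndarray:
        return A @ x + b

    n_full = int(dt / step)
    remainder = dt - n_full * step
    x = state.as_vector()
    for h in [step] * n_full + ([remainder] if remainder > 1e-12 else []):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return CompartmentState.from_vector(state.t + dt, x)


def simulate_schedule(
    schedule: DoseSchedule,
    params: PKParameterSet,
    grid_dt: float,
    t_end: float,
) -> ConcentrationSeries:
    """Propagate an administration history and sample Cp/Ce on a grid.

    Boluses are applied instantaneously at their timestamp (the sample at
    exactly that time reflects the post-bolus state); infusion-rate events
    hold until superseded.  Propagation between breakpoints uses the exact
    stepper, so the result carries no integration error.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be > 0")
    events = schedule.events
    if events and events[-1].t > t_end:
        raise ValueError("schedule contains events after t_end")

    n_grid = int(round(t_end / grid_dt))
    grid = [round(i * grid_dt, 9) for i in range(n_grid + 1)]
    breakpoints = sorted(set(grid) | {round(e.t, 9) for e in events})
    grid_set = set(grid)

    by_time: dict[float, list[DoseEvent]] = {}
    for e in events:
        by_time.setdefault(round(e.t, 9), []).append(e)

    x = np.zeros(N_STATE)
    rate = 0.0
    out_t: list[float] = []
    out_cp: list[float] = []
    out_ce: list[float] = []
    prev = 0.0
    for t in breakpoints:
        if t > prev:
            E, s = discretize(params, t - prev)
            x = E @ x + s * rate
            prev = t
        for e in by_time.get(t, ()):
            if e.kind == "bolus":
                x[0] += e.value
            else:
                rate = e.value
        if t in grid_set:
            out_t.append(t)
            out_cp.append(max(x[0], 0.0) / params.v1)
            out_ce.append(max(x[3], 0.0))
    return ConcentrationSeries(np.array(out_t), np.array(out_cp), np.array(out_ce))
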