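"""Effect-site concentration → neuromuscular monitor readings.

The depression of the first train-of-four twitch (%T1, percent of the
calibrated pre-drug control) follows a sigmoid Emax (Hill) model on the
effect-site concentration Ce:

    %T1(Ce) = 100 · ec50^γ / (Ce^γ + ec50^γ)

which is strictly decreasing, equals 100 at Ce = 0 and 50 at Ce = ec50,
and is analytically invertible — the controller uses the inverse to turn a
%T1 set point into a concentration target.

The remaining monitor outputs are simulation scaffolding around that core:
additive Gaussian noise (truncated at zero) on %T1; a train-of-four fade
model T_k = T1 · f_eff^(k−1) with a block-depth-dependent effective fade
f_eff = 1 − (1 − fade)·(100 − %T1)/100, so that fade vanishes at full
recovery (TOF ratio → 1) and bottoms out at ``fade`` under deep block; a
detectability threshold that yields the train-of-four count (TOFC); and
the TOF ratio T4/T1 reported only when all four twitches are detectable.

As on the physical device, a first twitch below the detection threshold
is displayed as %T1 = 0 (TOFC = 0): the monitor never reports a
sub-threshold amplitude.  This is what makes the controller's
"%T1 remained at 0 %" rule well defined under measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "PDParameterSet",
    "TwitchReading",
    "t1_from_ce",
    "inverse_ce_at_t1",
    "reading_from_ce",
]


@dataclass(frozen=True)
class PDParameterSet:
    """Hill parameters plus monitor scaffolding for one subject.

    ec50
        Effect-site concentration at half-maximal T1 depression (µg·mL⁻¹).
    gamma
        Hill steepness (dimensionless).
    noise_sd
        SD of the additive Gaussian %T1 measurement noise (% points).
    fade
        Deep-block fade floor per successive twitch, in (0, 1].  The
        effective fade interpolates between this value (full block) and
        1 (full recovery).
    detect_threshold
        Twitch amplitude (% of control) below which a twitch is not
        detected; determines the TOF count.
    """

    ec50: float
    gamma: float
    noise_sd: float = 1.5
    fade: float = 0.75
    detect_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and math.isfinite(self.ec50)):
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.fade <= 1):
            raise ValueError("fade must be in (0, 1]")
        if self.detect_threshold < 0:
            raise ValueError("detect_threshold must be >= 0")


@dataclass(frozen=True)
class TwitchReading:
    """One train-of-four reading from the simulated monitor."""

    t: float
    t1_percent: float
    tof_count: int
    tof_ratio: Optional[float]

    def __post_init__(self) -> None:
        if self.t1_percent < 0:
            raise ValueError("t1_percent must be >= 0")
        if self.tof_count not in (0, 1, 2, 3, 4):
            raise ValueError("tof_count must be in 0..4")
        if self.tof_ratio is not None and not (0 <= self.tof_ratio <= 1):
            raise ValueError("tof_ratio must be in [0, 1] when defined")


def t1_from_ce(ce: float, pd: PDParameterSet) -> float:
    """Noise-free %T1 for an effect-site concentration (Hill model)."""
    if ce < 0 or not math.isfinite(ce):
        raise ValueError(f"ce must be finite and >= 0, got {ce}")
    if ce == 0.0:
        return 100.0
    # computed via the ratio form for numerical robustness at large ce
    r = (ce / pd.ec50) ** pd.gamma
    return 100.0 / (1.0 + r)


def inverse_ce_at_t1(t1_target: float, pd: PDParameterSet) -> float:
    """Effect-site concentration giving the requested noise-free %T1.

    Analytic inverse of :func:`t1_from_ce`; defined for targets strictly
    inside (0, 100).
    """
    if not (0.0 < t1_target < 100.0):
        raise ValueError(f"t1_target must be in (0, 100), got {t1_target}")
    return pd.ec50 * ((100.0 - t1_target) / t1_target) ** (1.0 / pd.gamma)


def _effective_fade(t1: float, pd: PDParameterSet) -> float:
    depth = min(max((100.0 - t1) / 100.0, 0.0), 1.0)
    return 1.0 - (1.0 - pd.fade) * depth


def reading_from_ce(
    ce: float,
    pd: PDParameterSet,
    rng: Union[int, np.random.Generator, None] = None,
    t: float = 0.0,
) -> TwitchReading:
    """Simulate one monitor reading at effect-site concentration ``ce``.

    Reproducible: passing the same seed (or a generator in the same state)
    returns an identical reading.
    """
    if ce < 0:
        raise ValueError(f"ce must be >= 0, got {ce}")
    t1 = t1_from_ce(ce, pd)
    if pd.noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        t1 = max(0.0, t1 + gen.normal(0.0, pd.noise_sd))
    if t1 < pd.detect_threshold:
        t1 = 0.0  # undetectable first twitch displays as 0 %
    f = _effective_fade(t1, pd)
    twitches = [t1 * f**k for k in range(4)]
    tof_count = 0
    for amp in twitches:
        if amp >= pd.detect_threshold and pd.detect_threshold > 0 or (
            pd.detect_threshold == 0 and amp > 0
        ):
            tof_count += 1
        else:
            break
    tof_ratio = twitches[3] / twitches[0] if tof_count == 4 and twitches[0] > 0 else None
    return TwitchReading(t=t, t1_percent=t1, tof_count=tof_count, tof_ratio=tof_ratio)
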