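# Methods

## Scope and design

`rocoloop` simulates an automated rocuronium infusion-adjustment system
end-to-end: a linear pharmacokinetic (PK) engine, a sigmoid-Emax
pharmacodynamic (PD) twitch model, a target-controlled-infusion (TCI)
rate calculator, the %T1 feedback rule engine, a virtual-patient
generator, and prediction-accuracy statistics.  The central design is a
*twin simulation*: the patient's true (perturbed) PK/PD produces monitor
readings and synthetic "measured" blood concentrations, while the
controller sees only the nominal population model driven by the *same*
administration history.  Agreement between the two tracks at the four
protocol sampling points is the quantity of interest.

Units are fixed throughout: minutes, mg, L, µg·mL⁻¹ (≡ mg·L⁻¹).  Time
zero is the first rocuronium bolus.

## Pharmacokinetics

Three-compartment mammillary model with effect site (see README for the
equations).  A fifth state integrates eliminated mass (k10·a₁) so mass
balance is auditable to round-off.

* **Exact stepping.**  The infusion input is piecewise constant, so each
  constant-rate interval is propagated with the matrix exponential of
  the augmented (state, input) system: x(t+dt) = E·x + s·r with
  (E, s) cached per (parameter set, dt).  This stepper is exact up to
  floating point and closed under composition.
* **Numerical oracle.**  A classical fixed-step RK4 integrator of the
  same ODEs (`advance_oracle`) is retained purely as an independent
  cross-check; tests require agreement with the exact stepper to 1e−6
  relative on randomized states, parameters, rates and step sizes.
* **Default parameters.**  The weight-normalised Wierda rocuronium set
  (V1 0.044 L·kg⁻¹; k10 0.10, k12 0.21, k21 0.13, k13 0.028, k31 0.01
  min⁻¹), scaled by total body weight, with ke0 = 0.168 min⁻¹ (the
  standard adductor-pollicis equilibration constant, which is not part
  of the original plasma model).  Both live in `rocoloop.config`, never
  in engine logic; any `PKParameterSet`-shaped set is accepted.

Dosing convention: a bolus is applied instantaneously at its timestamp
(the sample at exactly that time reflects the post-bolus state); a rate
event holds until superseded.

## Pharmacodynamics and the simulated monitor

%T1(Ce) = 100·ec50^γ/(Ce^γ + ec50^γ).  The Hill form is the standard
pharmacometric choice; it is strictly decreasing, equals 100 at Ce = 0,
and is analytically invertible, which the controller relies on.

No Hill parameters are published for this protocol, so the defaults are
synthetic and chosen once: **ec50 = 0.6 µg·mL⁻¹, γ = 4.5**, placing the
nominal subject's Ce at %T1 = 3 % recovery near 1.3 µg·mL⁻¹ — inside
the clinically reported 0.6–2.2 µg·mL⁻¹ range for that event.

Monitor scaffolding (simulation devices, not claims about physiology):

* **Noise**: additive Gaussian on %T1, SD 1.5 % points, truncated at 0.
* **Display threshold**: a first twitch below `detect_threshold`
  (default 2 % of control) is displayed as %T1 = 0 with TOF count 0, as
  on the physical device.  This is what makes the controller's
  "%T1 remained at 0 %" rule well defined under noise.
* **Fade**: T_k = T1·f_eff^(k−1) with a depth-dependent effective fade
  f_eff = 1 − (1 − fade)·(100 − %T1)/100 (deep-block floor
  `fade` = 0.75).  A *constant* fade would make the TOF-ratio ≥ 0.9
  recovery criterion degenerate (the ratio would be the same constant
  whenever four twitches are detectable); the depth-dependent form lets
  the ratio recover to 1 with the twitch.  TOF count = number of leading
  twitches above the display threshold; TOF ratio = T4/T1, defined only
  at count 4.
* **Cadence**: readings every 10 s; the controller's 12-s ticks use the
  latest reading (last observation carried forward).

## TCI and the feedback controller

The end-of-epoch Cp is affine in the epoch rate, so the rate attaining a
plasma target has the closed form r = (target·V1 − (E·x)₁)/s₁, clamped
to [0, max_rate] (default max 200 mg·min⁻¹, deliberately generous so
clamping is observable but not binding).  Attainment is defined at the
end of the 0.2-min epoch.  Maintenance targets *plasma* concentration,
even though the target's value originates from an effect-site quantity —
this mirrors the clinical system's stated behaviour.

Controller rules (protocol constants): target −0.05 µg·mL⁻¹ after 1 min
of %T1 = 0; +0.1 after 1 min of ≥ 5 %; +0.2 after 1 min of ≥ 8 %.
Largest-applicable precedence (≥ 8 % implies ≥ 5 %; only one adjustment
per firing) is the only reading under which the +0.2 rule is reachable.
A rule timer runs while its condition holds continuously and resets when
it breaks or any adjustment fires; after an adjustment the target is
frozen for 2 min while the TCI rate keeps recomputing every tick.  The
initial target is the nominal Ce at the TOFC = 1 event; at maintenance
start the target is revised once to the Ce giving %T1 = 5 under the
*population* PD model (an individually fitted model would require an
estimation stage that is out of scope here).

## Trial protocol

Induction: 0.6 mg·kg⁻¹ of ideal body weight (IBW = 22·height², the
BMI-22 convention) as a bolus; if a twitch is still detectable at the
1-min check, one rescue bolus of 0.3 mg·kg⁻¹ (cumulative cap
0.9 mg·kg⁻¹ IBW).  Maintenance runs 150 min (the clinical mean duration)
after infusion start; cessation waits for %T1 in band, then sugammadex
2 mg·kg⁻¹ (actual body weight) is given, with a 0.5 mg·kg⁻¹ rescue if
the TOF ratio has not reached 0.9 by 3 min.  Samples: (1) %T1 ≥ 3 %
recovery; (2) stable period; (3) cessation (simultaneous with the
infusion stop); (4) 5 min post-sugammadex.

Event detection under noise is debounced: the TOFC = 1 event requires 6
consecutive detectable readings (1 min), the 3 %-recovery event 3
consecutive readings ≥ 3 %, each timestamped at the first reading of the
qualifying run so noise-free timing is unchanged.  The stable period is
judged on a 5-min moving average of %T1 staying in 3–10 % for 15
continuous minutes beginning ≥ 60 min after infusion start; a case that
never achieves it is flagged `incomplete_stable_window` and simply lacks
that sample, mirroring clinically excluded samples.

Reversal is **not** modelled mechanistically (sugammadex encapsulation
kinetics are out of scope by design).  Two empirical surrogates stand in
for it: (a) the *effective* Ce seen by the PD model decays exponentially
after sugammadex with τ = 1.5 min, which yields TOF-ratio recovery in
roughly 100 s — the clinically observed scale; (b) the synthetic
measured concentration after reversal is multiplied by an inflation
factor (default 1.47, the observed measured-vs-predicted slope at that
sampling point), representing total (free + encapsulated) drug returning
from tissue.  The predicted track is deliberately left on the unchanged
nominal PK model.

Simulation grid: 2-s steps (exact stepping makes the grid a bookkeeping
choice, not an accuracy parameter); readings every 5 steps, controller
ticks every 6.

## Virtual cohort

Each patient's true PK rate constants, V1 and ke0 receive independent
unit-mean log-normal deviates (CV 0.25); ec50 CV 0.2; γ CV 0.1; assay
noise log-normal CV 0.07.  Only the resulting spread is clinically
constrained — a few-fold range of Ce at the recovery event — and the
defaults produce a 4–13-fold max/min spread in cohorts of 15–50, which
brackets the reported ~3.7-fold in 14 patients.  Covariates: height
uniform 1.50–1.75 m, BMI uniform 20–27 kg·m⁻² with weight = BMI·height²
(independent uniform height and weight could violate the study's own BMI
inclusion window), age uniform 35–81 y, 2:1 female.  All randomness
flows from a single master seed through `numpy.random.SeedSequence`;
cohort tables are bit-reproducible.

## Accuracy statistics

PE = 100·(measured − predicted)/predicted (prediction in the
denominator, the universal TCI convention); MDPE/MDAPE are medians
(midpoint convention for even sizes), computed per condition across
patients.  Through-origin slope Σxy/Σx²; Pearson r via scipy.  The 95 %
interval convention in summaries is explicit and configurable
(Student-t for the mean by default, or mean ± 1.96·SD), and is echoed in
every output row.

## What passing tests do and do not show

The generator emulates inter-individual PK/PD mismatch, assay noise and
post-reversal inflation — not within-patient physiological drift
(temperature, cardiac output), measurement artefacts of
acceleromyography, or drug interactions.  Null-case identities
(measured = predicted, MDPE = MDAPE = 0, slope = 1) validate the
plumbing, and the cohort checks validate orders of magnitude; neither
demonstrates clinical predictive accuracy on real patients.

## Known limitations

* With the default noise (SD 1.5 %), patients over-blocked by PK
  mismatch equilibrate at a true %T1 of ~2–3 %: once occasional noise
  blips break the 1-min zero-%T1 run, the decrement rule's firing
  probability collapses, and nothing else pushes the block shallower.
  Roughly half of noisy virtual patients therefore never achieve the
  15-min stable window.  The clinical system's better floor compliance
  likely comes from its continuously updated individual PD model, which
  is represented here only by the one-shot target revision.
* The rescue-bolus check reads a single noisy reading at 1 min, so
  fully blocked patients occasionally draw a spurious rescue; the
  induction cap still always holds.
* The reversal surrogates reproduce timing and inflation scale, not
  mechanism; free vs encapsulated drug is not distinguished.
* The TOF fade/count model is monitor scaffolding with plausible but
  uncalibrated staging.
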