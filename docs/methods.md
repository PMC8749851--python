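# Methods

This note documents the models, parameter choices and numerical decisions
behind `stridesense`, and what the synthetic validation does and does not
establish about measured data.

## Stride model and the touch-down problem

A stride is the interval between consecutive touch-downs (TD) of the same
foot; its length is the norm of the horizontal displacement of the foot
sensor over that interval, obtained by double integration of global-frame
acceleration. Two assumptions carry the method:

1. **Amortisation zero-velocity premise.** Even in maximal sprinting the
   foot is momentarily (near-)stationary early in ground contact, so the
   velocity integrated from TD should sit at ~0 shortly after TD. Any
   non-zero plateau there is treated as a spurious offset.
2. **Artefact confinement.** The landing-impact acceleration peaks do not
   reflect horizontal foot motion and are confined to roughly the first
   20 ms of contact. Integrating through them produces precisely the
   velocity offset that assumption 1 detects; the first 20 ms are therefore
   excluded from the offset search, and samples before the detected offset
   index are zeroed outright.

Each horizontal axis (x, z) is processed independently — offsets differ in
sign and size between axes — and an axis whose stride-mean velocity is
negative is mirrored first, so the guard/search logic always sees a
forward-running trace. Stride length, being a norm, is invariant to both
the mirroring and the horizontal heading, which is why a magnetometer-free
global frame (x = initial heading) is acceptable.

The first stride of each foot has no preceding TD. Integration for it
starts 280 ms before the first toe-off — early enough to include all
pre-toe-off foot motion from a split-stance standing start — with zero
initial velocity and no offset correction.

## Parameters

| key | default | meaning |
| --- | --- | --- |
| `madgwick.beta` | 0.043 | orientation-filter gain (dimensionless) |
| `start.pre_toeoff_s` | 0.280 s | first-stride integration lead before first toe-off |
| `zvu.window_lo_s` / `zvu.window_hi_s` | 0.020 / 0.100 s | offset-search window after TD |
| `zvu.window_hi_stride2_s` | 0.160 s | extended window for stride 2 (longest contact, usually >150 ms) |
| `zvu.guard_m_s` | 1.0 m·s⁻¹ | guard added to the 20 ms clamp of the temporary velocity |
| `zvu.lowpass_hz` | 40 Hz | temporary-velocity low-pass cutoff |
| `zvu.filter` | `critical` | zero-phase 2nd-order filter family (see below) |
| `events.lowpass_hz` | 10 Hz | swing-peak pre-smoothing for event detection |
| `events.swing_prominence` | 3 rad·s⁻¹ | minimum prominence of a mid-swing peak |
| `events.dip_prominence` | 1 rad·s⁻¹ | minimum prominence of the raw TD/TO extrema |
| `gravity.g` | 9.81 m·s⁻² | gravity constant used for unit conversion and gravity removal |

Window endpoints are converted to samples with `round(·fs)` and are
inclusive on both ends; ties in the minimum take the earliest sample.
Strides whose stance is shorter than the lower window bound are skipped
with a warning rather than silently processed.

## Numerical choices

**Integration.** Both integration stages use the cumulative trapezoid with
`dt = 1/fs`. On the simulator's smooth minimum-jerk kinematics at 500 Hz
the total double-integration error is below 0.02% of stride length.

**Temporary-velocity filter.** The guard construction (first 20 ms clamped
to the 20 ms value + 1 m·s⁻¹) creates a ~1 m·s⁻¹ downward step right at the
edge of the offset-search window. A zero-phase Butterworth undershoots such
a step by ~4% of its height (−0.036 m·s⁻¹ measured), which lands inside the
window and systematically inflates every corrected stride by ~1%. The
default filter is therefore a critically damped 2nd-order section (double
real pole at 40 Hz) run forward–backward: its step response is monotone, so
the guard cannot ring a spurious minimum into the window, and its
suppression of white-noise power above 40 Hz is stronger (−26 dB vs
−20 dB). A conventional Butterworth remains available via
`zvu.filter: butter`.

**Zeroing convention.** "Before the offset index" is read exclusively: the
offset sample itself takes `v_orig[i_off] − v_off`; all earlier samples are
exactly zero. This keeps the corrected velocity continuous at the offset
index up to the subtracted constant.

**Linear dedrifting** (subtracting a velocity ramp so the stride ends at
zero velocity) is provided behind `dedrift.linear` (default off) for
comparison only. It addresses slow integration drift, not the touch-down
offset, which is a step rather than a ramp.

**Orientation.** The gradient-descent filter is formulated for an arbitrary
global reference direction, so the y-up frame is handled natively; with
β = 0 it reduces exactly to gyroscope strap-down integration (verified
against the closed-form axis-angle rotation). Initialization aligns the
mean specific force over the first 0.5 s (assumed quiet standing) with
global up; heading is arbitrary without a magnetometer, which stride
length tolerates. When magnetometer data is present, the geomagnetic
objective uses the measured field's horizontal/vertical split, matching the
frame definition (x along the horizontal field component).

**Event detection.** The published event rule's exact operator is not
specified beyond "the medial–lateral gyroscope axis"; the implementation
low-passes at 10 Hz to find mid-swing peaks by prominence, then takes
opposite-sign raw-signal extrema: first after a swing peak = TD, last
before the next swing peak = TO. Flat extrema tie-break to the first
sample. The rule is validated against the simulator (100% recall, 0 ms
worst timing error at 500 Hz across all three effort profiles); equivalence
with other detectors can only be established on shared data.

## The synthetic sprint generator

The generator is the package's ground-truth instrument. Body speed follows
the mono-exponential sprint profile `v(t) = v_max(1 − e^(−t/τ))` with
defaults v_max = 7.0 / 7.65 / 8.4 m·s⁻¹ at 60 / 80 / 100% subjective effort
(matching typical maximal stride speeds of recreational sprinters), τ =
1.3 s, distance 35 m. Stride frequency rises (1.55 + 0.08·v Hz) and ground
contact time falls (0.240 − 0.014·v s, floored at 105 ms) with speed —
plausible linear maps chosen once; contact at the second stride exceeds
150 ms and near-maximal contact sits near 120 ms. Each foot is strictly
stationary during stance (the zero-velocity premise holds by construction)
and swings between footfalls along a minimum-jerk path, so the kinematic
acceleration is analytic and every true stride length is known exactly.
Footfall positions track the body, with 2 cm lateral scatter about each
foot's line.

The touch-down artefact is an exponentially damped ~120 Hz burst (peak
10–40 g, demeaned so the burst alone changes velocity by ~0) confined to
the first 15 ms of contact, plus — unless `zero_net` is set — a half-sine
pulse carrying a spurious net velocity integral of nominally 0.4 m·s⁻¹
(±20% jitter, random sign, x-axis; 0.08–0.2 m·s⁻¹ on z). The 0.4 m·s⁻¹
scale makes naive (uncorrected) integration mis-estimate mid-sprint strides
by ~5–15%, i.e. an artefact that *must* be corrected; artefact amplitudes
in the field are known only up to range saturation, so this is a
calibration choice, not a measured fact. White noise defaults:
0.3 m·s⁻² on acceleration, 0.05 rad·s⁻¹ on angular rate. Optional clipping
saturates at ±16 g. A synthetic medial–lateral gyroscope channel carries
the swing/stance signature with sharp extrema exactly at the true events.

**What the simulator does not emulate:** orientation-estimation error
(the pipeline is fed global-frame acceleration directly; orientation is
validated separately on prescribed rotations), soft-tissue and shoe-
deformation artefacts near toe-off, sensor-fixation slip, gyroscope bias
drift, non-sagittal foot placement beyond lateral scatter, and reference-
measurement (video digitization) error. Passing the synthetic recovery
tests therefore demonstrates the correctness of the integration/correction
machinery under the stated assumptions — not field accuracy, which in
measured data is dominated by orientation and fixation effects.

## Agreement statistics

Validity against a reference is reported as Bland–Altman bias ± limits of
agreement (LOA = 1.96·SD) on per-stride percentage differences, with the SD
built from a one-way random-effects partition over participants: between-
participant variance `(MSB − MSW)/n₀` (harmonic-style effective cluster
size `n₀ = (N² − Σnᵢ²)/((m−1)N)`, clamped at zero) plus within-participant
variance MSW. With one observation per participant, or fewer than two
participants, the classic independent-differences SD is used with a
warning. The Monte-Carlo validation draws participant means with 1%
between-participant SD and strides with √(3.5² − 1²)% within-participant SD
around a −1% bias (20 participants × 50 strides; the split between
components is a generator choice — only bias and total SD are recovered
quantities).

## Validation problem sizes

The test suite and the acceptance script run entirely on synthetic data:
three noiseless sprints (one per effort, ~11 strides per foot), twenty
noisy sprints for the error percentiles, six sprints for the
correction-on/off mechanism contrast, ten Monte-Carlo repetitions of the
Bland–Altman recovery, and one 100%-effort sprint for the maximal stride
speed. The deposited worked-example sprint is verified only when a local
copy of the published per-sprint files is present under
`data/zenodo-5814971/`; the package does not download data.

## Known limitations

* The event-detection operator is simulator-validated, not validated
  against the original detector or measured gyroscope traces.
* The repeated-measures LOA treats strides within a participant as
  exchangeable; serial correlation along a sprint is not modelled.
* The offset-search windows assume ground contact longer than 20 ms
  (100 ms for a reliable minimum); extremely short contacts are skipped.
* Sub-sample synchronization between feet is not attempted (≤1 ms residual
  at 500 Hz).
* Whether deposited vertical-axis data has gravity removed is irrelevant to
  the core (horizontal axes only) and is not resolved by the reader.
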