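# Methods

## Scope and model

The package implements a two-part model: (1) per-second binary vigilance
detection from occipital EEG via sparse-representation classification (SRC)
over KSVD-learned dictionaries, and (2) a vehicle speed-control strategy that
converts the vigilance stream into deceleration/braking commands, gated by a
car-following safety-distance model. Hardware concerns (electrode caps,
Bluetooth telemetry, stereo ranging cameras, ECU actuation) are out of scope;
a simulated range sensor and a point-mass two-car simulator stand in for them.

## Synthetic EEG generator

No public recordings accompany this problem setting, so the generator is a
first-class module: it produces the *statistical structure the detector
assumes*, not physiological EEG. A channel is a sum of

- band-limited Gaussian noise per rhythm — white noise band-passed with a
  4th-order Butterworth filter at theta 4–8, alpha 8–14, beta 14–34 Hz, scaled
  to an exact target variance (µV²);
- a 1/f pink background (FFT-shaped, high-passed at 1 Hz), default 15 µV²;
- sub-3 Hz drift (two random-phase sinusoids at 0.4 and 1.1 Hz, 80 µV²
  total) and >50 Hz interference (70 Hz tone plus 70–90 Hz noise, 20 µV²),
  giving the denoiser realistic out-of-band energy to remove;
- in the drowsy state only, alpha bursts: Poisson arrivals (4/min), 1–3 s
  Hann envelopes over band-limited alpha noise with 40 µV² peak power,
  modeling intermittent rather than tonic drowsy alpha.

State contrast defaults are alert theta/alpha/beta = 8/12/24 µV² and drowsy
32/48/6 µV². These were chosen so the full detection chain operates in a
meaningful, non-saturated regime: per-second features classify in the low 80%s
and history-averaged features (b = 8) in the mid 90%s, so the benefit of
averaging is visible. What passing tests show is therefore that the *pipeline
mechanics* (denoising, feature extraction, dictionary learning, residual
classification) recover a drowsiness signature of this spectral form; they say
nothing about inter-subject variability, non-stationarity, eye-blink/EMG
artifacts, or electrode noise in real recordings, none of which are modeled.

## Preprocessing

Denoising is sub-band selection, not coefficient thresholding: a 6-level db5
DWT (symmetric boundary extension) and reconstruction of the d3–d6 detail
branches only, which at 512 Hz nominally span 4–64 Hz. The approximation a6
(drift) and d1/d2 (interference) are discarded wholesale. The transform is
applied at the native rate, before downsampling. Two numerical notes:

- db5's filters are not brick-wall: a 10 Hz tone places ~86% of its energy in
  the d5 (8–16 Hz) branch, with the remainder leaking into d4/d6. End-to-end
  the denoiser still keeps >99.6% of a 10 Hz tone and removes >99.9% of a
  1 Hz tone (FFT power oracle), which is the guarantee that matters.
- at 1000 Hz the dyadic branch edges shift (d3–d6 = 3.9–125 Hz); the same
  branch-selection rule is kept for the BP path, and the subsequent 100 Hz
  downsampling truncates content above 50 Hz anyway.

Downsampling (512→128, 1000→100 Hz) uses polyphase rational resampling with
the built-in anti-alias FIR (`scipy.signal.resample_poly`).

## Features

Each full second gets a 128-point FFT (rectangular window; at 100 Hz the
epoch is zero-padded to 128 points), one-sided periodogram scaling, then
log₁₀ with a 1e-12 floor to keep silent epochs finite. The theta/alpha/beta
bins are concatenated in band order — 30 bins at 128 Hz (1 Hz spacing). Band
edges are half-open [4,8), [8,14), [14,34) Hz; alpha deliberately runs to
14 Hz rather than the more common 13 Hz. The feature at second t is the mean
over seconds t−b…t (b+1 epochs); on stationary input this shrinks feature
variance as a sample mean, which is why discriminability grows with b.
Channels O1 and O2 are processed and classified independently.

## Sparse classifier

Atoms and test features are scaled to unit norm, making residual comparisons
scale-free. OMP is the textbook greedy loop: pick the atom with maximal
absolute correlation to the residual, re-fit least squares on the support,
stop at q atoms or a vanished residual. KSVD learns one dictionary per class
(w = 50 atoms, q = 5, default 30 iterations; the multi-seed evaluation in the
test suite uses 15 iterations, which is indistinguishable in accuracy at half
the cost); atoms are initialized from random training vectors, dead atoms are
re-seeded with the worst-represented signal, and the coding step keeps a
signal's previous code whenever the fresh OMP code would not improve it —
this makes the recorded Frobenius objective provably non-increasing, which the
plain alternation does not quite guarantee. Classification codes y against
the concatenated [DIC_a DIC_d] and takes the class with the smaller
class-restricted residual; exact ties go to "alert" so a borderline second
never triggers an intervention. The train/test split is by contiguous blocks
(leading two-thirds of each class) because history-averaged features are
temporally correlated and a random shuffle would leak.

Problem sizes used throughout the evaluation: 10 min per state at 512 Hz,
two channels, w = 50, q = 5, b ∈ {0, 4, 8}, five generator seeds.

## Speed control

All kinematics are SI internally; km/h appears only at the API boundary. The
follower's three-stage profile (reaction t₁ = 1.2 s, linear deceleration ramp
t₂ = 0.2 s, constant a_m = 4.5 m/s²) gives

    t₃ = (v₂₁ − v₂₂)/a_m − t₂/2
    s_following = v₂₁(t₁ + t₂/2) + (v₂₁² − v₂₂²)/(2 a_m)

where the closed form drops an O(a_m t₂²) ramp correction of ~8 mm; the
fixed-step simulator (dt = 0.01 s, trapezoidal velocity update over the
piecewise-linear acceleration profile) agrees with the closed form to better
than 0.05%. Both final speeds are defined as v₂₁ − ΔV with ΔV = 20 km/h —
the speed drop is set against the *follower's* initial speed, which is the
reading that reproduces the reference safety distance — and the front car
spreads its drop over exactly t_following so the two cars settle
simultaneously; the gap is then monotone decreasing during the maneuver and
its minimum equals the terminal gap. a_m is stored as a positive magnitude;
a_f carries its natural (negative) sign. The range-based follower-speed
estimate uses the physical sign convention v₂₁ = v₁₁ + (L₁ − L₂)/dt: the gap
to the follower closes when the follower is faster.

The state machine holds two run counters (consecutive drowsy, consecutive
alert) plus a drowsy flag. DECELERATE fires when the drowsy run reaches n
with the flag clear; RELEASE_LIMIT when the alert run reaches m with the flag
set; BRAKE — terminal, further input is ignored with a warning — when the
flag is set, at least k seconds have elapsed since the DECELERATE, no
m-second alert run has occurred since, and the current second is drowsy.
This operationalization of the "u + z" wake-up bookkeeping is the one
consistent with both worked timelines (release at 21 s, brake at 38 s). If
the range sensor reports a gap at or below the required distance L when a
DECELERATE fires, the command is still logged but the speed change is
withheld, an `unsafe_gap` event is recorded, and the check is retried each
second. The horn is a logged event only.

## Degenerate inputs and tie-breaks

- zero-power generator parameters produce an exactly zero signal;
- all-zero PSD epochs hit the log floor and yield a constant feature vector;
- OMP at q = 0 returns the zero code with residual ‖y‖; equal residuals
  classify as alert; q larger than the atom count is rejected;
- a front car already at its target speed (v₁₂ = v₁₁) is handled as
  constant-speed travel (a_f = 0);
- downsampling to the current rate is the identity.

## Known limitations

- The generator's classes are stationary within a state and switch abruptly;
  real drowsiness onset is gradual, so reported accuracies are optimistic for
  the boundary seconds (at b = 8, up to 8 post-transition seconds mix states).
- SRC with strongly correlated atoms is markedly weaker than a linear
  discriminant on the same features; the pipeline reproduces the method as
  specified rather than the best achievable classifier.
- The controller assumes an ideal one-second detection cadence and a single
  follower; multi-vehicle traffic, actuator dynamics and sensor latency are
  not modeled.
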