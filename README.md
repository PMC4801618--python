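# drowsydrive

EEG-based driver drowsiness detection coupled to a car-following speed-control
strategy, as one tested pipeline: multichannel occipital EEG is wavelet-denoised,
reduced to per-second log power-spectral-density band features, classified
alert/drowsy by minimal-residual sparse representation over KSVD-learned
dictionaries, and the resulting per-second vigilance stream drives a
three-situation vehicle speed controller backed by a two-car deceleration model.

The package is for researchers prototyping EEG vigilance monitors and
active-safety control logic who need every stage — signal synthesis,
preprocessing, features, classifier, controller, simulator — runnable and
testable on a desk, with no recording hardware.

## Method

**Detection.** Raw EEG (512 Hz wearable mode or 1000 Hz lab mode, 3–100 Hz
hardware passband) is decomposed with a 6-level db5 discrete wavelet transform;
reconstructing only the d3–d6 detail branches (4–64 Hz nominal at 512 Hz)
removes baseline drift and high-frequency interference. After anti-aliased
downsampling (512→128 Hz or 1000→100 Hz), each 1 s epoch of an occipital
channel (O1, O2) gets a 128-point FFT log₁₀ PSD, and the bins in theta
(4–8 Hz), alpha (8–14 Hz) and beta (14–34 Hz) are concatenated into a feature
y ∈ R³⁰. The feature at second *t* is averaged with the previous *b* seconds.
Per class *x* ∈ {alert, drowsy}, a dictionary DICₓ of *w* unit-norm atoms is
learned by KSVD (alternating OMP sparse coding at sparsity *q* with rank-1 SVD
atom updates). A test feature is coded by orthogonal matching pursuit against
DIC = [DIC_a DIC_d] and labeled

  class(y) = argmin_x ‖ y − DIC α′ₓ ‖₂ ,

where α′ₓ keeps only class *x*'s coefficients.

**Control.** The instrumented (front) car sheds ΔV = 20 km/h when drowsiness is
confirmed. The follower reacts after t₁ = 1.2 s, ramps to its maximum
deceleration a_m = 4.5 m/s² over t₂ = 0.2 s, and holds it, giving a total
deceleration time t_following = t₁ + t₂ + (v₂₁ − v₂₂)/a_m − t₂/2. The maneuver
is safe when the actual gap exceeds

  L = D_min + s_following − s_front ,  s_following = v₂₁(t₁ + t₂/2) + (v₂₁² − v₂₂²)/(2 a_m),

with the front car decelerating at a_f = (v₁₂ − v₁₁)/t_following over
s_front = (v₁₂² − v₁₁²)/(2 a_f). A per-second state machine emits DECELERATE
after *n* = 3 consecutive drowsy seconds, RELEASE_LIMIT after *m* = 10
consecutive alert seconds, and a terminal BRAKE when ≥ *k* = 10 s have passed
since DECELERATE without an m-second alert run and the driver is still drowsy.

## Worked example

```
$ drowsydrive simulate --v11 95 --v21 100 --gap 10.5 --out trace.tsv
required distance L = 10.37 m (safe at La = 10.5 m)
terminal speeds: front 80.0 km/h, follower 80.0 km/h; terminal gap 5.14 m
```

A follower at 100 km/h behind a 95 km/h car needs L ≈ 10.4 m of gap before a
coordinated 20 km/h speed drop; from 10.5 m the two-car simulation ends with
both cars at 80 km/h and the gap shrunk to ≈ 5 m — exactly the configured
minimum safety distance D_min = 5 m.

The detection path on a synthetic 10 min alert / 10 min drowsy session:

```
$ drowsydrive synth  --config cfg.yaml --out session.tsv
wrote session.tsv (1200 s, 2 channels)
$ drowsydrive train  --config cfg.yaml --recording session.tsv --channel O1 --out dic.npz
held-out accuracy (O1, b=8): 97.48%
$ drowsydrive detect --config cfg.yaml --recording session.tsv --dictionary dic.npz \
                     --channel O1 --out labels.tsv
wrote labels.tsv (1192 labeled seconds)
```

Training uses the leading two-thirds of each state's features; the printed
97.48% is accuracy on the held-back final third. Replaying a vigilance stream
(0 = alert, 1 = drowsy, one per second) through the controller:

```
$ drowsydrive control --labels stream.txt --out commands.tsv
4 commands: DECELERATE@9s, RELEASE_LIMIT@21s, DECELERATE@28s, BRAKE@38s
```

For a stream that is drowsy over seconds 7–11, alert 12–25 and drowsy 26–38:
drowsiness is confirmed at second 9 (third consecutive drowsy second), the
driver's 10 s alert run releases the speed limit at 21, a second episode
triggers deceleration at 28, and with no recovery within the 10 s wake-up
window the car brakes at 38.

## Layout

- `drowsydrive.synthetic` — labeled alert/drowsy EEG generator (band-limited
  rhythms, 1/f background, alpha bursts, drift and interference)
- `drowsydrive.preprocessing` — db5 sub-band denoiser and rational downsampler
- `drowsydrive.features` — per-second log-PSD band features, history averaging
- `drowsydrive.sparse` — OMP, KSVD, and `SparseRepresentationClassifier`
  (scikit-learn estimator API)
- `drowsydrive.control` — deceleration model, safety distance, range-based
  speed estimate, two-car simulator, `SpeedController` state machine
- `drowsydrive.cli` / `io` / `config` — `drowsydrive` command-line tool
  (synth, train, detect, control, simulate) with manifest-stamped outputs
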