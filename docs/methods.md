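# Methods

## Signal model and conventions

The EOG is treated as a linear transducer of horizontal gaze angle:
x(t) = S·α(t) + artefacts, with sensitivity S = 16 µV/° (14 µV/° for the
vertical derivation) and a linear range of ±50° (±30° vertical). Angle
estimates outside the linear range are flagged, never silently returned.
Amplitudes are µV, time is milliseconds, and sample k of a recording sits
at `start_time_ms + k·Ts`; the default Ts = 1 ms matches the 1 ms stream
interval of typical Bluetooth bioamplifiers. The acquisition hardware may
digitise faster internally; the pipeline only assumes the delivered rate,
which is configurable.

## Preprocessing

* **Low-pass filter.** 9th-order Butterworth, 30 Hz cutoff — EOG content
  of interest lies below ~40 Hz and fixational tremor (30–150 Hz) is
  deliberately excluded. The filter is realised as cascaded second-order
  sections (a 9th-order polynomial realisation is numerically fragile) and
  applied forward–backward by default. Zero-phase application matters
  here: a causal 9th-order filter would delay the signal by tens of
  milliseconds and bias the response-delay feature; recordings are
  processed offline, so non-causality is free. A `causal` mode is kept for
  real-time parity experiments. Boundary handling uses *symmetric* (even)
  padding: the default odd extension pins the output to the raw first
  sample, which on a noisy trace injects a spurious velocity spike at the
  edge big enough to masquerade as a saccade.
* **Derivative.** Central difference with half-window h = 1 sample
  (configurable); one-sided differences at the two edges keep the output
  length equal to the input and make the derivative of affine signals
  exact everywhere.
* **Trailing smoother.** A causal mean (or median) over the last 100
  samples is provided to visualise slow pursuit (≈0) versus saccadic
  peaks. It is **not** applied before detection by default: a trailing
  mean divides a step's velocity peak by roughly the window length, so a
  1° saccade (16 µV) would fall from ~1 µV/ms to 0.16 µV/ms and below any
  sensible threshold. The stage is exposed as `--smooth {mean,median,off}`
  ("off" default). Both mean and median are implemented because usage of
  "media filter" in the field is ambiguous between the two.

## Saccade detection

Samples with |x′| ≥ Th are grouped into maximal runs; runs separated by
less than a 50 ms refractory gap are merged (a saccade's velocity profile
may graze the threshold twice) and runs shorter than 3 ms are dropped as
noise. Detecting on |x′| treats leftward and rightward saccades
symmetrically. Th has no published value for this application; the
default, 0.48 µV/ms, is the conventional 30°/s angular-velocity criterion
expressed through S, and `calibrate_threshold` replaces it with
max(mean + k·SD of pooled |x′| from fixation recordings, velocity floor),
k = 5 by default. Degenerate (constant) calibration input warns and falls
back to the floor.

Raising Th is guaranteed not to increase the event count only when events
are unimodal velocity pulses separated by more than the refractory gap —
the regime saccade counting assumes; on arbitrary signals a shrinking run
can split into two. The property tests assert monotonicity in that
physiological regime.

## Features

* **ROS** = N / T uses the protocol's full test duration (45 s), not the
  recording length, and is reported rounded half-up to 2 decimals
  (6/45 → 0.13).
* **Deviation.** V is the mean filtered amplitude over the static window
  after a 500 ms settle (the subject first orients to the target); the
  mean is robust to zero-mean fixational micromovements. ϕ = V/S − θ is
  reported signed (advance positive, lag negative) and compared to the
  threshold by magnitude.
* **Delay.** Measured from the *first* motion onset — the end of the
  static window, when the stimulus starts moving — to the onset of the
  first detected saccade after it; `delay_mode=mean` instead averages
  per-onset delays over all five motion onsets (start + four direction
  changes). A recording with no responding saccade yields an explicit
  `NO_RESPONSE` sentinel (`inf`) that always classifies as abnormal —
  silent zeros would mask exactly the pathology being screened.

## Decision rule and evaluation

Positive ⇔ any of N > 6, |ϕ| > 3°, D ≥ 300 ms. Boundary semantics follow
the published worked examples: ROS 0.13 (N = 6) and ϕ = 3.0° are still
healthy, D = 300 ms is already abnormal. The count comparison uses the
integer N rather than the rounded quotient to avoid float-rounding
ambiguity. The three flags are all reported so a positive can be traced to
its driver. Metrics are rounded half-up to one decimal (81.25 → 81.3); a
zero denominator leaves only the affected metric undefined.

## Synthetic generator

The generator emulates the test as the signal taxonomy describes it:

* stimulus: 5 s static, then a constant-speed triangular sweep with four
  reversals at ±32.4° and return to centre at 45 s (the printed ±32.4°
  excursion is kept as the default even though the stated screen geometry
  implies ≈±24°; the value is a free parameter);
* pursuit: velocity matching of the latency-delayed stimulus, scaled by
  `pursuit_gain` (first-order, the simplest defensible pursuit model);
* catch-up saccades: at each motion onset, the accumulated position error
  is closed `latency_ms` later by a raised-cosine step whose duration
  follows a main-sequence-like rule (21 ms + 2.2 ms/°, ≈43 ms for 10°);
  errors below 0.3° are left to pursuit (no saccade). With the default
  protocol this yields 5 commanded saccades — pursuit initiation plus four
  reversals — so a healthy subject sits at N = 5–6, inside the N ≤ 6
  bound;
* involuntary saccades (the ataxic fixation-instability signature): 2–4°
  flicks with an 80 ms hold and a slow (~7.5°/s, sub-threshold) glide
  back. Injection times are drawn inside the tracking phase, kept ≥0.8 s
  from commanded saccades, motion onsets and each other, and out of the
  static window — so the ground-truth annotation stays unambiguous and
  every feature measures what its label claims;
* fixational micromovements: zero-mean Gaussian process band-limited to
  2 Hz, scaled to SD = amplitude/3 (default amplitude 1°, the typical
  drift/flick excursion); the low bandwidth keeps its velocity an order of
  magnitude below Th, as real drift is;
* drift 0.3 µV/s (slow corneo-retinal/electrode baseline wander),
  broadband white noise 2 µV RMS (typical post-amplifier residual), blinks
  off by default (the horizontal montage largely suppresses them) but
  available as asymmetric 120 µV pulses.

Annotations record every true event (onset, velocity-peak time, amplitude,
kind), the deviation and the latency. On noise-free traces the detector
recovers the annotated events exactly in count and to within 2 samples at
the velocity peaks; *onsets* agree to within ~10 ms, not 1 sample, because
a threshold detector necessarily fires partway up the velocity sigmoid —
peak times are the robust anchor under zero-phase filtering.

What passing synthetic tests does **not** show: real EOG nonstationarity
(diurnal corneo-retinal potential variation, electrode impedance drift,
EMG and motion artefacts), real oculomotor dynamics (saccadic overshoot,
pursuit nonlinearity, square-wave jerks), or the clinical feature
distributions of actual ataxia subtypes. Synthetic validation certifies
the measurement chain, not clinical performance.

## Problem sizes and determinism

Each simulated test is 45 001 samples at 1 kHz. The test suite and the
acceptance script use a 20-recording parameter-recovery sweep and
5+5-subject cohorts — large enough to exercise every feature axis, small
enough that the whole suite runs in seconds. All randomness flows through
`numpy.random.default_rng` seeds carried in profiles and CLI/script
arguments; identical seeds give byte-identical traces.

## Known limitations

* Single-channel horizontal analysis only; vertical is supported in the
  types but not analysed.
* The decision thresholds are fixed population bounds; no per-subject
  adaptation or probabilistic scoring.
* The deviation feature assumes the linear dipole range; beyond ±50° the
  estimate is flagged but still linear.
* EOG signal power is not used as a feature: its dependence on squared,
  subject-varying amplitude makes it unreliable for discrimination.
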