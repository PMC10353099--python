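# Methods

## Signal model and conventions

A recording is one uniformly sampled frame grid (default 50 Hz; the rate is
inferred from the timestamps and must be constant to within 1 %).
Timestamps are seconds since recording start; all intervals are half-open
`[onset, offset)` except FALL flags, whose onset/offset are the
high-crossing and low-crossing sample times of the impact pattern.  Heart
rate and SpO2 are *sensor-reported* scalars, not waveforms: the wearable's
pulse oximeter produces roughly one reading per second, so these channels
are carried between observations by forward fill, with a per-channel
staleness age.  A slow channel older than `staleness_limit` (10 s) disables
its detector entirely rather than letting frozen values raise or suppress
flags — the fail-safe reading of a sensor dropout.

## Detectors

**Fall.** The triaxial magnitude ‖a‖ = √(ax²+ay²+az²) (≈ 9.81 m/s² at
rest) is smoothed by a centred moving average (`smooth_window`, 0.5 s;
partial windows at the edges average over the available samples).  A flag is
the impact pattern: an upward crossing of `a_high` (23.4 m/s²) followed by
the first sample below `a_low` (10 m/s²) within `fall_pattern_window`
(2 s).  Candidates that share samples merge; evidence is the peak smoothed
magnitude.  Smoothing-then-thresholding was chosen over thresholding raw
magnitude because the averaged signal is what the rule's two phrasings have
in common; the consequence, that a transient must hold its plateau on the
smoothing timescale to cross 23.4, is mirrored in the simulator's transient
shape (below).

**Ictal tachycardia.** Excess = HR − baseline ≥ `hr_delta` (10 bpm)
sustained ≥ 10 s.  The personal baseline is either a fixed constant or a
rolling median of the filled HR over `[t − 300 s, t − 30 s]`; the 30 s gap
keeps the ictal rise itself out of its own reference.  The rolling median is
recomputed on a 1 s anchor grid (`baseline_update`) and held constant
between anchors — the HR sensor only updates at ~1 Hz, and the anchored
computation lets the streaming engine reproduce the offline values exactly
(same median over the same window).  It is undefined (detector disabled)
until a full window of history exists.

**Desaturation.** SpO2 strictly below `spo2_min` (90 %) sustained ≥ 5 s;
evidence is the minimum SpO2.  90.0 % exactly is *not* a desaturation.

**Jerk.** The vibration sensor yields a binary channel; frequency over the
trailing window `(t − 2 s, t]` is the rising-edge count divided by the
window length, so resolution is ±1/`vib_window` = ±0.5 Hz.  Fewer than
`vib_min_edges` (4) edges means "inactive": without this activity gate a
silent channel would read 0 Hz, which is outside every band, and the
detector would latch permanently at rest.  With the default `outside`
semantics, active vibration at f < 3 Hz or f > 17 Hz sustained ≥ 2 s is
flagged (normal body vibration lives inside 3–17 Hz); `inside` semantics are
available as a configuration switch because clonic jerking itself is often
quoted near 3–8 Hz and a deployment may want the complementary reading.

**Debounce durations** (`min_*_duration`: FALL 0 s — the pattern is
intrinsically transient —, TACHYCARDIA 10 s, DESATURATION 5 s, JERK 2 s)
suppress single-sample noise crossings; all are tunable.

## Fusion and alarms

At a candidate time t (every flag onset — each new piece of evidence), the
contributing set is every modality with a flag intersecting
`[t − fusion_window, t]` (30 s).  Rules: `ANY`, `K_OF_N` (k distinct
modalities) and the default `MOTOR_AND_AUTONOMIC` — one motor sign (FALL or
JERK) and one autonomic sign (TACHYCARDIA or DESATURATION) — the reading of
"multimodal sensing raises sensitivity and lowers false discovery" that a
single noisy channel cannot satisfy alone.  After a DANGER, a 60 s
refractory period suppresses candidates; no event re-fires without a new
flag onset, so one long seizure yields one alarm.  The false-alarm button
cancels the most recent un-cancelled DANGER within `cancel_window` (120 s;
the paper-described device has such a button but no stated window, and
replay determinism needs a finite one); the panic button always raises an
alert.  Alerts render red (DANGER/PANIC) or green (FALSE_ALARM) with a
location placeholder — transport (BLE, phone, email) is out of scope.

## Streaming equivalence

`StreamDetector` holds only ring buffers (smoothing context, the
fall-pattern window, the 300 s HR history, the 2 s edge window) plus open
indicator runs and recent flags.  Exact equality with the offline pipeline
is by construction: every windowed statistic is an `np.mean`/`np.median`/
integer count over the *same* sample window in both paths, so the floats
are bit-identical, and fusion is re-evaluated as flags finalize.  Events are
released once they age past a decision horizon (the largest debounce plus
the pattern, smoothing and vibration windows plus 1 s), beyond which no
future sample can change them; their timestamps are unaffected by this
emission delay.  The equivalence is asserted exactly on 100 seeded random
recordings and on the full fixture suite through the CLI.

## Simulator

The generator emulates sensor outputs, not physiology: per-axis Gaussian
accelerometer noise around gravity (sd 0.2 m/s²), heart rate as an AR(1)
process at the 1 Hz report grid (coefficient 0.99, stationary sd 1.5 bpm —
slow drift, so the rolling-baseline estimator is meaningfully exercised),
SpO2 Gaussian about 97 % (sd 0.3), and sparse background vibration pulses
(0.05 Hz — one spurious pulse per ~20 s, low enough that Poisson clusters
cannot hold ≥ 4 edges in every sliding 2 s window for 2 s).  Episodes
inject, per their signature subset: a fall transient (0.2 s ramp to `peak`,
a plateau, an instant drop to `dip` with a hold — plateau and hold each
half of the remaining `pattern_span` — then 1 s recovery; the plateau
exists so a 30 m/s² impact still crosses 23.4 *after* 0.5 s smoothing — a
0.2 s spike would be diluted to ~15 m/s² and the threshold rule could never
fire), an HR ramp of `hr_rise` over `hr_ramp` seconds with a 20 s decay
after the episode, an SpO2 descent to `spo2_floor` over 5 s with 10 s
recovery, and a square-wave vibration train at `jerk_freq`.  All channel
values are quantized to 1e-6 (the CSV precision), so in-memory recordings,
written files and re-read files are bit-identical and every run is
byte-reproducible from its seed.

What the simulator does **not** model: real accelerometer waveforms of
falls (orientation change, bounce), PPG motion artefacts, baseline wander
of SpO2, sensor quantization, missing-data bursts, or non-seizure movements
(walking, tooth-brushing) that drive real-world false alarms.  Passing the
synthetic benches therefore demonstrates that the decision logic implements
its stated rules with margin — not that those rules would achieve the same
sensitivity/FDR on patients.

## Benches and problem sizes

Two seeded benches drive the tests and `scripts/acceptance.py`:

* **Threshold-fidelity fixtures** (10 × 420 s at 50 Hz; episode at 330 s so
  the rolling baseline is warm): a clean trace, four strong
  single-signature traces (peak 30 m/s², rise 15 bpm, floor 85 %, 20 Hz),
  a full-signature trace, and four borderline traces (peak 20 m/s², rise
  9 bpm, floor 91 %, 10 Hz) that must stay silent at defaults.  The bench
  uses quiet background noise (hr sd 0.3 bpm, SpO2 sd 0.2 %) so outcomes
  reflect the rules rather than noise excursions — the borderline margins
  are as small as 1 bpm, and with the realistic hr sd of 1.5 bpm the slow
  AR(1) drift would cross a 1 bpm margin by chance alone.
* **End-to-end suite** (20 recordings × 5 full-signature episodes, 960 s
  each, realistic default noise): episode recovery, false discovery rate,
  false alarms per hour and latency under the default motor+autonomic rule.

These sizes keep the whole battery under a minute while estimating
event-level rates from 100 episodes and ~5 h of background.

## Evaluation

Scoring is event-based — the device's claim is "alert during the episode",
not per-sample labelling.  A DANGER at time t matches an episode if t ∈
`[onset − pre_tol, offset + post_tol]` (defaults 5 s / 30 s); matching is
greedy earliest-first, an episode counts as detected once, and unmatched
alarms are false discoveries, also reported per hour.  Undefined ratios
(sensitivity with no episodes, FDR with no alarms) are reported as explicit
`undefined`/`null`, never silently 0.

## Numerical choices and degenerate inputs

Strict inequalities at all thresholds (`> a_high`, `< a_low`, `< spo2_min`,
`≥ hr_delta`); a smoothing window shorter than ~1.5 sample intervals is the
identity; a two-sample recording is the minimum; empty flag lists fuse to
empty event lists; out-of-range HR (outside 20–250 bpm), SpO2 (0–100 %),
non-binary vibration values, non-monotonic timestamps and malformed cells
are load errors naming the file line.  Evidence ties in the jerk detector
resolve to the first most-out-of-band estimate.

## Known limitations

* Fall monotonicity in `a_high` holds for impact-like transients; a slow
  excursion that stays above `a_low` longer than the pattern window at a low
  `a_high` can, in contrived cases, satisfy the pattern only at a higher
  threshold.  The property tests use impact-like spikes.
* Tolerance monotonicity of sensitivity holds while episode match windows
  stay disjoint; once widened windows overlap, earliest-first assignment can
  reassign an alarm to an earlier episode and lower sensitivity.
* The streaming engine infers the rate from the first two frames when not
  given one; for exact offline equivalence pass the validated recording
  rate.
* The 3–17 Hz "normal vibration" band and the out-of-band rule are taken as
  stated; whether clonic jerking should instead be sought *inside* a band is
  left to the `band_semantics` switch rather than guessed.
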