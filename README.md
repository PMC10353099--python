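# seizurekit

Multimodal wearable seizure detection in software: the decision logic of a
wrist-worn device that watches four channels for the signatures of a
generalized tonic-clonic seizure, re-implemented as a testable Python
package with a synthetic-signal simulator and an event-based evaluator.

Roughly one in a hundred people lives with epilepsy, and SUDEP (sudden
unexpected death in epilepsy) risk concentrates in the minutes during and
after unwitnessed convulsive seizures.  A cheap wearable that raises a
caregiver alert in real time therefore needs high episode sensitivity and a
low false discovery rate — which is what multimodal sensing buys over any
single channel.

## The detection rule

A recording is a uniformly sampled multichannel series (triaxial
acceleration *a* in m/s², sensor-reported heart rate in bpm and SpO2 in %
at ~1 Hz, a binary vibration channel).  Four per-modality detectors emit
*flags* — time intervals where a channel satisfies its seizure criterion:

| modality     | rule (defaults)                                                         |
|--------------|-------------------------------------------------------------------------|
| FALL         | smoothed ‖a‖ crosses above 23.4 m/s², then drops below 10 m/s² within 2 s (the body absorbing the impact) |
| TACHYCARDIA  | HR − personal baseline ≥ 10 bpm, sustained ≥ 10 s (ictal tachycardia); baseline = rolling median of HR over [t−300 s, t−30 s] |
| DESATURATION | SpO2 < 90 %, sustained ≥ 5 s                                             |
| JERK         | vibration active (≥ 4 rising edges per 2 s window) at an estimated frequency *outside* 3–17 Hz, the band of normal body vibration, sustained ≥ 2 s |

A fusion rule combines flags over a 30 s co-occurrence window into DANGER
alarms; the default, `MOTOR_AND_AUTONOMIC`, requires one motor sign (fall or
jerk) plus one autonomic sign (tachycardia or desaturation).  A 60 s
refractory period suppresses re-alarms, a false-alarm button cancels a
recent DANGER (green alert), and a panic button always alerts (red).
`StreamDetector` runs the identical pipeline incrementally with bounded
memory for real-time use.

## Worked example

```python
import seizurekit as sk
from seizurekit.fusion import FusionRule

spec = sk.SimulationSpec(duration=480.0, seed=42,
                         episodes=[sk.EpisodeSpec(onset=330.0, duration=45.0)])
recording, annotations = sk.simulate(spec)
config = sk.DetectorConfig()
flags = sk.detect_all(recording, config)
events = sk.fuse(flags, FusionRule.from_config(config), config)
```

Running `python examples/simulate_and_detect.py` (this exact pipeline)
prints:

```
episode ground truth: 330-375 s
  FALL         [ 330.20,  331.06) evidence=29.99
  JERK         [ 331.72,  375.26) evidence=20.00
  DESATURATION [ 333.00,  380.00) evidence=84.52
  TACHYCARDIA  [ 334.00,  384.00) evidence=16.60
DANGER alarm at t=333.00 s (DESATURATION+FALL+JERK), latency 3.00 s
```

Each flag's evidence is the quantity its rule thresholds: the fall peaked at
29.99 m/s² (above 23.4), the jerking ran at 20.00 Hz (outside 3–17), SpO2
bottomed at 84.52 % (below 90) and the heart rate rose 16.60 bpm over its
rolling baseline (above 10).  The fused DANGER fires 3 s after the annotated
onset, when the first autonomic sign joins the fall.

The other scripts under `examples/` show streaming detection, the button
semantics with alert rendering, and the event-based evaluation report.  The
same functionality is available from the shell:

```sh
seizurekit simulate --spec spec.json --out run
seizurekit detect --in run.csv [--stream] --out run
seizurekit evaluate --events run.events.json --annotations run.annotations.json \
    --duration 480 --out report.json
```

## Layout

- `src/seizurekit/core.py` — domain types, configuration, recording/event I/O
- `src/seizurekit/detectors.py` — the four threshold detectors
- `src/seizurekit/fusion.py` — decision fusion, alarm state machine, alerts
- `src/seizurekit/streaming.py` — bounded-state real-time engine
- `src/seizurekit/simulate.py` — seeded signal simulator + fixture benches
- `src/seizurekit/evaluate.py` — event-based scoring
- `src/seizurekit/cli.py` — `seizurekit simulate | detect | evaluate`
- `docs/methods.md` — model, parameter and design documentation
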