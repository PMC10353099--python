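"""Real-time detection: feed frames one at a time to the bounded-state engine.

The streaming detector keeps only ring buffers of window length, yet its
event list is exactly what the offline pipeline produces on the full
recording; alarms surface a few seconds after their timestamp because an
indicator run must outlast its debounce duration before it becomes evidence.
"""

import seizurekit as sk
from seizurekit.fusion import FusionRule, fuse

spec = sk.SimulationSpec(duration=480.0, seed=7,
                         episodes=[sk.EpisodeSpec(onset=330.0, duration=45.0)])
recording, _ = sk.simulate(spec)
config = sk.DetectorConfig()
rule = FusionRule.from_config(config)

detector = sk.StreamDetector(config, rule, rate=recording.rate)
for frame in recording:
    for event in detector.process(frame):
        mods = "+".join(m.value for m in event.modalities)
        print(f"at stream time {frame.t:7.2f}: {event.state.value} "
              f"timestamped t={event.time:.2f} ({mods})")
detector.finalize()

offline = fuse(sk.detect_all(recording, config), rule, config)
print(f"streaming events == offline events: {detector.events == offline}")
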