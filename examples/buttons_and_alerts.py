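"""The wearable's two buttons: cancelling a false alarm and calling for help.

A FALSE_ALARM press within the cancel window marks the DANGER event cancelled
and emits a green alert; a PANIC press raises an unconditional red alert with
no contributing modalities.
"""

import json

import seizurekit as sk

danger = sk.AlarmEvent(100.0, sk.AlarmState.DANGER,
                       (sk.Modality.FALL, sk.Modality.TACHYCARDIA))
presses = [
    sk.ButtonPress(130.0, sk.AlarmState.FALSE_ALARM),  # wearer waves it off
    sk.ButtonPress(400.0, sk.AlarmState.PANIC),        # later: needs help
]
events = sk.apply_buttons([danger], presses, cancel_window=120.0)

for event in events:
    print(json.dumps(sk.render_alert(event)))
# The caregiver app shows red for DANGER/PANIC, green for the cancellation;
# "location" stays null here — the phone fills it in the deployed system.
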