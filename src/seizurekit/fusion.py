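"""Decision fusion and the alarm state machine.

Modality flags are combined over a sliding co-occurrence window into DANGER
alarms.  Candidate alarm times are flag onsets (each new piece of evidence);
at a candidate time ``t`` the contributing set is every modality with a flag
intersecting ``[t - fusion_window, t]``.  A DANGER fires at the earliest
candidate satisfying the rule, after which the refractory period suppresses
further alarms.  The two wearable buttons are modelled as a time-stamped
input: the false-alarm button cancels a recent DANGER (rendered green), the
panic button raises an unconditional alert (rendered red).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import AlarmEvent, AlarmState, ButtonPress, DetectorConfig, Modality, ModalityFlag

__all__ = ["FusionRule", "fuse", "apply_buttons", "render_alert"]

log = logging.getLogger(__name__)

MOTOR = frozenset({Modality.FALL, Modality.JERK})
AUTONOMIC = frozenset({Modality.TACHYCARDIA, Modality.DESATURATION})

_STATE_ORDER = {AlarmState.DANGER: 0, AlarmState.FALSE_ALARM: 1, AlarmState.PANIC: 2}


@dataclass(frozen=True)
class FusionRule:
    """A named fusion rule: ANY (≥1 modality), K_OF_N (≥k distinct
    modalities) or MOTOR_AND_AUTONOMIC (one motor sign — fall or jerk — plus
    one autonomic sign — tachycardia or desaturation)."""

    name: str = "MOTOR_AND_AUTONOMIC"
    k: int = 2

    def __post_init__(self) -> None:
        if self.name not in ("ANY", "K_OF_N", "MOTOR_AND_AUTONOMIC"):
            raise ValueError(f"unknown fusion rule {self.name!r}")
        if not (1 <= self.k <= 4):
            raise ValueError("require 1 <= k <= 4")

    @classmethod
    def from_config(cls, cfg: DetectorConfig) -> "FusionRule":
        return cls(name=cfg.fusion_rule, k=cfg.fusion_k)

    def satisfied(self, modalities: set[Modality]) -> bool:
        if self.name == "ANY":
            return len(modalities) >= 1
        if self.name == "K_OF_N":
            return len(modalities) >= self.k
        return bool(modalities & MOTOR) and bool(modalities & AUTONOMIC)


def fuse(flags: list[ModalityFlag], rule: FusionRule,
         cfg: DetectorConfig) -> list[AlarmEvent]:
    """Combine flags into DANGER events under ``rule`` with the configured
    fusion window and refractory period."""
    ordered = sorted(flags, key=lambda f: f.onset)
    events: list[AlarmEvent] = []
    last = -float("inf")
    for cand in ordered:
        t = cand.onset
        if t - last < cfg.refractory:
            continue
        active = {f.modality for f in ordered
                  if f.onset <= t and f.offset >= t - cfg.fusion_window}
        if rule.satisfied(active):
            events.append(AlarmEvent(
                time=t, state=AlarmState.DANGER,
                modalities=tuple(sorted(active, key=lambda m: m.value)),
            ))
            last = t
    return events


def apply_buttons(events: list[AlarmEvent], presses: list[ButtonPress],
                  cancel_window: float) -> list[AlarmEvent]:
    """Apply button presses to a finalized event list.

    A FALSE_ALARM press cancels the most recent un-cancelled DANGER within
    ``cancel_window`` before the press (marking ``cancelled_at`` and appending
    a FALSE_ALARM event referencing it); presses matching nothing are logged
    and dropped.  A PANIC press always appends a PANIC event.
    """
    out = sorted(events, key=lambda e: (e.time, _STATE_ORDER[e.state]))
    for press in sorted(presses, key=lambda p: p.t):
        if press.kind is AlarmState.PANIC:
            out.append(AlarmEvent(time=press.t, state=AlarmState.PANIC))
            continue
        target = None
        for idx in range(len(out) - 1, -1, -1):
            e = out[idx]
            if (e.state is AlarmState.DANGER and e.cancelled_at is None
                    and e.time <= press.t <= e.time + cancel_window):
                target = idx
                break
        if target is None:
            log.warning("false-alarm press at t=%.3f matches no DANGER; dropped",
                        press.t)
            continue
        e = out[target]
        out[target] = AlarmEvent(time=e.time, state=e.state,
                                 modalities=e.modalities,
                                 cancelled_at=press.t, ref=e.ref)
        out.append(AlarmEvent(time=press.t, state=AlarmState.FALSE_ALARM,
                              ref=e.time))
    out.sort(key=lambda e: (e.time, _STATE_ORDER[e.state]))
    return out


def render_alert(event: AlarmEvent) -> dict:
    """Serialize an event as the caregiver alert record: red for DANGER and
    PANIC, green for FALSE_ALARM; the location field is a placeholder filled
    by the phone in the deployed system."""
    color = "green" if event.state is AlarmState.FALSE_ALARM else "red"
    return {
        "time": event.time,
        "state": event.state.value,
        "modalities": [m.value for m in event.modalities],
        "color": color,
        "location": None,
    }
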