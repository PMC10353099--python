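"""Incremental (real-time) detection with bounded internal state.

:class:`StreamDetector` consumes frames one at a time, keeping only
ring buffers of window length (smoothing context, the rolling-baseline
history, the vibration edge window) plus the open indicator runs and the
recent flags the fusion window needs.  Its emitted event list is identical to
running the offline pipeline (``detect_all`` followed by ``fuse``) on the full
recording, because every windowed quantity is computed by the same numpy
kernel on the same sample window in both paths.

Alarms are necessarily emitted with a small bounded delay (an indicator run
only becomes a flag once it has lasted its minimum duration, and the centred
smoother needs half a window of look-ahead); the *timestamps* of the emitted
events are unaffected.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Iterable, Iterator, Optional

import numpy as np

from .core import (
    HR_RANGE,
    AlarmEvent,
    DetectorConfig,
    Modality,
    ModalityFlag,
    RecordingError,
    SampleFrame,
)
from .detectors import baseline_window_samples, smoothing_span
from .fusion import FusionRule, fuse

__all__ = ["StreamError", "StreamDetector", "stream_detect"]


class StreamError(RecordingError):
    """Out-of-order or malformed frame in a live stream."""


class _RunTracker:
    """Open/close bookkeeping for one indicator-run detector."""

    def __init__(self, modality: Modality, min_duration: float, mode: str,
                 band_centre: float = 0.0):
        self.modality = modality
        self.min_duration = min_duration
        self.mode = mode  # "max" | "min" | "band"
        self.band_centre = band_centre
        self.onset: Optional[float] = None
        self._evidence = 0.0
        self._best_dev = -1.0
        self.provisional_since: Optional[float] = None

    def update(self, t: float, indicator: bool, value: float) -> tuple[Optional[ModalityFlag], bool]:
        """Advance one sample; returns (closed flag or None, became-provisional)."""
        became = False
        flag = None
        if indicator:
            if self.onset is None:
                self.onset = t
                self._evidence = value
                self._best_dev = abs(value - self.band_centre)
            else:
                if self.mode == "max":
                    if value > self._evidence:
                        self._evidence = value
                elif self.mode == "min":
                    if value < self._evidence:
                        self._evidence = value
                else:  # band: most out-of-band estimate (first occurrence wins ties)
                    dev = abs(value - self.band_centre)
                    if dev > self._best_dev:
                        self._best_dev = dev
                        self._evidence = value
            if (self.provisional_since is None
                    and t - self.onset >= self.min_duration):
                self.provisional_since = t
                became = True
        elif self.onset is not None:
            flag = self._close(t)
        return flag, became

    def _close(self, offset: float) -> Optional[ModalityFlag]:
        flag = None
        if offset - self.onset >= self.min_duration:
            flag = ModalityFlag(self.modality, self.onset, offset, self._evidence)
        self.onset = None
        self.provisional_since = None
        return flag

    def finalize(self, offset: float) -> Optional[ModalityFlag]:
        if self.onset is None:
            return None
        return self._close(offset)

    def provisional(self, now: float) -> Optional[ModalityFlag]:
        if self.onset is not None and now - self.onset >= self.min_duration:
            return ModalityFlag(self.modality, self.onset, now, self._evidence)
        return None


class StreamDetector:
    """Bounded-state incremental seizure detector.

    Parameters
    ----------
    cfg:
        Detector configuration.
    rule:
        Fusion rule; defaults to the one named in ``cfg``.
    rate:
        Sampling rate in Hz.  Pass the recording's validated rate for exact
        offline equivalence; if omitted it is inferred from the first two
        frames.
    """

    def __init__(self, cfg: DetectorConfig, rule: Optional[FusionRule] = None,
                 rate: Optional[float] = None):
        self.cfg = cfg
        self.rule = rule or FusionRule.from_config(cfg)
        self.rate = rate
        self._pending_first: Optional[SampleFrame] = None
        self._ready = rate is not None
        self._i = -1
        self._prev_t: Optional[float] = None
        self._events: list[AlarmEvent] = []
        self._flags: list[ModalityFlag] = []
        self._pending_events: list[AlarmEvent] = []
        self._emitted = 0
        self._finalized = False
        # decision horizon: beyond this age an event can no longer change
        self._horizon = (
            max(cfg.min_fall_duration, cfg.min_tachycardia_duration,
                cfg.min_desaturation_duration, cfg.min_jerk_duration)
            + cfg.fall_pattern_window + cfg.smooth_window + cfg.vib_window + 1.0
        )
        if self._ready:
            self._setup()

    # -- lifecycle --------------------------------------------------------

    def _setup(self) -> None:
        cfg, rate = self.cfg, self.rate
        self._left, self._right = smoothing_span(cfg.smooth_window, rate)
        w = self._left + self._right + 1
        self._mbuf: deque[float] = deque(maxlen=w)
        fall_span = int(round(cfg.fall_pattern_window * rate)) + 2
        self._smbuf: deque[tuple[int, float, float]] = deque(maxlen=fall_span)
        self._prev_sm: Optional[float] = None
        self._fall_open: list[tuple[int, float]] = []
        self._tbuf: deque[float] = deque(maxlen=w)

        self._win_lo, self._win_hi, self._bstep = baseline_window_samples(cfg, rate)
        self._hrbuf: deque[float] = deque(maxlen=self._win_lo + 1)
        self._baseline = math.nan
        self._last_hr: Optional[tuple[float, float]] = None   # (value, t)
        self._last_spo2: Optional[tuple[float, float]] = None

        self._vib_n = int(round(cfg.vib_window * rate))
        self._edgebuf: deque[int] = deque(maxlen=self._vib_n)
        self._edge_count = 0
        self._prev_vib: Optional[int] = None

        centre = 0.5 * (cfg.f_low + cfg.f_high)
        self._tachy = _RunTracker(Modality.TACHYCARDIA,
                                  cfg.min_tachycardia_duration, "max")
        self._desat = _RunTracker(Modality.DESATURATION,
                                  cfg.min_desaturation_duration, "min")
        jerk_mode = "band" if cfg.band_semantics == "outside" else "max"
        self._jerk = _RunTracker(Modality.JERK, cfg.min_jerk_duration,
                                 jerk_mode, centre)

    def process(self, frame: SampleFrame) -> list[AlarmEvent]:
        """Consume one frame; return events newly finalized by it."""
        if self._finalized:
            raise StreamError("stream already finalized")
        self._validate(frame)
        if not self._ready:
            if self._pending_first is None:
                self._pending_first = frame
                self._prev_t = frame.t
                return []
            dt = frame.t - self._pending_first.t
            self.rate = 1.0 / dt
            self._ready = True
            self._setup()
            first, self._pending_first = self._pending_first, None
            self._prev_t = None
            out = self._process_ready(first)
            return out + self._process_ready(frame)
        return self._process_ready(frame)

    def finalize(self) -> list[AlarmEvent]:
        """Flush look-ahead buffers and open runs; return remaining events."""
        if self._finalized:
            return []
        self._finalized = True
        if not self._ready or self._i < 0:
            return []
        changed = False
        # smoothing tail: centres that were waiting for right context
        n = self._i + 1
        for c in range(max(0, n - self._right), n):
            changed |= self._emit_smoothed(c, tail=True)
        t_end = self._t_last + 1.0 / self.rate
        for tracker in (self._tachy, self._desat, self._jerk):
            flag = tracker.finalize(t_end)
            if flag is not None:
                self._flags.append(flag)
                changed = True
        if changed or True:
            self._refresh_fusion(provisional=False)
        out = self._pending_events[self._emitted:]
        self._events.extend(out)
        self._emitted = len(self._pending_events)
        return out

    # -- accessors --------------------------------------------------------

    @property
    def flags(self) -> list[ModalityFlag]:
        """Finalized modality flags so far, sorted like the offline detectors."""
        return sorted(self._flags, key=lambda f: (f.onset, f.modality.value))

    @property
    def events(self) -> list[AlarmEvent]:
        return list(self._events)

    # -- internals --------------------------------------------------------

    def _validate(self, frame: SampleFrame) -> None:
        if self._prev_t is not None and frame.t <= self._prev_t:
            raise StreamError(
                f"out-of-order frame: t={frame.t!r} after t={self._prev_t!r}")
        if frame.hr is not None and not (HR_RANGE[0] <= frame.hr <= HR_RANGE[1]):
            raise StreamError(f"hr out of range at t={frame.t!r}")
        if frame.spo2 is not None and not (0.0 <= frame.spo2 <= 100.0):
            raise StreamError(f"spo2 out of range at t={frame.t!r}")
        if frame.vib not in (0, 1):
            raise StreamError(f"vib not in {{0, 1}} at t={frame.t!r}")

    def _process_ready(self, frame: SampleFrame) -> list[AlarmEvent]:
        self._prev_t = frame.t
        self._i += 1
        i = self._i
        t = frame.t
        self._t_last = t
        changed = False

        # acceleration -> magnitude -> (delayed) smoothed sample
        m = np.sqrt(frame.ax ** 2 + frame.ay ** 2 + frame.az ** 2)
        self._mbuf.append(float(m))
        self._tbuf.append(t)
        c = i - self._right
        if c >= 0:
            changed |= self._emit_smoothed(c, tail=False)

        # slow channels: forward fill with staleness age; a value is a fresh
        # observation only when its staleness age is zero (frames replayed
        # from a Recording carry already-filled values with their true age)
        if frame.hr is not None and frame.hr_age == 0.0:
            self._last_hr = (frame.hr, t)
        if frame.spo2 is not None and frame.spo2_age == 0.0:
            self._last_spo2 = (frame.spo2, t)
        hr = self._last_hr[0] if self._last_hr else math.nan
        hr_age = t - self._last_hr[1] if self._last_hr else math.inf
        sp = self._last_spo2[0] if self._last_spo2 else math.nan
        sp_age = t - self._last_spo2[1] if self._last_spo2 else math.inf

        # rolling heart-rate baseline on the anchor grid
        cfg = self.cfg
        if cfg.baseline_mode == "fixed":
            self._baseline = float(cfg.baseline_fixed)
        else:
            self._hrbuf.append(hr)
            if i >= self._win_lo and i % self._bstep == 0:
                arr = np.array(self._hrbuf)[0: self._win_lo - self._win_hi + 1]
                arr = arr[~np.isnan(arr)]
                self._baseline = float(np.median(arr)) if len(arr) else math.nan
            elif i < self._win_lo:
                self._baseline = math.nan

        excess = hr - self._baseline
        tachy_on = (hr_age <= cfg.staleness_limit and not math.isnan(excess)
                    and excess >= cfg.hr_delta)
        flag, became = self._tachy.update(t, tachy_on, excess)
        changed |= self._note(flag, became)

        desat_on = (sp_age <= cfg.staleness_limit and not math.isnan(sp)
                    and sp < cfg.spo2_min)
        flag, became = self._desat.update(t, desat_on, sp)
        changed |= self._note(flag, became)

        # vibration frequency over the trailing window
        edge = 1 if (self._prev_vib == 0 and frame.vib == 1) else 0
        self._prev_vib = frame.vib
        if len(self._edgebuf) == self._edgebuf.maxlen:
            self._edge_count -= self._edgebuf[0]
        self._edgebuf.append(edge)
        self._edge_count += edge
        freq = math.nan
        if i >= self._vib_n and self._edge_count >= cfg.vib_min_edges:
            freq = self._edge_count / cfg.vib_window
        if math.isnan(freq):
            jerk_on = False
        elif cfg.band_semantics == "outside":
            jerk_on = freq < cfg.f_low or freq > cfg.f_high
        else:
            jerk_on = cfg.f_low <= freq <= cfg.f_high
        flag, became = self._jerk.update(t, jerk_on, freq)
        changed |= self._note(flag, became)

        if changed:
            self._refresh_fusion(provisional=True)
        # release pending events past the decision horizon
        out: list[AlarmEvent] = []
        while (self._emitted < len(self._pending_events)
               and self._pending_events[self._emitted].time <= t - self._horizon):
            out.append(self._pending_events[self._emitted])
            self._emitted += 1
        self._events.extend(out)
        return out

    def _note(self, flag: Optional[ModalityFlag], became: bool) -> bool:
        if flag is not None:
            self._flags.append(flag)
            return True
        return became

    def _emit_smoothed(self, c: int, tail: bool) -> bool:
        """Compute the smoothed magnitude at centre ``c`` and advance the fall
        pattern machine.  Returns True if a FALL flag was finalized."""
        i = self._i
        lo = max(0, c - self._left)
        # buffer spans [i - len + 1, i]
        base = i - len(self._mbuf) + 1
        a = lo - base
        b = (min(i, c + self._right) if tail else i) - base + 1
        arr = np.array(self._mbuf, dtype=float)[a:b]
        v = float(np.mean(arr))
        tc = self._tbuf[c - base]
        return self._fall_step(c, tc, v)

    def _fall_step(self, c: int, tc: float, v: float) -> bool:
        cfg = self.cfg
        up = v > cfg.a_high and (self._prev_sm is None or self._prev_sm <= cfg.a_high)
        self._prev_sm = v
        self._smbuf.append((c, tc, v))
        if up:
            self._fall_open.append((c, tc))
        self._fall_open = [(ci, ti) for (ci, ti) in self._fall_open
                           if tc - ti <= cfg.fall_pattern_window]
        changed = False
        if v < cfg.a_low and self._fall_open:
            c0, t0 = self._fall_open[0]
            if tc - t0 >= cfg.min_fall_duration:
                evidence = max(vv for (cc, _, vv) in self._smbuf if cc >= c0)
                self._flags.append(ModalityFlag(Modality.FALL, t0, tc, evidence))
                changed = True
            self._fall_open.clear()
        return changed

    def _refresh_fusion(self, provisional: bool) -> None:
        flags = list(self._flags)
        if provisional:
            now = self._t_last
            for tracker in (self._tachy, self._desat, self._jerk):
                p = tracker.provisional(now)
                if p is not None:
                    flags.append(p)
        self._pending_events = fuse(flags, self.rule, self.cfg)


def stream_detect(frames: Iterable[SampleFrame], cfg: DetectorConfig,
                  rule: Optional[FusionRule] = None,
                  rate: Optional[float] = None) -> Iterator[AlarmEvent]:
    """Run incremental detection over an in-order frame iterable, yielding
    alarm events as they become final."""
    det = StreamDetector(cfg, rule, rate)
    for frame in frames:
        yield from det.process(frame)
    yield from det.finalize()
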