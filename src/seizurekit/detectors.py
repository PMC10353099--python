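"""Per-modality threshold detectors.

Each detector is a pure function of a validated :class:`~seizurekit.core.Recording`
and a :class:`~seizurekit.core.DetectorConfig`, returning time-sorted
:class:`~seizurekit.core.ModalityFlag` intervals:

* **FALL** — the smoothed acceleration magnitude crosses above ``a_high``
  (23.4 m/s² by default, the impact) and subsequently drops below ``a_low``
  (10 m/s², the body absorbing the energy) within ``fall_pattern_window``.
* **TACHYCARDIA** — heart rate exceeds the personal baseline by at least
  ``hr_delta`` (10 bpm) for ``min_tachycardia_duration``.
* **DESATURATION** — SpO2 strictly below ``spo2_min`` (90 %) for
  ``min_desaturation_duration``.
* **JERK** — the vibration channel is active (enough rising edges in the
  estimation window) at a frequency outside the 3–17 Hz band of normal body
  vibration, for ``min_jerk_duration``.

Stale slow channels (hr/spo2 older than ``staleness_limit``) disable the
corresponding detector rather than emitting flags from frozen values.

Indicator-run flags (TACHYCARDIA, DESATURATION, JERK) use half-open
intervals: ``offset`` is the time of the first sample after the run (or the
last sample plus one interval at end of recording).  FALL flags use the
high-crossing and low-crossing sample times as onset/offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DetectorConfig, Modality, ModalityFlag, Recording

__all__ = [
    "MagnitudeSeries",
    "accel_magnitude",
    "smooth",
    "detect_fall",
    "hr_baseline",
    "detect_tachycardia",
    "detect_desaturation",
    "vibration_frequency",
    "jerk_frequency_series",
    "detect_jerk",
    "detect_all",
]

log = logging.getLogger(__name__)


@dataclass
class MagnitudeSeries:
    """Acceleration magnitude on the recording's sample grid."""

    t: np.ndarray
    m: np.ndarray
    rate: float

    def __len__(self) -> int:
        return len(self.t)


def accel_magnitude(rec: Recording) -> MagnitudeSeries:
    """Euclidean norm of the triaxial acceleration, sample by sample."""
    m = np.sqrt(rec.ax ** 2 + rec.ay ** 2 + rec.az ** 2)
    return MagnitudeSeries(t=rec.t, m=m, rate=rec.rate)


def smoothing_span(window: float, rate: float) -> tuple[int, int]:
    """(left, right) half-window sample counts of the centred moving average.

    A window shorter than ~1.5 sample intervals degenerates to the identity.
    For an even sample count the extra sample goes to the past (causal) side.
    """
    n = int(round(window * rate))
    if n <= 1:
        return 0, 0
    left = n // 2
    right = n - 1 - left
    return left, right


def smooth(series: MagnitudeSeries, window: float) -> MagnitudeSeries:
    """Centred moving average; partial windows at the edges are averaged over
    the available samples only."""
    left, right = smoothing_span(window, series.rate)
    if left == 0 and right == 0:
        return MagnitudeSeries(series.t, series.m.copy(), series.rate)
    m = series.m
    n = len(m)
    out = np.empty(n)
    w = left + right + 1
    if n >= w:
        # full windows: identical FP result to a per-window np.mean
        out[left:n - right] = sliding_window_view(m, w).mean(axis=1)
        head = range(left)
        tail = range(n - right, n)
    else:
        head = range(n)
        tail = range(0)
    for i in head:
        out[i] = np.mean(m[max(0, i - left): i + right + 1])
    for i in tail:
        out[i] = np.mean(m[i - left: min(n, i + right + 1)])
    return MagnitudeSeries(series.t, out, series.rate)


def detect_fall(series: MagnitudeSeries, cfg: DetectorConfig) -> list[ModalityFlag]:
    """High-then-low impact pattern on the smoothed magnitude.

    An upward crossing of ``a_high`` followed by the first sample below
    ``a_low`` within ``fall_pattern_window`` forms a candidate
    ``[crossing, drop]``; candidates sharing samples merge into one flag.
    Evidence is the peak magnitude inside the (merged) interval.
    """
    m = series.m
    t = series.t
    n = len(m)
    if n == 0:
        return []
    above = m > cfg.a_high
    up = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if len(up) == 0:
        return []
    lows = np.flatnonzero(m < cfg.a_low)
    flags: list[ModalityFlag] = []
    intervals: list[list[int]] = []  # merged [i, j] index intervals
    for i in up:
        k = np.searchsorted(lows, i + 1)
        if k == len(lows):
            continue
        j = int(lows[k])
        if t[j] - t[i] > cfg.fall_pattern_window:
            continue
        if intervals and i <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], j)
        else:
            intervals.append([int(i), j])
    for i, j in intervals:
        onset, offset = float(t[i]), float(t[j])
        if offset - onset < cfg.min_fall_duration:
            continue
        flags.append(ModalityFlag(Modality.FALL, onset, offset,
                                  float(np.max(m[i:j + 1]))))
    return flags


# ---------------------------------------------------------------------------
# heart rate


def baseline_window_samples(cfg: DetectorConfig, rate: float) -> tuple[int, int, int]:
    """(lookback, gap, anchor step) in samples for the rolling baseline."""
    win_lo = int(round(cfg.baseline_window * rate))
    win_hi = int(round(cfg.baseline_gap * rate))
    step = max(1, int(round(cfg.baseline_update * rate)))
    return win_lo, win_hi, step


def hr_baseline(rec: Recording, cfg: DetectorConfig) -> np.ndarray:
    """Personal heart-rate baseline in bpm, per sample (NaN = undefined).

    Fixed mode returns the configured constant.  Rolling mode takes, on a
    ``baseline_update`` anchor grid, the median of the forward-filled heart
    rate over ``[t - baseline_window, t - baseline_gap]`` and holds it
    constant until the next anchor; it is undefined until a full
    ``baseline_window`` of history exists.  The gap keeps an ongoing ictal
    rise from inflating its own baseline.
    """
    n = len(rec)
    if cfg.baseline_mode == "fixed":
        if cfg.baseline_fixed is None:
            raise ValueError("fixed baseline mode requires baseline_fixed")
        return np.full(n, float(cfg.baseline_fixed))
    win_lo, win_hi, step = baseline_window_samples(cfg, rec.rate)
    out = np.full(n, np.nan)
    hr = rec.hr
    for i in range(0, n, step):
        if i - win_lo < 0:
            continue
        window = hr[i - win_lo: i - win_hi + 1]
        window = window[~np.isnan(window)]
        if len(window) == 0:
            continue
        out[i: i + step] = np.median(window)
    return out


def _run_flags(rec: Recording, indicator: np.ndarray, modality: Modality,
               min_duration: float, evidence_fn) -> list[ModalityFlag]:
    """Turn a boolean per-sample indicator into maximal-interval flags."""
    n = len(indicator)
    if n == 0:
        return []
    dt = 1.0 / rec.rate
    padded = np.concatenate(([False], indicator, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    flags = []
    for i, j in zip(starts, ends):
        onset = float(rec.t[i])
        offset = float(rec.t[j]) if j < n else float(rec.t[n - 1] + dt)
        if offset - onset < min_duration:
            continue
        flags.append(ModalityFlag(modality, onset, offset,
                                  float(evidence_fn(i, j))))
    return flags


def detect_tachycardia(rec: Recording, baseline: np.ndarray,
                       cfg: DetectorConfig) -> list[ModalityFlag]:
    """Maximal intervals with hr − baseline ≥ ``hr_delta``; evidence is the
    peak excess in bpm."""
    if np.all(np.isnan(rec.hr)):
        log.warning("heart-rate channel entirely missing; tachycardia detector idle")
        return []
    fresh = rec.hr_age <= cfg.staleness_limit
    with np.errstate(invalid="ignore"):
        excess = rec.hr - baseline
        indicator = fresh & ~np.isnan(excess) & (excess >= cfg.hr_delta)
    return _run_flags(rec, indicator, Modality.TACHYCARDIA,
                      cfg.min_tachycardia_duration,
                      lambda i, j: np.max(excess[i:j]))


def detect_desaturation(rec: Recording, cfg: DetectorConfig) -> list[ModalityFlag]:
    """Maximal intervals with SpO2 strictly below ``spo2_min``; evidence is
    the minimum SpO2 reached."""
    if np.all(np.isnan(rec.spo2)):
        log.warning("SpO2 channel entirely missing; desaturation detector idle")
        return []
    fresh = rec.spo2_age <= cfg.staleness_limit
    with np.errstate(invalid="ignore"):
        indicator = fresh & ~np.isnan(rec.spo2) & (rec.spo2 < cfg.spo2_min)
    return _run_flags(rec, indicator, Modality.DESATURATION,
                      cfg.min_desaturation_duration,
                      lambda i, j: np.min(rec.spo2[i:j]))


# ---------------------------------------------------------------------------
# vibration


def rising_edges(vib: np.ndarray) -> np.ndarray:
    """Per-sample 0→1 transition indicator (an edge needs an observed 0)."""
    e = np.zeros(len(vib), dtype=np.int64)
    if len(vib) > 1:
        e[1:] = (vib[1:] == 1) & (vib[:-1] == 0)
    return e


def jerk_frequency_series(rec: Recording, cfg: DetectorConfig) -> np.ndarray:
    """Estimated vibration frequency in Hz per sample (NaN = inactive or
    window not yet inside the recording).

    The frequency over the trailing window ``(t - vib_window, t]`` is the
    rising-edge count divided by the window length; below ``vib_min_edges``
    edges the channel counts as inactive.
    """
    n = len(rec)
    win_n = int(round(cfg.vib_window * rec.rate))
    out = np.full(n, np.nan)
    if n <= win_n:
        return out
    e = rising_edges(rec.vib)
    csum = np.concatenate(([0], np.cumsum(e)))
    idx = np.arange(win_n, n)
    counts = csum[idx + 1] - csum[idx + 1 - win_n]
    active = counts >= cfg.vib_min_edges
    out[idx[active]] = counts[active] / cfg.vib_window
    return out


def vibration_frequency(rec: Recording, cfg: DetectorConfig, t: float):
    """Estimated vibration frequency at time ``t`` (Hz), or ``None`` when the
    channel is inactive.  The window ``[t - vib_window, t]`` must lie inside
    the recording."""
    win_n = int(round(cfg.vib_window * rec.rate))
    i = int(np.searchsorted(rec.t, t, side="right")) - 1
    if i < win_n or i >= len(rec):
        raise ValueError("vibration window not inside the recording")
    f = jerk_frequency_series(rec, cfg)[i]
    return None if np.isnan(f) else float(f)


def detect_jerk(rec: Recording, cfg: DetectorConfig) -> list[ModalityFlag]:
    """Maximal intervals of active vibration at a frequency outside (default
    semantics) or inside the ``f_low``–``f_high`` band.  Evidence is the most
    extreme estimated frequency in the interval (farthest out of band for
    "outside", highest for "inside")."""
    f = jerk_frequency_series(rec, cfg)
    with np.errstate(invalid="ignore"):
        if cfg.band_semantics == "outside":
            indicator = ~np.isnan(f) & ((f < cfg.f_low) | (f > cfg.f_high))
        else:
            indicator = ~np.isnan(f) & (f >= cfg.f_low) & (f <= cfg.f_high)

    centre = 0.5 * (cfg.f_low + cfg.f_high)

    def evidence(i: int, j: int) -> float:
        vals = f[i:j]
        if cfg.band_semantics == "outside":
            return vals[int(np.argmax(np.abs(vals - centre)))]
        return np.max(vals)

    return _run_flags(rec, indicator, Modality.JERK, cfg.min_jerk_duration,
                      evidence)


def detect_all(rec: Recording, cfg: DetectorConfig) -> list[ModalityFlag]:
    """Run all four detectors and return their flags sorted by onset."""
    series = smooth(accel_magnitude(rec), cfg.smooth_window)
    flags = detect_fall(series, cfg)
    baseline = hr_baseline(rec, cfg)
    flags += detect_tachycardia(rec, baseline, cfg)
    flags += detect_desaturation(rec, cfg)
    flags += detect_jerk(rec, cfg)
    flags.sort(key=lambda fl: (fl.onset, fl.modality.value))
    return flags
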