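"""Domain types, configuration and I/O for multimodal seizure recordings.

A recording is a uniformly sampled multichannel time series: triaxial
acceleration in m/s² (streamed at the frame rate), sensor-reported heart rate
in bpm and oxygen saturation in percent (slow channels, typically ~1 Hz,
carried between observations by forward fill with a per-channel staleness
age), and a binary vibration channel.  Timestamps are seconds since the start
of the recording; intervals are half-open ``[onset, offset)`` unless stated
otherwise.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Modality",
    "AlarmState",
    "SampleFrame",
    "Recording",
    "DetectorConfig",
    "ModalityFlag",
    "AlarmEvent",
    "EpisodeAnnotation",
    "ButtonPress",
    "RecordingError",
    "ConfigError",
    "read_recording",
    "write_recording",
    "load_config",
    "write_flags",
    "read_flags",
    "write_events",
    "read_events",
    "write_annotations",
    "read_annotations",
    "read_button_presses",
    "write_button_presses",
]

RECORDING_COLUMNS = ("t", "ax", "ay", "az", "hr", "spo2", "vib")

HR_RANGE = (20.0, 250.0)


class RecordingError(ValueError):
    """A recording file or frame stream violates the format contract."""


class ConfigError(ValueError):
    """A detector configuration violates its invariants."""


class Modality(str, enum.Enum):
    FALL = "FALL"
    TACHYCARDIA = "TACHYCARDIA"
    DESATURATION = "DESATURATION"
    JERK = "JERK"


class AlarmState(str, enum.Enum):
    DANGER = "DANGER"
    FALSE_ALARM = "FALSE_ALARM"
    PANIC = "PANIC"


@dataclass(frozen=True)
class SampleFrame:
    """One time-stamped multimodal sample.

    ``hr``/``spo2`` are the forward-filled channel values (``None`` before the
    first observation); ``hr_age``/``spo2_age`` give the seconds since the last
    actual observation (0.0 at an observation, ``inf`` before the first).
    """

    t: float
    ax: float
    ay: float
    az: float
    hr: Optional[float]
    spo2: Optional[float]
    vib: int
    hr_age: float = 0.0
    spo2_age: float = 0.0


class Recording(Sequence[SampleFrame]):
    """A validated, uniformly sampled recording.

    Column arrays are exposed as numpy attributes (``t``, ``ax`` ... ``vib``,
    ``hr_age``, ``spo2_age``); indexing and iteration yield
    :class:`SampleFrame` objects, so the object doubles as the "sequence of
    frames" the detectors and the streaming engine consume.
    """

    def __init__(
        self,
        t: np.ndarray,
        ax: np.ndarray,
        ay: np.ndarray,
        az: np.ndarray,
        hr: np.ndarray,
        spo2: np.ndarray,
        vib: np.ndarray,
        hr_age: np.ndarray,
        spo2_age: np.ndarray,
        rate: float,
    ):
        self.t = np.asarray(t, dtype=float)
        self.ax = np.asarray(ax, dtype=float)
        self.ay = np.asarray(ay, dtype=float)
        self.az = np.asarray(az, dtype=float)
        self.hr = np.asarray(hr, dtype=float)  # NaN before first observation
        self.spo2 = np.asarray(spo2, dtype=float)
        self.vib = np.asarray(vib, dtype=np.int64)
        self.hr_age = np.asarray(hr_age, dtype=float)
        self.spo2_age = np.asarray(spo2_age, dtype=float)
        self.rate = float(rate)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_channels(
        cls,
        t: np.ndarray,
        ax: np.ndarray,
        ay: np.ndarray,
        az: np.ndarray,
        hr_raw: np.ndarray,
        spo2_raw: np.ndarray,
        vib: np.ndarray,
        expected_rate: Optional[float] = None,
    ) -> "Recording":
        """Validate raw channel arrays (NaN = missing for hr/spo2) and build a
        recording with forward-filled slow channels."""
        t = np.asarray(t, dtype=float)
        n = len(t)
        if n < 2:
            raise RecordingError("a recording needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise RecordingError(
                f"non-monotonic timestamps at sample {i + 1} (t={t[i + 1]!r})"
            )
        dt_med = float(np.median(dt))
        if np.any(np.abs(dt - dt_med) > 0.01 * dt_med):
            raise RecordingError("sampling interval varies by more than 1%")
        rate = 1.0 / dt_med
        if expected_rate is not None and abs(rate - expected_rate) > 0.01 * expected_rate:
            raise RecordingError(
                f"inferred rate {rate:.3f} Hz differs from expected {expected_rate} Hz"
            )

        hr_raw = np.asarray(hr_raw, dtype=float)
        spo2_raw = np.asarray(spo2_raw, dtype=float)
        vib = np.asarray(vib)
        hr_obs = ~np.isnan(hr_raw)
        if np.any((hr_raw[hr_obs] < HR_RANGE[0]) | (hr_raw[hr_obs] > HR_RANGE[1])):
            bad = int(np.flatnonzero(hr_obs)[
                np.argmax((hr_raw[hr_obs] < HR_RANGE[0]) | (hr_raw[hr_obs] > HR_RANGE[1]))
            ])
            raise RecordingError(f"hr out of range [20, 250] at sample {bad}")
        sp_obs = ~np.isnan(spo2_raw)
        if np.any((spo2_raw[sp_obs] < 0) | (spo2_raw[sp_obs] > 100)):
            bad = int(np.flatnonzero(sp_obs)[
                np.argmax((spo2_raw[sp_obs] < 0) | (spo2_raw[sp_obs] > 100))
            ])
            raise RecordingError(f"spo2 out of range [0, 100] at sample {bad}")
        if not np.all(np.isin(vib, (0, 1))):
            bad = int(np.argmax(~np.isin(vib, (0, 1))))
            raise RecordingError(f"vib not in {{0, 1}} at sample {bad}")

        hr_f, hr_age = forward_fill(t, hr_raw)
        sp_f, sp_age = forward_fill(t, spo2_raw)
        return cls(t, ax, ay, az, hr_f, sp_f, vib.astype(np.int64), hr_age, sp_age, rate)

    # -- sequence protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i):  # type: ignore[override]
        if isinstance(i, slice):
            raise TypeError("slicing a Recording is not supported")
        hr = None if math.isnan(self.hr[i]) else float(self.hr[i])
        sp = None if math.isnan(self.spo2[i]) else float(self.spo2[i])
        return SampleFrame(
            t=float(self.t[i]), ax=float(self.ax[i]), ay=float(self.ay[i]),
            az=float(self.az[i]), hr=hr, spo2=sp, vib=int(self.vib[i]),
            hr_age=float(self.hr_age[i]), spo2_age=float(self.spo2_age[i]),
        )

    def __iter__(self) -> Iterator[SampleFrame]:
        for i in range(len(self)):
            yield self[i]

    @property
    def duration(self) -> float:
        """Recording span in seconds (half-open: last sample + one interval)."""
        return float(self.t[-1]) + 1.0 / self.rate


def forward_fill(t: np.ndarray, raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward-fill a sparsely observed channel; return (filled, staleness age).

    ``age[i]`` is ``t[i] - t[last observation <= i]``; ``inf`` (and NaN value)
    before the first observation.
    """
    n = len(t)
    obs = ~np.isnan(raw)
    idx = np.where(obs, np.arange(n), -1)
    last = np.maximum.accumulate(idx)
    filled = np.full(n, np.nan)
    age = np.full(n, np.inf)
    have = last >= 0
    filled[have] = raw[last[have]]
    age[have] = t[have] - t[last[have]]
    return filled, age


# ---------------------------------------------------------------------------
# configuration


class DetectorConfig(BaseModel):
    """All thresholds, windows and fusion settings of the detection pipeline.

    Defaults are the published decision rule: a fall is an excursion of the
    smoothed acceleration magnitude above 23.4 m/s² followed within
    ``fall_pattern_window`` by a drop below 10 m/s²; ictal tachycardia is a
    rise of ≥ 10 bpm over the personal baseline; desaturation is SpO2 below
    90 %; jerky movement is sustained vibration at a frequency outside the
    3–17 Hz band of normal body vibration.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    a_high: float = 23.4       # m/s², fall impact threshold
    a_low: float = 10.0        # m/s², post-impact drop threshold
    hr_delta: float = 10.0     # bpm over baseline
    spo2_min: float = 90.0     # percent
    f_low: float = 3.0         # Hz, lower band edge
    f_high: float = 17.0       # Hz, upper band edge

    smooth_window: float = 0.5          # s, acceleration moving average
    fall_pattern_window: float = 2.0    # s, max high->low crossing gap

    baseline_mode: Literal["fixed", "rolling"] = "rolling"
    baseline_fixed: Optional[float] = None  # bpm, required in fixed mode
    baseline_window: float = 300.0      # s of history for the rolling median
    baseline_gap: float = 30.0          # s excluded just before the present
    baseline_update: float = 1.0        # s between rolling-baseline refreshes

    vib_window: float = 2.0             # s, frequency-estimation window
    vib_min_edges: int = 4              # rising edges for the activity gate
    band_semantics: Literal["outside", "inside"] = "outside"

    fusion_rule: Literal["ANY", "K_OF_N", "MOTOR_AND_AUTONOMIC"] = "MOTOR_AND_AUTONOMIC"
    fusion_k: int = 2
    fusion_window: float = 30.0         # s, co-occurrence span
    refractory: float = 60.0            # s after a DANGER alarm
    cancel_window: float = 120.0        # s for the false-alarm button

    min_fall_duration: float = 0.0
    min_tachycardia_duration: float = 10.0
    min_desaturation_duration: float = 5.0
    min_jerk_duration: float = 2.0

    staleness_limit: float = 10.0       # s; older hr/spo2 disables the detector

    @model_validator(mode="after")
    def _check(self) -> "DetectorConfig":
        if not (self.a_high > self.a_low > 0):
            raise ValueError("require a_high > a_low > 0")
        if not (self.f_high > self.f_low > 0):
            raise ValueError("require f_high > f_low > 0")
        if not (0 < self.spo2_min <= 100):
            raise ValueError("require 0 < spo2_min <= 100")
        if self.hr_delta <= 0:
            raise ValueError("require hr_delta > 0")
        for name in ("smooth_window", "fall_pattern_window", "baseline_window",
                     "baseline_gap", "baseline_update", "vib_window",
                     "fusion_window", "refractory", "cancel_window",
                     "staleness_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"require {name} > 0")
        for name in ("min_fall_duration", "min_tachycardia_duration",
                     "min_desaturation_duration", "min_jerk_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"require {name} >= 0")
        if not (1 <= self.fusion_k <= 4):
            raise ValueError("require 1 <= fusion_k <= 4")
        if self.baseline_gap >= self.baseline_window:
            raise ValueError("require baseline_gap < baseline_window")
        if self.vib_min_edges < 1:
            raise ValueError("require vib_min_edges >= 1")
        if self.baseline_mode == "fixed" and self.baseline_fixed is None:
            raise ValueError("fixed baseline mode requires baseline_fixed")
        if self.baseline_fixed is not None and self.baseline_fixed <= 0:
            raise ValueError("require baseline_fixed > 0")
        return self

    def min_duration(self, modality: Modality) -> float:
        return {
            Modality.FALL: self.min_fall_duration,
            Modality.TACHYCARDIA: self.min_tachycardia_duration,
            Modality.DESATURATION: self.min_desaturation_duration,
            Modality.JERK: self.min_jerk_duration,
        }[modality]


def load_config(path: Union[str, Path]) -> DetectorConfig:
    """Load a flat JSON config; missing keys take the published defaults,
    unknown keys are rejected."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ConfigError("config must be a JSON object")
    try:
        return DetectorConfig(**obj)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# detection outputs and annotations


@dataclass(frozen=True)
class ModalityFlag:
    """A per-channel detection interval with its evidence value.

    Evidence is the peak smoothed magnitude (FALL), max HR excess over
    baseline (TACHYCARDIA), min SpO2 (DESATURATION) or the most out-of-band
    estimated frequency (JERK).
    """

    modality: Modality
    onset: float
    offset: float
    evidence: float

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError("flag offset must be >= onset")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality.value,
            "onset": self.onset,
            "offset": self.offset,
            "evidence": self.evidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModalityFlag":
        return cls(Modality(d["modality"]), float(d["onset"]),
                   float(d["offset"]), float(d["evidence"]))


@dataclass(frozen=True)
class AlarmEvent:
    """A fused detection (DANGER), its cancellation (FALSE_ALARM) or a manual
    PANIC call.  ``ref`` on a FALSE_ALARM is the time of the DANGER it cancels;
    PANIC carries an empty modality set."""

    time: float
    state: AlarmState
    modalities: tuple[Modality, ...] = ()
    cancelled_at: Optional[float] = None
    ref: Optional[float] = None

    def to_dict(self) -> dict:
        d: dict = {
            "time": self.time,
            "state": self.state.value,
            "modalities": [m.value for m in self.modalities],
        }
        if self.cancelled_at is not None:
            d["cancelled_at"] = self.cancelled_at
        if self.ref is not None:
            d["ref"] = self.ref
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AlarmEvent":
        return cls(
            time=float(d["time"]),
            state=AlarmState(d["state"]),
            modalities=tuple(Modality(m) for m in d["modalities"]),
            cancelled_at=None if d.get("cancelled_at") is None else float(d["cancelled_at"]),
            ref=None if d.get("ref") is None else float(d["ref"]),
        )


@dataclass(frozen=True)
class EpisodeAnnotation:
    """Ground-truth seizure interval with the set of injected signatures."""

    onset: float
    offset: float
    signature: tuple[Modality, ...] = (
        Modality.FALL, Modality.TACHYCARDIA, Modality.DESATURATION, Modality.JERK,
    )

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("annotation offset must be > onset")

    def to_dict(self) -> dict:
        return {
            "onset": self.onset,
            "offset": self.offset,
            "signature": [m.value for m in self.signature],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpisodeAnnotation":
        return cls(float(d["onset"]), float(d["offset"]),
                   tuple(Modality(m) for m in d["signature"]))


@dataclass(frozen=True)
class ButtonPress:
    """A time-stamped press of the false-alarm or panic button."""

    t: float
    kind: AlarmState  # FALSE_ALARM or PANIC

    def __post_init__(self) -> None:
        if self.kind is AlarmState.DANGER:
            raise ValueError("a button press is FALSE_ALARM or PANIC")

    def to_dict(self) -> dict:
        return {"t": self.t, "kind": self.kind.value}

    @classmethod
    def from_dict(cls, d: dict) -> "ButtonPress":
        return cls(float(d["t"]), AlarmState(d["kind"]))


# ---------------------------------------------------------------------------
# file I/O


def read_recording(path: Union[str, Path],
                   expected_rate: Optional[float] = None) -> Recording:
    """Read and validate a recording CSV (header ``t,ax,ay,az,hr,spo2,vib``).

    Empty cells mean "missing" for hr/spo2 only; the slow channels are
    forward-filled with their staleness age retained.  Errors name the
    offending 1-based file line.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingError(f"no such recording file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != RECORDING_COLUMNS:
        raise RecordingError(
            f"bad header {tuple(df.columns)!r}; expected {','.join(RECORDING_COLUMNS)}"
        )
    if len(df) == 0:
        raise RecordingError("recording is empty")

    def col(name: str, allow_blank: bool) -> np.ndarray:
        s = df[name].str.strip()
        blank = s == ""
        if not allow_blank and blank.any():
            line = int(np.argmax(blank.to_numpy())) + 2
            raise RecordingError(f"malformed row: empty {name!r} cell at line {line}")
        v = pd.to_numeric(s.where(~blank, other=None), errors="coerce").to_numpy(float)
        bad = np.isnan(v) & ~blank.to_numpy()
        if bad.any():
            line = int(np.argmax(bad)) + 2
            raise RecordingError(f"malformed row: non-numeric {name!r} at line {line}")
        return v

    t = col("t", False)
    ax = col("ax", False)
    ay = col("ay", False)
    az = col("az", False)
    hr = col("hr", True)
    spo2 = col("spo2", True)
    vib_f = col("vib", False)
    if not np.all(np.isin(vib_f, (0.0, 1.0))):
        line = int(np.argmax(~np.isin(vib_f, (0.0, 1.0)))) + 2
        raise RecordingError(f"vib not in {{0, 1}} at line {line}")
    try:
        return Recording.from_channels(t, ax, ay, az, hr, spo2,
                                       vib_f.astype(np.int64), expected_rate)
    except RecordingError as exc:
        raise RecordingError(str(exc)) from None


def write_recording(rec: Recording, path: Union[str, Path]) -> None:
    """Write a recording CSV; hr/spo2 cells are blank except at observations
    (staleness age 0), so the file round-trips through :func:`read_recording`."""
    lines = ["t,ax,ay,az,hr,spo2,vib"]
    hr_cell = np.where(rec.hr_age == 0.0,
                       np.char.mod("%.6f", np.nan_to_num(rec.hr)), "")
    sp_cell = np.where(rec.spo2_age == 0.0,
                       np.char.mod("%.6f", np.nan_to_num(rec.spo2)), "")
    tc = np.char.mod("%.6f", rec.t)
    axc = np.char.mod("%.6f", rec.ax)
    ayc = np.char.mod("%.6f", rec.ay)
    azc = np.char.mod("%.6f", rec.az)
    vc = np.char.mod("%d", rec.vib)
    for i in range(len(rec)):
        lines.append(f"{tc[i]},{axc[i]},{ayc[i]},{azc[i]},{hr_cell[i]},{sp_cell[i]},{vc[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_json_array(items, path) -> None:
    Path(path).write_text(
        json.dumps([it.to_dict() for it in items], indent=2) + "\n"
    )


def _read_json_array(path, factory):
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON array")
    return [factory(d) for d in data]


def write_flags(flags: Sequence[ModalityFlag], path: Union[str, Path]) -> None:
    _write_json_array(flags, path)


def read_flags(path: Union[str, Path]) -> list[ModalityFlag]:
    return _read_json_array(path, ModalityFlag.from_dict)


def write_events(events: Sequence[AlarmEvent], path: Union[str, Path]) -> None:
    _write_json_array(events, path)


def read_events(path: Union[str, Path]) -> list[AlarmEvent]:
    return _read_json_array(path, AlarmEvent.from_dict)


def write_annotations(annotations: Sequence[EpisodeAnnotation],
                      path: Union[str, Path]) -> None:
    _write_json_array(annotations, path)


def read_annotations(path: Union[str, Path]) -> list[EpisodeAnnotation]:
    anns = _read_json_array(path, EpisodeAnnotation.from_dict)
    anns.sort(key=lambda a: a.onset)
    for a, b in zip(anns, anns[1:]):
        if b.onset < a.offset:
            raise ValueError("annotations overlap")
    return anns


def write_button_presses(presses: Sequence[ButtonPress],
                         path: Union[str, Path]) -> None:
    _write_json_array(presses, path)


def read_button_presses(path: Union[str, Path]) -> list[ButtonPress]:
    return _read_json_array(path, ButtonPress.from_dict)
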