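"""Seeded synthetic multimodal recordings with ground-truth annotations.

The generator emulates what the wearable's sensors report, not raw
physiology: triaxial acceleration around gravity with Gaussian noise, a
sensor-reported heart rate updated at 1 Hz following a slow AR(1) drift, SpO2
at 1 Hz with Gaussian noise, and a binary vibration channel with sparse
background pulses.  Each annotated episode injects, per its signature subset,
the four seizure signatures the detectors look for:

* a fall transient — linear ramp to ``peak`` over 0.2 s, a plateau at the
  peak, an instant drop to ``dip`` with a hold, then a 1 s recovery to
  gravity (plateau and hold each span half the remaining ``pattern_span``, so
  the smoothed magnitude genuinely crosses both thresholds);
* an ictal heart-rate ramp of ``hr_rise`` bpm over ``hr_ramp`` seconds,
  sustained for the episode and decaying over 20 s afterwards;
* an SpO2 descent to ``spo2_floor`` over 5 s, held, recovering over 10 s;
* a square-wave vibration train at ``jerk_freq``.

All values are quantized to 1e-6 (the CSV precision), so an in-memory
recording and its CSV round trip are bit-identical, and identical seed+spec
yield byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    EpisodeAnnotation,
    Modality,
    Recording,
    write_annotations,
    write_recording,
)

__all__ = [
    "BaselineParams",
    "FallShape",
    "EpisodeSpec",
    "SimulationSpec",
    "simulate",
    "fixture_suite",
    "make_fixture_suite",
    "FIXTURE_NAMES",
]

ALL_SIGNATURES = (Modality.FALL, Modality.TACHYCARDIA,
                  Modality.DESATURATION, Modality.JERK)

GRAVITY = 9.81
SLOW_CHANNEL_PERIOD = 1.0   # s between hr/spo2 sensor reports
FALL_RAMP = 0.2             # s, rise time of the impact transient
FALL_RECOVERY = 1.0         # s back to gravity after the dip hold
HR_RECOVERY = 20.0          # s for the ictal rise to decay after the episode
SPO2_DESCENT = 5.0          # s down to the floor
SPO2_RECOVERY = 10.0        # s back to baseline


class BaselineParams(BaseModel):
    """Inter-ictal background statistics of the simulated sensors."""

    model_config = ConfigDict(extra="forbid")

    hr_mean: float = 70.0          # bpm
    hr_sd: float = 1.5             # bpm, stationary sd of the AR(1) drift
    hr_ar1: float = 0.99           # AR(1) coefficient at 1 Hz updates
    spo2_mean: float = 97.0        # percent
    spo2_sd: float = 0.3           # percent
    accel_noise_sd: float = 0.2    # m/s² per axis
    vib_background_rate: float = 0.05  # Hz, sparse spurious pulses

    @model_validator(mode="after")
    def _check(self) -> "BaselineParams":
        if not (0 <= self.hr_ar1 < 1):
            raise ValueError("require 0 <= hr_ar1 < 1")
        for name in ("hr_sd", "spo2_sd", "accel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"require {name} >= 0")
        if self.vib_background_rate < 0:
            raise ValueError("require vib_background_rate >= 0")
        if not (20 < self.hr_mean < 250) or not (0 < self.spo2_mean <= 100):
            raise ValueError("baseline means out of physiological range")
        return self


class FallShape(BaseModel):
    """Impact transient parameters of an episode's fall signature."""

    model_config = ConfigDict(extra="forbid")

    peak: float = 30.0          # m/s²
    dip: float = 8.0            # m/s²
    pattern_span: float = 1.5   # s, ramp start to end of dip hold

    @model_validator(mode="after")
    def _check(self) -> "FallShape":
        if self.peak <= self.dip:
            raise ValueError("require peak > dip")
        if self.dip <= 0:
            raise ValueError("require dip > 0")
        if self.pattern_span <= FALL_RAMP:
            raise ValueError(f"require pattern_span > {FALL_RAMP}")
        return self


class EpisodeSpec(BaseModel):
    """One annotated seizure episode and its injected signature subset."""

    model_config = ConfigDict(extra="forbid")

    onset: float
    duration: float = 40.0
    fall: FallShape = Field(default_factory=FallShape)
    hr_rise: float = 15.0       # bpm over baseline
    hr_ramp: float = 5.0        # s to reach the full rise
    spo2_floor: float = 85.0    # percent
    jerk_freq: float = 20.0     # Hz
    signature: tuple[Modality, ...] = ALL_SIGNATURES

    @model_validator(mode="after")
    def _check(self) -> "EpisodeSpec":
        if self.duration <= 0 or self.onset < 0:
            raise ValueError("require onset >= 0 and duration > 0")
        if not (0 < self.spo2_floor <= 100):
            raise ValueError("require 0 < spo2_floor <= 100")
        if self.hr_ramp <= 0 or self.jerk_freq <= 0:
            raise ValueError("require hr_ramp > 0 and jerk_freq > 0")
        if len(self.signature) == 0:
            raise ValueError("episode needs at least one signature")
        return self

    @property
    def offset(self) -> float:
        return self.onset + self.duration


class SimulationSpec(BaseModel):
    """Full description of one synthetic recording."""

    model_config = ConfigDict(extra="forbid")

    duration: float             # s
    rate: float = 50.0          # Hz
    seed: int = 0
    baseline: BaselineParams = Field(default_factory=BaselineParams)
    episodes: list[EpisodeSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("require duration > 0 and rate > 0")
        eps = sorted(self.episodes, key=lambda e: e.onset)
        for e in eps:
            if e.offset > self.duration:
                raise ValueError("episode extends past the recording")
            if e.jerk_freq >= self.rate / 2:
                raise ValueError("jerk_freq must be below the Nyquist rate")
        for a, b in zip(eps, eps[1:]):
            if b.onset < a.offset:
                raise ValueError("episodes overlap")
        return self


def _ramp(t: np.ndarray, start: float, span: float) -> np.ndarray:
    """0→1 linear ramp beginning at ``start`` over ``span`` seconds."""
    return np.clip((t - start) / span, 0.0, 1.0)


def simulate(spec: SimulationSpec) -> tuple[Recording, list[EpisodeAnnotation]]:
    """Generate one recording and its ground-truth annotations.

    Identical ``spec`` (including its seed) always produces identical output,
    down to the CSV bytes.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.baseline
    rate = spec.rate
    n = int(round(spec.duration * rate))
    t = np.round(np.arange(n) / rate, 6)

    # --- acceleration ----------------------------------------------------
    ax = rng.normal(0.0, base.accel_noise_sd, n)
    ay = rng.normal(0.0, base.accel_noise_sd, n)
    az = GRAVITY + rng.normal(0.0, base.accel_noise_sd, n)
    for ep in spec.episodes:
        if Modality.FALL not in ep.signature:
            continue
        f = ep.fall
        hold = (f.pattern_span - FALL_RAMP) / 2.0
        t0 = ep.onset
        peak_start = t0 + FALL_RAMP
        drop = peak_start + hold
        dip_end = drop + hold
        recover_end = dip_end + FALL_RECOVERY
        seg = (t >= t0) & (t < recover_end)
        ts = t[seg]
        profile = np.where(
            ts < peak_start,
            GRAVITY + (f.peak - GRAVITY) * (ts - t0) / FALL_RAMP,
            np.where(
                ts < drop, f.peak,
                np.where(
                    ts < dip_end, f.dip,
                    f.dip + (GRAVITY - f.dip) * (ts - dip_end) / FALL_RECOVERY,
                ),
            ),
        )
        az[seg] = profile + rng.normal(0.0, base.accel_noise_sd, int(seg.sum()))

    # --- slow channels at 1 Hz reports -----------------------------------
    obs_step = max(1, int(round(SLOW_CHANNEL_PERIOD * rate)))
    obs_idx = np.arange(0, n, obs_step)
    t_obs = t[obs_idx]
    k = len(obs_idx)

    drift = np.empty(k)
    drift[0] = rng.normal(0.0, base.hr_sd)
    innov_sd = base.hr_sd * np.sqrt(1.0 - base.hr_ar1 ** 2)
    eps = rng.normal(0.0, innov_sd, k)
    for i in range(1, k):
        drift[i] = base.hr_ar1 * drift[i - 1] + eps[i]
    hr_obs = base.hr_mean + drift
    for ep in spec.episodes:
        if Modality.TACHYCARDIA not in ep.signature:
            continue
        rise = ep.hr_rise * _ramp(t_obs, ep.onset, ep.hr_ramp)
        decay = 1.0 - _ramp(t_obs, ep.offset, HR_RECOVERY)
        hr_obs = hr_obs + rise * np.where(t_obs < ep.offset, 1.0, decay)
    hr_obs = np.clip(hr_obs, 20.0, 250.0)

    spo2_obs = base.spo2_mean + rng.normal(0.0, base.spo2_sd, k)
    for ep in spec.episodes:
        if Modality.DESATURATION not in ep.signature:
            continue
        depth = base.spo2_mean - ep.spo2_floor
        down = _ramp(t_obs, ep.onset, SPO2_DESCENT)
        up = _ramp(t_obs, ep.offset, SPO2_RECOVERY)
        spo2_obs = spo2_obs - depth * np.where(t_obs < ep.offset, down, 1.0 - up)
    spo2_obs = np.clip(spo2_obs, 0.0, 100.0)

    hr_raw = np.full(n, np.nan)
    hr_raw[obs_idx] = np.round(hr_obs, 6)
    spo2_raw = np.full(n, np.nan)
    spo2_raw[obs_idx] = np.round(spo2_obs, 6)

    # --- vibration -------------------------------------------------------
    vib = (rng.random(n) < base.vib_background_rate / rate).astype(np.int64)
    for ep in spec.episodes:
        if Modality.JERK not in ep.signature:
            continue
        seg = (t >= ep.onset) & (t < ep.offset)
        ts = t[seg]
        vib[seg] = (np.floor(2.0 * ep.jerk_freq * (ts - ep.onset)) % 2 == 0).astype(np.int64)

    rec = Recording.from_channels(
        t,
        np.round(ax, 6), np.round(ay, 6), np.round(az, 6),
        hr_raw, spo2_raw, vib,
        expected_rate=rate,
    )
    annotations = [
        EpisodeAnnotation(ep.onset, ep.offset, tuple(ep.signature))
        for ep in sorted(spec.episodes, key=lambda e: e.onset)
    ]
    return rec, annotations


# ---------------------------------------------------------------------------
# fixture suite


FIXTURE_NAMES = (
    "clean",
    "fall_only",
    "tachycardia_only",
    "desaturation_only",
    "jerk_only",
    "full_signature",
    "borderline_fall",
    "borderline_tachycardia",
    "borderline_desaturation",
    "borderline_jerk",
)

# quiet bench baselines: the fixtures probe the threshold rules themselves,
# so background noise is kept well below the borderline margins (1 bpm, 1 %,
# 3.4 m/s²); the end-to-end suite uses the realistic defaults instead
_BENCH_BASELINE = dict(hr_sd=0.3, spo2_sd=0.2, accel_noise_sd=0.2,
                       vib_background_rate=0.05)

_FIXTURE_DURATION = 420.0   # leaves a full rolling-baseline warm-up
_EPISODE_ONSET = 330.0
_EPISODE_DURATION = 45.0


def _fixture_spec(name: str, seed: int) -> SimulationSpec:
    strong = dict(onset=_EPISODE_ONSET, duration=_EPISODE_DURATION,
                  fall=FallShape(peak=30.0, dip=8.0),
                  hr_rise=15.0, spo2_floor=85.0, jerk_freq=20.0)
    single = {
        "fall_only": (Modality.FALL,),
        "tachycardia_only": (Modality.TACHYCARDIA,),
        "desaturation_only": (Modality.DESATURATION,),
        "jerk_only": (Modality.JERK,),
    }
    if name == "clean":
        episodes = []
    elif name in single:
        episodes = [EpisodeSpec(signature=single[name], **strong)]
    elif name == "full_signature":
        episodes = [EpisodeSpec(signature=ALL_SIGNATURES, **strong)]
    elif name == "borderline_fall":
        episodes = [EpisodeSpec(signature=(Modality.FALL,),
                                **{**strong, "fall": FallShape(peak=20.0, dip=8.0)})]
    elif name == "borderline_tachycardia":
        episodes = [EpisodeSpec(signature=(Modality.TACHYCARDIA,),
                                **{**strong, "hr_rise": 9.0})]
    elif name == "borderline_desaturation":
        episodes = [EpisodeSpec(signature=(Modality.DESATURATION,),
                                **{**strong, "spo2_floor": 91.0})]
    elif name == "borderline_jerk":
        episodes = [EpisodeSpec(signature=(Modality.JERK,),
                                **{**strong, "jerk_freq": 10.0})]
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return SimulationSpec(
        duration=_FIXTURE_DURATION, rate=50.0, seed=seed,
        baseline=BaselineParams(**_BENCH_BASELINE), episodes=episodes,
    )


def child_seed(seed: int, index: int) -> int:
    """Derive a deterministic sub-seed (< 2**31) from a master seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))


def fixture_suite(seed: int) -> dict[str, tuple[SimulationSpec, Recording, list[EpisodeAnnotation]]]:
    """Generate the deterministic in-memory fixture suite: a clean baseline,
    one strong single-signature trace per modality, a full-signature seizure,
    and four borderline traces that must not trigger at default thresholds."""
    out = {}
    for idx, name in enumerate(FIXTURE_NAMES):
        spec = _fixture_spec(name, child_seed(seed, idx))
        rec, anns = simulate(spec)
        out[name] = (spec, rec, anns)
    return out


def end_to_end_spec(seed: int, n_episodes: int = 5,
                    episode_spacing: float = 130.0) -> SimulationSpec:
    """A realistic-noise recording with ``n_episodes`` full-signature
    seizures for end-to-end recovery benchmarks.

    The first onset sits past the rolling-baseline warm-up (330 s) and
    episodes are spaced beyond the refractory period; realistic default
    baseline noise (hr_sd 1.5 bpm etc.) is used, unlike the quiet
    threshold-fidelity bench.
    """
    episodes = [
        EpisodeSpec(onset=_EPISODE_ONSET + k * episode_spacing, duration=40.0)
        for k in range(n_episodes)
    ]
    duration = episodes[-1].offset + 70.0
    return SimulationSpec(duration=duration, rate=50.0, seed=seed,
                          episodes=episodes)


def make_fixture_suite(out_dir: Union[str, Path], seed: int) -> list[Path]:
    """Write the fixture suite as recording CSVs, annotation JSONs and spec
    JSONs under ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, (spec, rec, anns) in fixture_suite(seed).items():
        rec_path = out_dir / f"{name}.csv"
        ann_path = out_dir / f"{name}.annotations.json"
        spec_path = out_dir / f"{name}.spec.json"
        write_recording(rec, rec_path)
        write_annotations(anns, ann_path)
        spec_path.write_text(spec.model_dump_json(indent=2) + "\n")
        paths += [rec_path, ann_path, spec_path]
    return paths
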