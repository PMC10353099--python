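import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seizurekit as sk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_recording(az=None, hr=None, spo2=None, vib=None, rate=50.0,
                   n=None, ax=None, ay=None):
    """Build a small validated Recording from per-channel arrays.

    Channels default to rest values (gravity on z, hr 70 observed every
    sample, spo2 97, vib 0); hr/spo2 may contain NaN for missing cells.
    """
    for arr in (az, hr, spo2, vib, ax, ay):
        if arr is not None:
            n = len(arr)
            break
    assert n is not None
    t = np.round(np.arange(n) / rate, 6)
    az = np.full(n, 9.81) if az is None else np.asarray(az, float)
    ax = np.zeros(n) if ax is None else np.asarray(ax, float)
    ay = np.zeros(n) if ay is None else np.asarray(ay, float)
    hr = np.full(n, 70.0) if hr is None else np.asarray(hr, float)
    spo2 = np.full(n, 97.0) if spo2 is None else np.asarray(spo2, float)
    vib = np.zeros(n, dtype=int) if vib is None else np.asarray(vib, int)
    return sk.Recording.from_channels(t, ax, ay, az, hr, spo2, vib)


@pytest.fixture(scope="session")
def default_config():
    return sk.DetectorConfig()


@pytest.fixture(scope="session")
def suite():
    """The deterministic threshold-fidelity fixture suite."""
    return sk.fixture_suite(1)


def random_recording(rng: np.random.Generator, duration: float = 30.0,
                     rate: float = 50.0) -> sk.Recording:
    """A random recording whose channels wander across every threshold, for
    oracle-equivalence and streaming-equivalence tests."""
    n = int(round(duration * rate))
    t = np.round(np.arange(n) / rate, 6)

    # acceleration: piecewise levels crossing 23.4 and 10 in random patterns
    levels = np.array([9.81, 5.0, 8.0, 15.0, 26.0, 32.0])
    seg = max(2, int(0.15 * rate))
    k = n // seg + 1
    az = np.repeat(levels[rng.integers(0, len(levels), k)], seg)[:n]
    az = az + rng.normal(0, 0.3, n)

    # heart rate: 1 Hz observations random-walking around the threshold
    hr = np.full(n, np.nan)
    obs = np.arange(0, n, int(rate))
    walk = 72 + np.cumsum(rng.normal(0, 4, len(obs)))
    hr[obs] = np.clip(walk, 40, 180)

    # spo2: 1 Hz observations straddling 90 %
    spo2 = np.full(n, np.nan)
    spo2[obs] = np.clip(90.5 + rng.normal(0, 2.5, len(obs)), 60, 100)

    # vibration: alternating silence and square-wave bursts at random rates
    vib = np.zeros(n, dtype=int)
    pos = 0
    while pos < n:
        gap = int(rng.uniform(0.5, 3.0) * rate)
        pos += gap
        if pos >= n:
            break
        burst = int(rng.uniform(1.0, 5.0) * rate)
        f = rng.uniform(1.0, 24.0)
        idx = np.arange(pos, min(n, pos + burst))
        vib[idx] = (np.floor(2 * f * (t[idx] - t[pos])) % 2 == 0).astype(int)
        pos += burst
    return sk.Recording.from_channels(
        t, rng.normal(0, 0.3, n), rng.normal(0, 0.3, n), az, hr, spo2, vib)


def random_config(rng: np.random.Generator) -> sk.DetectorConfig:
    """A randomized, short-window configuration suitable for short recordings."""
    mode = rng.choice(["fixed", "rolling"])
    return sk.DetectorConfig(
        smooth_window=float(rng.choice([0.02, 0.1, 0.3])),
        fall_pattern_window=float(rng.uniform(0.5, 2.0)),
        baseline_mode=str(mode),
        baseline_fixed=72.0 if mode == "fixed" else None,
        baseline_window=8.0,
        baseline_gap=1.0,
        baseline_update=0.5,
        min_tachycardia_duration=float(rng.uniform(0.0, 1.0)),
        min_desaturation_duration=float(rng.uniform(0.0, 1.0)),
        min_jerk_duration=float(rng.uniform(0.0, 1.0)),
        hr_delta=float(rng.uniform(5.0, 12.0)),
        vib_window=float(rng.choice([1.0, 2.0])),
        staleness_limit=float(rng.choice([1.5, 10.0])),
        band_semantics=str(rng.choice(["outside", "inside"])),
    )
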