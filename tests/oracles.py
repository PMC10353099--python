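"""Independent brute-force oracles for the detectors.

Each oracle recomputes the per-sample predicate and the interval merging with
plain Python loops (or exhaustive scans), independently of the vectorized
implementations, and returns the same flag structures for exact comparison.
"""

import math
import statistics

from seizurekit import DetectorConfig, Modality, ModalityFlag, Recording


def oracle_fall(smoothed_m, t, cfg: DetectorConfig):
    """Exhaustive scan over all (high-crossing, first-low) pairs + merging."""
    m = list(smoothed_m)
    n = len(m)
    candidates = []
    for i in range(n):
        if not (m[i] > cfg.a_high and (i == 0 or m[i - 1] <= cfg.a_high)):
            continue
        for j in range(i + 1, n):
            if m[j] < cfg.a_low:
                if t[j] - t[i] <= cfg.fall_pattern_window:
                    candidates.append((i, j))
                break
    merged = []
    for i, j in candidates:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    flags = []
    for i, j in merged:
        if t[j] - t[i] < cfg.min_fall_duration:
            continue
        flags.append(ModalityFlag(Modality.FALL, float(t[i]), float(t[j]),
                                  float(max(m[i:j + 1]))))
    return flags


def oracle_baseline(rec: Recording, cfg: DetectorConfig):
    """Per-sample rolling-median baseline recomputed sample by sample."""
    n = len(rec)
    if cfg.baseline_mode == "fixed":
        return [float(cfg.baseline_fixed)] * n
    out = [math.nan] * n
    win_lo = int(round(cfg.baseline_window * rec.rate))
    win_hi = int(round(cfg.baseline_gap * rec.rate))
    step = max(1, int(round(cfg.baseline_update * rec.rate)))
    current = math.nan
    for i in range(n):
        if i % step == 0 and i - win_lo >= 0:
            window = [rec.hr[j] for j in range(i - win_lo, i - win_hi + 1)
                      if not math.isnan(rec.hr[j])]
            current = statistics.median(window) if window else math.nan
        out[i] = current
    return out


def _runs_to_flags(indicator, t, rate, min_dur, modality, evidence_of):
    n = len(indicator)
    flags = []
    i = 0
    while i < n:
        if not indicator[i]:
            i += 1
            continue
        j = i
        while j < n and indicator[j]:
            j += 1
        onset = float(t[i])
        offset = float(t[j]) if j < n else float(t[n - 1] + 1.0 / rate)
        if offset - onset >= min_dur:
            flags.append(ModalityFlag(modality, onset, offset,
                                      float(evidence_of(i, j))))
        i = j
    return flags


def oracle_tachycardia(rec: Recording, cfg: DetectorConfig):
    baseline = oracle_baseline(rec, cfg)
    excess = [rec.hr[i] - baseline[i] for i in range(len(rec))]
    indicator = [
        rec.hr_age[i] <= cfg.staleness_limit
        and not math.isnan(excess[i]) and excess[i] >= cfg.hr_delta
        for i in range(len(rec))
    ]
    return _runs_to_flags(indicator, rec.t, rec.rate,
                          cfg.min_tachycardia_duration, Modality.TACHYCARDIA,
                          lambda i, j: max(excess[i:j]))


def oracle_desaturation(rec: Recording, cfg: DetectorConfig):
    indicator = [
        rec.spo2_age[i] <= cfg.staleness_limit
        and not math.isnan(rec.spo2[i]) and rec.spo2[i] < cfg.spo2_min
        for i in range(len(rec))
    ]
    return _runs_to_flags(indicator, rec.t, rec.rate,
                          cfg.min_desaturation_duration, Modality.DESATURATION,
                          lambda i, j: min(rec.spo2[i:j]))


def oracle_jerk(rec: Recording, cfg: DetectorConfig):
    n = len(rec)
    win_n = int(round(cfg.vib_window * rec.rate))
    freq = [math.nan] * n
    for i in range(win_n, n):
        count = sum(
            1 for j in range(i - win_n + 1, i + 1)
            if j >= 1 and rec.vib[j] == 1 and rec.vib[j - 1] == 0
        )
        if count >= cfg.vib_min_edges:
            freq[i] = count / cfg.vib_window
    if cfg.band_semantics == "outside":
        indicator = [not math.isnan(f) and (f < cfg.f_low or f > cfg.f_high)
                     for f in freq]
    else:
        indicator = [not math.isnan(f) and cfg.f_low <= f <= cfg.f_high
                     for f in freq]
    centre = 0.5 * (cfg.f_low + cfg.f_high)

    def evidence(i, j):
        vals = freq[i:j]
        if cfg.band_semantics == "outside":
            return max(vals, key=lambda v: abs(v - centre))
        return max(vals)

    return _runs_to_flags(indicator, rec.t, rec.rate, cfg.min_jerk_duration,
                          Modality.JERK, evidence)


def oracle_match(detections, annotations, pre_tol, post_tol):
    """Exhaustive pairwise containment check; returns (matched episode set,
    false-positive detection indices)."""
    matched = set()
    false_pos = []
    for i, d in enumerate(sorted(detections, key=lambda d: d.time)):
        containing = [
            j for j, a in enumerate(sorted(annotations, key=lambda a: a.onset))
            if a.onset - pre_tol <= d.time <= a.offset + post_tol
        ]
        if containing:
            matched.add(min(containing))
        else:
            false_pos.append(i)
    return matched, false_pos
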