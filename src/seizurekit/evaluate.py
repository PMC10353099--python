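"""Event-based scoring of alarms against ground-truth episodes.

Detections and annotations are matched by containment with tolerances: a
DANGER alarm at time ``t`` matches an episode if ``t`` lies within
``[onset - pre_tol, offset + post_tol]``.  Matching is greedy
earliest-first — one episode may absorb several alarms, but it counts as
detected once, and each alarm matches at most the earliest episode containing
it.  The report gives episode sensitivity, the event-level false discovery
rate, false alarms per hour and the mean detection latency (first matching
alarm minus episode onset).  Ratios with an empty denominator are reported as
an explicit ``None``/"undefined", never as a silent zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import AlarmEvent, AlarmState, EpisodeAnnotation, Modality, ModalityFlag

__all__ = ["Matching", "EvaluationReport", "match_events", "score", "format_report"]


@dataclass(frozen=True)
class Matching:
    """Outcome of event/episode matching.

    ``assignment[i]`` is the index of the episode matched by detection ``i``
    (None for a false positive); ``first_detection[j]`` is the index of the
    first detection matching episode ``j`` (None for a missed episode).
    """

    assignment: tuple[Optional[int], ...]
    first_detection: tuple[Optional[int], ...]

    @property
    def n_matched_episodes(self) -> int:
        return sum(1 for d in self.first_detection if d is not None)

    @property
    def unmatched_detections(self) -> int:
        return sum(1 for a in self.assignment if a is None)


def match_events(detections: Sequence[AlarmEvent],
                 annotations: Sequence[EpisodeAnnotation],
                 pre_tol: float = 5.0, post_tol: float = 30.0) -> Matching:
    """Match DANGER alarms to annotated episodes by tolerant containment."""
    if pre_tol < 0 or post_tol < 0:
        raise ValueError("tolerances must be >= 0")
    dets = sorted((d for d in detections if d.state is AlarmState.DANGER),
                  key=lambda d: d.time)
    anns = sorted(annotations, key=lambda a: a.onset)
    assignment: list[Optional[int]] = []
    first: list[Optional[int]] = [None] * len(anns)
    for i, det in enumerate(dets):
        hit = None
        for j, ann in enumerate(anns):
            if ann.onset - pre_tol <= det.time <= ann.offset + post_tol:
                hit = j
                break
        assignment.append(hit)
        if hit is not None and first[hit] is None:
            first[hit] = i
    return Matching(tuple(assignment), tuple(first))


@dataclass(frozen=True)
class EvaluationReport:
    """Event-based performance summary; None marks an undefined ratio."""

    n_episodes: int
    n_detections: int
    n_matched: int
    sensitivity: Optional[float]
    fdr: Optional[float]
    false_alarms_per_hour: float
    mean_latency_s: Optional[float]
    latencies_s: tuple[float, ...] = ()
    flag_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "n_detections": self.n_detections,
            "n_matched": self.n_matched,
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "false_alarms_per_hour": self.false_alarms_per_hour,
            "mean_latency_s": self.mean_latency_s,
            "latencies_s": list(self.latencies_s),
            "flag_counts": dict(self.flag_counts),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def score(detections: Sequence[AlarmEvent],
          annotations: Sequence[EpisodeAnnotation],
          recording_duration: float,
          pre_tol: float = 5.0, post_tol: float = 30.0,
          flags: Sequence[ModalityFlag] = ()) -> EvaluationReport:
    """Score a detection run against its annotations."""
    if recording_duration <= 0:
        raise ValueError("recording_duration must be > 0")
    dets = sorted((d for d in detections if d.state is AlarmState.DANGER),
                  key=lambda d: d.time)
    anns = sorted(annotations, key=lambda a: a.onset)
    matching = match_events(dets, anns, pre_tol, post_tol)
    n_eps, n_dets = len(anns), len(dets)
    n_matched = matching.n_matched_episodes
    unmatched = matching.unmatched_detections
    latencies = tuple(
        dets[d].time - anns[j].onset
        for j, d in enumerate(matching.first_detection) if d is not None
    )
    counts = {m.value: 0 for m in Modality}
    for fl in flags:
        counts[fl.modality.value] += 1
    return EvaluationReport(
        n_episodes=n_eps,
        n_detections=n_dets,
        n_matched=n_matched,
        sensitivity=(n_matched / n_eps) if n_eps else None,
        fdr=(unmatched / n_dets) if n_dets else None,
        false_alarms_per_hour=unmatched / (recording_duration / 3600.0),
        mean_latency_s=(sum(latencies) / len(latencies)) if latencies else None,
        latencies_s=latencies,
        flag_counts=counts,
    )


def format_report(report: EvaluationReport) -> str:
    """Human-readable table of the report."""

    def fmt(v, unit=""):
        return "undefined" if v is None else f"{v:.3f}{unit}"

    lines = [
        "metric                     value",
        "-------------------------  ---------",
        f"episodes                   {report.n_episodes}",
        f"detections                 {report.n_detections}",
        f"matched episodes           {report.n_matched}",
        f"sensitivity                {fmt(report.sensitivity)}",
        f"false discovery rate       {fmt(report.fdr)}",
        f"false alarms per hour      {report.false_alarms_per_hour:.3f}",
        f"mean detection latency     {fmt(report.mean_latency_s, ' s')}",
    ]
    if report.flag_counts:
        lines.append("flags per modality         "
                     + ", ".join(f"{k}={v}" for k, v in sorted(report.flag_counts.items())))
    return "\n".join(lines)
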