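"""Usability-testing session layer: CPT first-impression timing, session
segmentation, and linking emotion labels to usability factors.

The continuous performance test (CPT) measures the subject's mean reaction
time — pressing space for every character except 'X' — and that mean
defines the *first impression* window length used when segmenting a
session.  Two segmentation modes exist:

* ``discrete``: every task window opens with its own first-impression
  segment followed by the task remainder;
* ``continuous``: a single first-impression segment at the start of the
  first task, all other tasks kept whole.

The linking stage turns per-segment VAD decisions into a usability report:
the first-impression label, a per-task dominant label (modal outcome per
dimension, ties resolved toward neutral), overall outcome proportions, and
a satisfaction indicator (fraction of non-error segments with upper
valence).  Dominance is reported but deliberately not mapped to any
usability factor.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import VADDecision
from .exceptions import PreconditionError, RangeError, SchemaError
from .io import DIMENSIONS, EventLog, Recording

__all__ = [
    "SessionPlan",
    "Segment",
    "UsabilityReport",
    "cpt_response_time",
    "segment_session",
    "link_report",
]


@dataclass
class SessionPlan:
    mode: str  # discrete | continuous
    tasks: list[tuple[str, float, float]]  # (task_id, start_s, end_s)
    first_impression_s: float

    def __post_init__(self):
        if self.mode not in ("discrete", "continuous"):
            raise SchemaError("mode must be 'discrete' or 'continuous'")
        if self.first_impression_s <= 0:
            raise RangeError("first-impression duration must be positive")
        prev_end = -np.inf
        for task_id, start, end in self.tasks:
            if end <= start:
                raise SchemaError(f"task {task_id} window is empty")
            if start < prev_end:
                raise SchemaError("task windows must be ordered and non-overlapping")
            prev_end = end

    @classmethod
    def from_event_log(
        cls, mode: str, log: EventLog, first_impression_s: float | None = None
    ) -> "SessionPlan":
        """Build a plan from task_start/task_end markers; the first-impression
        length defaults to the CPT mean response time in the same log."""
        starts = log.of_kind("task_start")
        ends = log.of_kind("task_end")
        if len(starts) != len(ends):
            raise SchemaError("unbalanced task_start/task_end events")
        tasks = [
            (s.payload, s.timestamp_s, e.timestamp_s) for s, e in zip(starts, ends)
        ]
        if first_impression_s is None:
            first_impression_s = cpt_response_time(log)
        return cls(mode=mode, tasks=tasks, first_impression_s=first_impression_s)


@dataclass
class Segment:
    start_s: float
    end_s: float
    role: str  # first_impression | task
    task_id: str | None = None
    data: np.ndarray | None = None  # (n_channels, n_samples) slice


def cpt_response_time(log: EventLog) -> float:
    """Mean CPT response time in seconds — the first-impression duration.

    For every non-X stimulus, the response is the first keypress after the
    stimulus and before the next stimulus; stimuli with no such press are
    omissions and excluded, and presses following an 'X' (commission
    errors) never enter the mean.
    """
    stimuli = log.of_kind("cpt_stimulus")
    presses = [e.timestamp_s for e in log.of_kind("cpt_keypress")]
    if not stimuli:
        raise PreconditionError("no CPT stimuli in log")
    times = []
    for i, stim in enumerate(stimuli):
        if stim.payload == "X":
            continue
        t_next = stimuli[i + 1].timestamp_s if i + 1 < len(stimuli) else np.inf
        candidates = [t for t in presses if stim.timestamp_s < t < t_next]
        if candidates:
            times.append(candidates[0] - stim.timestamp_s)
    if not times:
        raise PreconditionError("no valid CPT responses")
    return float(np.mean(times))


def segment_session(rec: Recording, plan: SessionPlan) -> list[Segment]:
    """Partition a session recording into first-impression and task segments.

    Discrete mode splits every task into a leading first-impression window
    plus remainder; continuous mode places one first-impression window at
    the start of the first task only.  Segments carry signal slices cut
    half-open in seconds.
    """
    if not plan.tasks:
        raise SchemaError("plan has no tasks")
    fi = plan.first_impression_s
    segs: list[Segment] = []

    def cut(start: float, end: float, role: str, task_id=None):
        i0, i1 = int(round(start * rec.fs)), int(round(end * rec.fs))
        if i0 < 0 or i1 > rec.n_samples:
            raise RangeError(f"window [{start}, {end}) s outside recording")
        segs.append(Segment(start, end, role, task_id, rec.data[:, i0:i1]))

    for k, (task_id, start, end) in enumerate(plan.tasks):
        dur = end - start
        if plan.mode == "discrete":
            if fi >= dur:
                raise RangeError(
                    f"first impression {fi} s >= task {task_id} duration {dur} s"
                )
            cut(start, start + fi, "first_impression", task_id)
            cut(start + fi, end, "task", task_id)
        else:  # continuous: first impression only at session start
            if k == 0:
                if fi >= dur:
                    raise RangeError(
                        f"first impression {fi} s >= first task duration {dur} s"
                    )
                cut(start, start + fi, "first_impression", task_id)
                cut(start + fi, end, "task", task_id)
            else:
                cut(start, end, "task", task_id)
    return segs


def _modal_outcome(outcomes: Sequence[str]) -> str:
    """Majority outcome; ties resolve toward neutral."""
    counts = Counter(outcomes)
    top = max(counts.values())
    winners = {o for o, c in counts.items() if c == top}
    if len(winners) > 1:
        return "neutral"
    return winners.pop()


@dataclass
class UsabilityReport:
    first_impression: VADDecision | None
    per_task: dict[str, dict]  # task_id -> {dominant: {dim: outcome}, proportions: {dim: {outcome: frac}}}
    overall: dict[str, float]  # pleasant / unpleasant / neutral / error fractions (valence-based)
    satisfaction_indicator: float | None
    dominance_note: str = (
        "dominance outcomes are reported but not mapped to a usability factor"
    )

    def to_json(self, path=None) -> str:
        def dec(d: VADDecision | None):
            if d is None:
                return None
            return {dim: d.outcome(dim) for dim in DIMENSIONS}

        obj = {
            "first_impression": dec(self.first_impression),
            "per_task": self.per_task,
            "overall": self.overall,
            "satisfaction_indicator": self.satisfaction_indicator,
            "dominance_note": self.dominance_note,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        lines = ["# Usability report", ""]
        if self.first_impression is not None:
            fi = {d: self.first_impression.outcome(d) for d in DIMENSIONS}
            lines.append(f"First impression: {fi}")
        lines.append("")
        lines.append("| task | valence | arousal | dominance |")
        lines.append("|------|---------|---------|-----------|")
        for task_id, entry in self.per_task.items():
            dom = entry["dominant"]
            lines.append(
                f"| {task_id} | {dom['valence']} | {dom['arousal']} | {dom['dominance']} |"
            )
        lines.append("")
        lines.append(f"Overall valence proportions: {self.overall}")
        sat = (
            "undetermined" if self.satisfaction_indicator is None
            else f"{self.satisfaction_indicator:.2f}"
        )
        lines.append(f"Satisfaction indicator (pleasant fraction): {sat}")
        lines.append(f"Note: {self.dominance_note}")
        return "\n".join(lines)


def link_report(
    labelled_segments: Sequence[tuple[Segment, VADDecision]],
    plan: SessionPlan,
) -> UsabilityReport:
    """Tie per-segment emotion decisions to the usability factors.

    * first-impression factor: label of the (first) first-impression segment;
    * task-based factor: per-task modal outcome per dimension over the
      task's segments;
    * overall factor: valence outcome proportions over all segments;
    * satisfaction indicator: fraction of non-error segments with upper
      valence (None, with a warning, if every segment is an error).
    """
    if not labelled_segments:
        raise SchemaError("no labelled segments")
    for seg, dec in labelled_segments:
        if dec is None:
            raise SchemaError(f"segment [{seg.start_s}, {seg.end_s}) unlabelled")

    fi_dec = next(
        (dec for seg, dec in labelled_segments if seg.role == "first_impression"), None
    )

    per_task: dict[str, dict] = {}
    for task_id, _, _ in plan.tasks:
        task_pairs = [
            (seg, dec) for seg, dec in labelled_segments
            if seg.task_id == task_id and seg.role == "task"
        ]
        if not task_pairs:
            continue
        dominant = {}
        proportions = {}
        for dim in DIMENSIONS:
            outs = [dec.outcome(dim) for _, dec in task_pairs]
            dominant[dim] = _modal_outcome(outs)
            counts = Counter(outs)
            proportions[dim] = {o: counts[o] / len(outs) for o in counts}
        per_task[task_id] = {"dominant": dominant, "proportions": proportions}

    val_outcomes = [dec.outcome("valence") for _, dec in labelled_segments]
    n = len(val_outcomes)
    counts = Counter(val_outcomes)
    overall = {
        "pleasant": counts["upper"] / n,
        "unpleasant": counts["lower"] / n,
        "neutral": counts["neutral"] / n,
        "error": counts["error"] / n,
    }
    non_error = [o for o in val_outcomes if o != "error"]
    if non_error:
        satisfaction = sum(o == "upper" for o in non_error) / len(non_error)
    else:
        warnings.warn("all segments classified as error; satisfaction undetermined")
        satisfaction = None
    return UsabilityReport(
        first_impression=fi_dec,
        per_task=per_task,
        overall=overall,
        satisfaction_indicator=satisfaction,
    )
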