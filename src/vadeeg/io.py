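"""Recordings, event logs and labelled trial sets.

The in-memory containers used throughout the pipeline live here:

* :class:`Recording` — a channels x samples matrix in microvolts with its
  sampling rate and 10-20 channel labels,
* :class:`EventLog` — timestamped session events (trial boundaries, CPT
  stimuli/keypresses, task markers),
* :class:`EmotionalState` — a valence/arousal/dominance level triple,
* :class:`TrialSet` — windowed signal segments with state labels.

Two on-disk dialects are supported: EDF (European Data Format) and a plain
"matrix + sidecar" dialect (delimited numeric matrix next to a JSON file
declaring ``fs``, ``channel_labels`` and ``subject_id``).  Event logs are CSV
with columns ``timestamp_s, kind, payload``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import FormatError, RangeError, SchemaError

__all__ = [
    "DIMENSIONS",
    "LEVELS",
    "EmotionalState",
    "NEUTRAL_STATE",
    "corner_states",
    "Recording",
    "Event",
    "EventLog",
    "Trial",
    "TrialSet",
    "read_recording",
    "write_recording",
    "read_event_log",
    "write_event_log",
    "extract_trials",
    "ratings_to_state",
]

DIMENSIONS = ("valence", "arousal", "dominance")
LEVELS = ("upper", "lower", "neutral")


@dataclass(frozen=True)
class EmotionalState:
    """A point of the valence-arousal-dominance (VAD) model.

    Each dimension sits at one of three levels: ``upper`` (positive valence /
    active arousal / upper dominance rating), ``lower``, or ``neutral``.  The
    eight all-non-neutral corner combinations are the eight emotional states
    the classifier distinguishes; the all-neutral triple is the reference
    (baseline) state.
    """

    valence: str = "neutral"
    arousal: str = "neutral"
    dominance: str = "neutral"

    def __post_init__(self):
        for dim in DIMENSIONS:
            if getattr(self, dim) not in LEVELS:
                raise SchemaError(
                    f"{dim} level must be one of {LEVELS}, got {getattr(self, dim)!r}"
                )

    def level(self, dimension: str) -> str:
        if dimension not in DIMENSIONS:
            raise SchemaError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)

    @property
    def is_neutral(self) -> bool:
        return all(getattr(self, d) == "neutral" for d in DIMENSIONS)

    def __str__(self) -> str:
        return f"V={self.valence}/A={self.arousal}/D={self.dominance}"


NEUTRAL_STATE = EmotionalState()


def corner_states() -> list[EmotionalState]:
    """The eight non-neutral corner states of the VAD cube."""
    out = []
    for v in ("upper", "lower"):
        for a in ("upper", "lower"):
            for d in ("upper", "lower"):
                out.append(EmotionalState(v, a, d))
    return out


def ratings_to_state(
    valence: float,
    arousal: float,
    dominance: float,
    *,
    upper_above: float = 6.0,
    lower_below: float = 4.0,
) -> EmotionalState:
    """Map 1-9 self-assessment ratings to VAD levels.

    Ratings strictly above ``upper_above`` map to ``upper``, strictly below
    ``lower_below`` to ``lower``, anything in between to ``neutral``.  The
    thresholds are configurable; the defaults leave a genuine neutral band
    that serves as the ERD/ERS reference class.
    """
    def one(r: float) -> str:
        if r > upper_above:
            return "upper"
        if r < lower_below:
            return "lower"
        return "neutral"

    return EmotionalState(one(valence), one(arousal), one(dominance))


@dataclass
class Recording:
    """Multichannel EEG signal in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: Sequence[str]
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.data.ndim != 2:
            raise SchemaError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise SchemaError("a recording needs at least 2 channels")
        if self.data.shape[1] < 1:
            raise SchemaError("a recording needs at least 1 sample")
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise SchemaError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("recording contains NaN or infinite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass(frozen=True)
class Event:
    timestamp_s: float
    kind: str  # trial_onset | trial_offset | cpt_stimulus | cpt_keypress | task_start | task_end
    payload: str = ""


@dataclass
class EventLog:
    """Ordered session events; timestamps must be non-decreasing."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        ts = [e.timestamp_s for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SchemaError("event timestamps must be non-decreasing")

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def trial_windows(self) -> list[tuple[float, float]]:
        """Pair trial_onset/trial_offset events into [onset, offset) windows."""
        onsets = self.of_kind("trial_onset")
        offsets = self.of_kind("trial_offset")
        if len(onsets) != len(offsets):
            raise SchemaError("every trial_onset needs a matching trial_offset")
        windows = []
        for on, off in zip(onsets, offsets):
            if off.timestamp_s <= on.timestamp_s:
                raise SchemaError("trial_offset must come after its trial_onset")
            windows.append((on.timestamp_s, off.timestamp_s))
        return windows


@dataclass
class Trial:
    """One signal segment with its state label."""

    data: np.ndarray  # (n_channels, n_samples)
    state: EmotionalState
    is_reference: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)


@dataclass
class TrialSet:
    """Trials (or fragments) sharing channel layout and sampling rate."""

    trials: list[Trial]
    fs: float
    channel_labels: Sequence[str]

    def __post_init__(self):
        self.channel_labels = list(self.channel_labels)
        n_ch = len(self.channel_labels)
        for t in self.trials:
            if t.data.shape[0] != n_ch:
                raise SchemaError("all trials must share the channel count")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def reference_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.is_reference]

    def by_state(self) -> dict[EmotionalState, list[Trial]]:
        out: dict[EmotionalState, list[Trial]] = {}
        for t in self.trials:
            out.setdefault(t.state, []).append(t)
        return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_recording(path, format: str = "auto") -> Recording:
    """Read a recording from EDF or the matrix+sidecar dialect.

    ``format='auto'`` picks EDF for a ``.edf`` suffix, matrix otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        from . import edf

        return edf.read_edf(path)
    if format == "matrix":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise SchemaError(f"sidecar {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        for key in ("fs", "channel_labels"):
            if key not in meta:
                raise SchemaError(f"sidecar missing {key!r}")
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        return Recording(
            data=data,
            fs=float(meta["fs"]),
            channel_labels=meta["channel_labels"],
            subject_id=str(meta.get("subject_id", "")),
        )
    raise FormatError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        from . import edf

        edf.write_edf(rec, path)
    elif format == "matrix":
        np.savetxt(path, rec.data, delimiter=",")
        meta = {
            "fs": rec.fs,
            "channel_labels": list(rec.channel_labels),
            "subject_id": rec.subject_id,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise FormatError(f"unknown recording format {format!r}")


def read_event_log(path) -> EventLog:
    events = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            events.append(
                Event(float(row["timestamp_s"]), row["kind"], row.get("payload", "") or "")
            )
    return EventLog(events)


def write_event_log(log: EventLog, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp_s", "kind", "payload"])
        for e in log.events:
            writer.writerow([repr(e.timestamp_s), e.kind, e.payload])


def extract_trials(
    rec: Recording,
    log: EventLog,
    labels: Mapping[int, EmotionalState],
) -> TrialSet:
    """Cut labelled trials out of a continuous recording.

    Trial windows come from paired ``trial_onset``/``trial_offset`` events and
    are cut half-open ``[onset, offset)`` in seconds.  ``labels`` maps the
    trial index (0-based, in onset order) to its state; trials labelled
    all-neutral are flagged as reference trials.
    """
    windows = log.trial_windows()
    trials = []
    for i, (t0, t1) in enumerate(windows):
        i0 = int(round(t0 * rec.fs))
        i1 = int(round(t1 * rec.fs))
        if i0 < 0 or i1 > rec.n_samples:
            raise RangeError(
                f"trial {i} window [{t0}, {t1}) s exceeds recording bounds"
            )
        if i not in labels:
            raise SchemaError(f"no label for trial {i}")
        state = labels[i]
        trials.append(
            Trial(rec.data[:, i0:i1].copy(), state, is_reference=state.is_neutral)
        )
    return TrialSet(trials, rec.fs, rec.channel_labels)
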