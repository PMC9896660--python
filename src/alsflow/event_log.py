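"""Event-log data model for disease-trajectory process mining.

A trace is one patient's timestamped sequence of activities, annotated
with static attributes (onset site, age at onset, sex, ...).  Timestamps
are real-valued days since the patient's disease onset, so the ``Onset``
activity, when present, sits at day 0.  The activity vocabulary is fixed:

* ``Onset`` — disease onset;
* ``TrialStart`` — enrollment into a trial (absent for registry data);
* ``M_abcd`` — functional-impairment state, one binary digit per
  MiToS domain in the order Walking/Self-care, Swallowing,
  Communicating, Breathing (16 states, ``M_0000`` .. ``M_1111``);
* ``Dead`` / ``Censored`` — terminal survival events.
"""

from __future__ import annotations

import math
import re
from collections.abc import Callable, Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, VocabularyError

ONSET = "Onset"
TRIAL_START = "TrialStart"
DEAD = "Dead"
CENSORED = "Censored"
TERMINAL = frozenset({DEAD, CENSORED})

_STATE_RE = re.compile(r"^M_[01]{4}$")


def state_activities() -> list[str]:
    """All 16 ``M_abcd`` activity labels in lexicographic order."""
    return [f"M_{i:04b}" for i in range(16)]


def is_state_activity(activity: str) -> bool:
    return bool(_STATE_RE.match(activity))


def is_known_activity(activity: str) -> bool:
    return (
        activity in (ONSET, TRIAL_START, DEAD, CENSORED)
        or is_state_activity(activity)
    )


def activity_priority(activity: str) -> int:
    """Tie-break order for simultaneous events: Onset < TrialStart < M_abcd < terminal."""
    if activity == ONSET:
        return 0
    if activity == TRIAL_START:
        return 1
    if activity in TERMINAL:
        return 3
    return 2


@dataclass(frozen=True)
class Event:
    """One activity occurrence at a time expressed in days from onset."""

    activity: str
    timestamp: float


@dataclass
class Trace:
    """Ordered event sequence of a single patient plus static attributes."""

    patient_id: str
    events: list[Event]
    attributes: dict[str, object] = field(default_factory=dict)

    def sort_events(self) -> None:
        """Sort ascending by timestamp; ties broken by the fixed activity priority."""
        self.events.sort(key=lambda e: (e.timestamp, activity_priority(e.activity)))

    def activities(self) -> list[str]:
        return [e.activity for e in self.events]

    def terminal(self) -> Event | None:
        if self.events and self.events[-1].activity in TERMINAL:
            return self.events[-1]
        return None


@dataclass
class EventLog:
    """Collection of traces keyed by patient id."""

    traces: dict[str, Trace]
    metadata: dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_traces(cls, traces: Iterable[Trace], **metadata: object) -> "EventLog":
        out: dict[str, Trace] = {}
        for tr in traces:
            if tr.patient_id in out:
                raise ValueError(f"duplicate patient_id {tr.patient_id!r}")
            if not tr.events:
                raise ValueError(f"empty trace for patient {tr.patient_id!r}")
            tr.sort_events()
            out[tr.patient_id] = tr
        return cls(traces=out, metadata=dict(metadata))

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces.values())

    def __getitem__(self, patient_id: str) -> Trace:
        return self.traces[patient_id]

    def activities(self) -> set[str]:
        return {a for tr in self for a in tr.activities()}


# ---------------------------------------------------------------------------
# Validation

ISSUE_NEGATIVE_TIMESTAMP = "negative_timestamp"
ISSUE_UNKNOWN_ACTIVITY = "unknown_activity"
ISSUE_MULTIPLE_TERMINAL = "multiple_terminal"
ISSUE_EVENT_AFTER_TERMINAL = "event_after_terminal"
ISSUE_ONSET_NOT_FIRST = "onset_not_first"
ISSUE_SIMULTANEOUS_STATES = "simultaneous_states"
ISSUE_EMPTY_TRACE = "empty_trace"


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    patient_id: str
    detail: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for issue in self.issues:
            out[issue.code] = out.get(issue.code, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.issues)


def validate_event_log(log: EventLog) -> ValidationReport:
    """Report every invariant violation in *log* without modifying it.

    Checked per trace: non-negative timestamps, known activity names, at
    most one terminal (Dead/Censored) event placed last, Onset (if
    present) first at day 0, and no two impairment states sharing a
    timestamp.
    """
    issues: list[ValidationIssue] = []

    def add(code: str, pid: str, detail: str) -> None:
        issues.append(ValidationIssue(code, pid, detail))

    for tr in log:
        pid = tr.patient_id
        if not tr.events:
            add(ISSUE_EMPTY_TRACE, pid, "trace has no events")
            continue
        terminal_seen = False
        for i, ev in enumerate(tr.events):
            if ev.timestamp < 0:
                add(ISSUE_NEGATIVE_TIMESTAMP, pid, f"{ev.activity} at {ev.timestamp}")
            if not is_known_activity(ev.activity):
                add(ISSUE_UNKNOWN_ACTIVITY, pid, repr(ev.activity))
            if ev.activity in TERMINAL:
                if terminal_seen:
                    add(ISSUE_MULTIPLE_TERMINAL, pid, f"{ev.activity} at {ev.timestamp}")
                terminal_seen = True
            elif terminal_seen:
                add(ISSUE_EVENT_AFTER_TERMINAL, pid, f"{ev.activity} at {ev.timestamp}")
            if ev.activity == ONSET and (i != 0 or ev.timestamp != 0):
                add(ISSUE_ONSET_NOT_FIRST, pid, f"Onset at position {i}, day {ev.timestamp}")
        states = [e for e in tr.events if is_state_activity(e.activity)]
        stamps = [e.timestamp for e in states]
        dupes = {t for t in stamps if stamps.count(t) > 1}
        for t in sorted(dupes):
            add(ISSUE_SIMULTANEOUS_STATES, pid, f"two M states at day {t}")
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED_COLUMNS = ("patient_id", "activity", "timestamp")


def read_event_log(
    path,
    attributes_path=None,
    dialect: Mapping[str, str] | None = None,
) -> EventLog:
    """Read an event log from a CSV file (plus optional attribute CSV).

    The event file needs columns ``patient_id``, ``activity`` and
    ``timestamp`` (days from onset); *dialect* remaps canonical names to
    the file's actual headers, e.g. ``{"patient_id": "subject"}``.  The
    attribute file carries one row per patient with one column per
    static attribute.  Events are sorted on read, so repeated reads of
    the same file yield identical traces.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path)
    colmap = {canon: dialect.get(canon, canon) for canon in _REQUIRED_COLUMNS}
    missing = [col for col in colmap.values() if col not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    frame = frame.rename(columns={v: k for k, v in colmap.items()})

    stamps = pd.to_numeric(frame["timestamp"], errors="coerce")
    bad = stamps.isna() & frame["timestamp"].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(
            f"non-numeric timestamp {frame['timestamp'][row]!r} at row {row}"
        )
    if stamps.isna().any():
        row = int(stamps.isna().idxmax())
        raise FormatError(f"missing timestamp at row {row}")

    for row, act in frame["activity"].items():
        if not is_known_activity(str(act)):
            raise VocabularyError(f"unknown activity {act!r} at row {row}")

    attributes: dict[str, dict[str, object]] = {}
    if attributes_path is not None:
        attr_frame = pd.read_csv(attributes_path)
        key = dialect.get("patient_id", "patient_id")
        if key not in attr_frame.columns:
            raise FormatError(f"missing required column(s) ['{key}'] in {attributes_path}")
        attr_frame = attr_frame.rename(columns={key: "patient_id"})
        for _, row_values in attr_frame.iterrows():
            pid = str(row_values["patient_id"])
            attributes[pid] = {
                name: value
                for name, value in row_values.items()
                if name != "patient_id" and not _is_missing(value)
            }

    traces = []
    for pid, group in frame.groupby("patient_id", sort=True):
        pid = str(pid)
        events = [
            Event(str(act), float(ts))
            for act, ts in zip(group["activity"], stamps[group.index])
        ]
        traces.append(Trace(pid, events, attributes.get(pid, {})))
    return EventLog.from_traces(traces, source=str(path))


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def write_event_log(log: EventLog, path, attributes_path=None) -> None:
    """Write *log* as CSV; attributes go to *attributes_path* when any exist.

    ``read_event_log(write_event_log(log))`` round-trips traces,
    timestamps and attributes exactly (up to column order).
    """
    rows = [
        {"patient_id": tr.patient_id, "activity": ev.activity, "timestamp": ev.timestamp}
        for tr in sorted(log, key=lambda t: t.patient_id)
        for ev in tr.events
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)

    if attributes_path is not None and any(tr.attributes for tr in log):
        attr_names = sorted({k for tr in log for k in tr.attributes})
        attr_rows = [
            {"patient_id": tr.patient_id, **{k: tr.attributes.get(k) for k in attr_names}}
            for tr in sorted(log, key=lambda t: t.patient_id)
        ]
        pd.DataFrame(attr_rows, columns=["patient_id", *attr_names]).to_csv(
            attributes_path, index=False
        )


# ---------------------------------------------------------------------------
# Stratification


@dataclass
class Stratification:
    """Result of splitting a log on one attribute: sub-logs plus dropped ids.

    Behaves as a mapping from level name to :class:`EventLog`.  Traces
    with a missing attribute value are never imputed; they are dropped
    and listed in :attr:`dropped`.
    """

    levels: dict[str, EventLog]
    dropped: list[str]
    attribute: str

    def __getitem__(self, level: str) -> EventLog:
        return self.levels[level]

    def __iter__(self) -> Iterator[str]:
        return iter(self.levels)

    def items(self):
        return self.levels.items()

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def stratify(
    log: EventLog,
    attribute: str,
    splitter: float | Iterable[str] | Mapping[object, str] | Callable[[object], str],
) -> Stratification:
    """Split *log* into disjoint sub-logs by a static attribute.

    *splitter* is one of:

    * a number — numeric cut: value ``<= cut`` maps to ``"low"``,
      ``> cut`` to ``"high"`` (the convention used when quantizing age
      at onset at its cohort mean);
    * an iterable of level names — keep traces whose value is one of
      those levels, one sub-log per level (others dropped and counted);
    * a mapping raw-value -> level name;
    * a callable value -> level name (return ``None`` to drop).

    Raises ``KeyError`` if no trace carries *attribute* at all.
    """
    if not any(attribute in tr.attributes for tr in log):
        raise KeyError(f"attribute {attribute!r} not present in any trace")

    if isinstance(splitter, (int, float)) and not isinstance(splitter, bool):
        cut = float(splitter)

        def assign(value):
            return "low" if float(value) <= cut else "high"

        level_names: list[str] = ["low", "high"]
    elif callable(splitter):
        assign = splitter  # type: ignore[assignment]
        level_names = []
    elif isinstance(splitter, Mapping):
        mapping = dict(splitter)

        def assign(value):
            return mapping.get(value)

        level_names = sorted(set(mapping.values()))
    else:
        allowed = list(splitter)

        def assign(value):
            return value if value in allowed else None

        level_names = list(allowed)

    buckets: dict[str, dict[str, Trace]] = {name: {} for name in level_names}
    dropped: list[str] = []
    for tr in log:
        value = tr.attributes.get(attribute)
        if _is_missing(value):
            dropped.append(tr.patient_id)
            continue
        level = assign(value)
        if level is None:
            dropped.append(tr.patient_id)
            continue
        buckets.setdefault(str(level), {})[tr.patient_id] = tr

    levels = {
        name: EventLog(traces=traces, metadata={**log.metadata, attribute: name})
        for name, traces in buckets.items()
    }
    return Stratification(levels=levels, dropped=dropped, attribute=attribute)
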