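"""HIS-style operational event logs and per-visit episode reconstruction.

An outpatient visit leaves a short trail of events in the hospital
information system: registration at the front desk, optionally a
preliminary examination, addition into the assigned physician's queue
(T1), and the physician's call for consultation (T2).  The physician's
*next* call within the same half-day session marks the end of the
consultation (T3), so consultation durations tile the call sequence.
Waiting time is T2 - T1; consultation time is T3 - T2.

Logs are plain delimited text (comma by default, tab accepted) with the
columns ``Index, Patient ID, Assign physician, Sequence, Activity,
Event Time``; the synthetic dialect appends ``Appointment`` (0/1) and
``Patient Type`` annotations, which real systems would derive from
medical records.
"""

from __future__ import annotations

import datetime as _dt
import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Activity",
    "PatientType",
    "EventRecord",
    "Episode",
    "DropReport",
    "read_event_log",
    "write_event_log",
    "reconstruct_episodes",
    "EventLogError",
    "SchemaError",
    "IntegrityError",
]

TIME_FORMAT = "%Y-%m-%d %H:%M:%S"

#: Morning/afternoon boundary used when chaining T3: a call before this
#: clock time belongs to the morning session.  Chaining never crosses it,
#: so the lunch break cannot inflate the last morning consultation.
SESSION_CUT = _dt.time(12, 30)

BASE_COLUMNS = [
    "Index",
    "Patient ID",
    "Assign physician",
    "Sequence",
    "Activity",
    "Event Time",
]
ANNOTATION_COLUMNS = ["Appointment", "Patient Type"]


class EventLogError(ValueError):
    """Base class for event-log validation failures."""


class SchemaError(EventLogError):
    """Header, activity label or timestamp does not match the dialect."""


class IntegrityError(EventLogError):
    """Rows violate within-visit ordering or uniqueness invariants."""


class Activity(str, enum.Enum):
    REGISTRATION = "Registration"
    PRELIMINARY_EXAMINATION = "Preliminary examination"
    ADDITION_INTO_QUEUE = "Addition into queue"
    CALL_FOR_CONSULTATION = "Call for a consultation"


class PatientType(str, enum.Enum):
    """Visit categories used for the queue-composition features."""

    RETURN = "return"
    NEWLY_VISITING = "newly_visiting"
    FIRST_TIME = "first_time"
    DEPT_FIRST_TIME = "dept_first_time"


@dataclass(frozen=True)
class EventRecord:
    index: int
    patient_id: str
    physician_id: str
    sequence: int
    activity: Activity
    event_time: _dt.datetime
    appointment: int | None = None  # synthetic-dialect annotation
    patient_type: PatientType | None = None

    @property
    def visit_key(self) -> tuple[str, _dt.date]:
        """One visit = one patient on one calendar day."""
        return (self.patient_id, self.event_time.date())


@dataclass
class Episode:
    """A reconstructed visit with its waiting / consultation durations."""

    patient_id: str
    physician_id: str
    visit_date: _dt.date
    t_registration: _dt.datetime
    t_queue_entry: _dt.datetime  # T1
    t_call: _dt.datetime  # T2
    t_consult_end: _dt.datetime | None  # T3 (absent for a session's last call)
    appointment_flag: int = 0
    patient_type: PatientType | None = None

    @property
    def waiting_minutes(self) -> float:
        return (self.t_call - self.t_queue_entry).total_seconds() / 60.0

    @property
    def consultation_minutes(self) -> float | None:
        if self.t_consult_end is None:
            return None
        return (self.t_consult_end - self.t_call).total_seconds() / 60.0


@dataclass
class DropReport:
    """Counts of visits excluded during reconstruction (reported, not raised)."""

    missing_queue_entry: int = 0
    missing_call: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.missing_queue_entry + self.missing_call


_ACTIVITY_BY_LABEL = {a.value: a for a in Activity}
_PATIENT_TYPE_BY_LABEL = {t.value: t for t in PatientType}


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_event_log(source) -> list[EventRecord]:
    """Parse a delimited event-log stream into validated records.

    ``source`` may be a path, a file object, or a string containing the
    log text.  Records are returned in file order; all within-visit
    invariants are checked (strictly increasing sequence, non-decreasing
    time, at most one queue entry and one call per visit).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise SchemaError("empty stream: expected a header row")
    sep = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(sep)]
    if header[: len(BASE_COLUMNS)] != BASE_COLUMNS:
        raise SchemaError(
            f"header {header!r} does not start with the required columns {BASE_COLUMNS}"
        )
    extra = header[len(BASE_COLUMNS) :]
    has_annotations = extra[: len(ANNOTATION_COLUMNS)] == ANNOTATION_COLUMNS

    records: list[EventRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < len(BASE_COLUMNS):
            raise SchemaError(f"row {lineno}: expected at least {len(BASE_COLUMNS)} fields")
        idx_s, pid, doc, seq_s, act_s, time_s = parts[: len(BASE_COLUMNS)]
        if act_s not in _ACTIVITY_BY_LABEL:
            raise SchemaError(f"row {lineno}: unknown activity label {act_s!r}")
        try:
            event_time = _dt.datetime.strptime(time_s, TIME_FORMAT)
        except ValueError as exc:
            raise SchemaError(f"row {lineno}: malformed timestamp {time_s!r}") from exc
        try:
            index = int(idx_s)
            sequence = int(seq_s)
        except ValueError as exc:
            raise SchemaError(f"row {lineno}: non-integer Index/Sequence") from exc
        if index <= 0 or sequence <= 0:
            raise SchemaError(f"row {lineno}: Index and Sequence must be positive")
        appointment: int | None = None
        patient_type: PatientType | None = None
        if has_annotations and len(parts) >= len(BASE_COLUMNS) + 2:
            appt_s = parts[len(BASE_COLUMNS)]
            ptype_s = parts[len(BASE_COLUMNS) + 1]
            if appt_s != "":
                if appt_s not in ("0", "1"):
                    raise SchemaError(f"row {lineno}: Appointment must be 0 or 1")
                appointment = int(appt_s)
            if ptype_s != "":
                if ptype_s not in _PATIENT_TYPE_BY_LABEL:
                    raise SchemaError(f"row {lineno}: unknown patient type {ptype_s!r}")
                patient_type = _PATIENT_TYPE_BY_LABEL[ptype_s]
        records.append(
            EventRecord(
                index=index,
                patient_id=pid,
                physician_id=doc,
                sequence=sequence,
                activity=Activity(act_s),
                event_time=event_time,
                appointment=appointment,
                patient_type=patient_type,
            )
        )
    _validate(records)
    return records


def _validate(records: Sequence[EventRecord]) -> None:
    by_visit: dict[tuple[str, _dt.date], list[EventRecord]] = {}
    for rec in records:
        by_visit.setdefault(rec.visit_key, []).append(rec)
    for key, recs in by_visit.items():
        last_seq = 0
        last_time = None
        seen: set[Activity] = set()
        for rec in recs:  # file order within the visit
            if rec.sequence <= last_seq:
                raise IntegrityError(
                    f"visit {key}: Sequence not strictly increasing "
                    f"({rec.sequence} after {last_seq})"
                )
            if last_time is not None and rec.event_time < last_time:
                raise IntegrityError(f"visit {key}: Event Time decreases along Sequence")
            last_seq = rec.sequence
            last_time = rec.event_time
            if rec.activity in (
                Activity.ADDITION_INTO_QUEUE,
                Activity.CALL_FOR_CONSULTATION,
            ):
                if rec.activity in seen:
                    raise IntegrityError(
                        f"visit {key}: duplicate {rec.activity.value!r} event"
                    )
                seen.add(rec.activity)


def write_event_log(records: Iterable[EventRecord], sink=None, sep: str = ",") -> str:
    """Serialize records back to the delimited dialect.

    Annotation columns are emitted whenever any record carries them, so a
    read -> write -> read round trip is the identity.  Returns the text;
    also writes it to ``sink`` (path or file object) when given.
    """
    records = list(records)
    with_annotations = any(
        r.appointment is not None or r.patient_type is not None for r in records
    )
    cols = BASE_COLUMNS + (ANNOTATION_COLUMNS if with_annotations else [])
    lines = [sep.join(cols)]
    for r in records:
        row = [
            str(r.index),
            r.patient_id,
            r.physician_id,
            str(r.sequence),
            r.activity.value,
            r.event_time.strftime(TIME_FORMAT),
        ]
        if with_annotations:
            row.append("" if r.appointment is None else str(r.appointment))
            row.append("" if r.patient_type is None else r.patient_type.value)
        lines.append(sep.join(row))
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def _session_of(t: _dt.datetime) -> int:
    """0 = morning, 1 = afternoon; boundary at SESSION_CUT."""
    return 0 if t.time() < SESSION_CUT else 1


def reconstruct_episodes(
    records: Sequence[EventRecord],
) -> tuple[list[Episode], DropReport]:
    """Rebuild per-visit episodes and chain consultation end times.

    T1 is the queue-entry event, T2 the call.  T3 is the same
    physician's next call within the same date and half-day session;
    the last call of each physician-session has no T3 (its consultation
    is dropped from duration statistics but its waiting time is kept).
    Visits lacking T1 or T2 are excluded and counted in the drop report.
    """
    report = DropReport()
    by_visit: dict[tuple[str, _dt.date], list[EventRecord]] = {}
    for rec in records:
        by_visit.setdefault(rec.visit_key, []).append(rec)

    episodes: list[Episode] = []
    for (pid, date), recs in by_visit.items():
        # same-second ties resolved by Sequence then file order (stable sort)
        recs = sorted(recs, key=lambda r: (r.event_time, r.sequence))
        t_reg = t1 = t2 = None
        physician = recs[0].physician_id
        appointment = 0
        ptype: PatientType | None = None
        for rec in recs:
            if rec.appointment is not None:
                appointment = rec.appointment
            if rec.patient_type is not None:
                ptype = rec.patient_type
            if rec.activity is Activity.REGISTRATION:
                t_reg = rec.event_time
            elif rec.activity is Activity.ADDITION_INTO_QUEUE:
                t1 = rec.event_time
            elif rec.activity is Activity.CALL_FOR_CONSULTATION:
                t2 = rec.event_time
                physician = rec.physician_id
        if t1 is None:
            report.missing_queue_entry += 1
            report.reasons["no queue entry"] = report.reasons.get("no queue entry", 0) + 1
            continue
        if t2 is None:
            report.missing_call += 1
            report.reasons["no call"] = report.reasons.get("no call", 0) + 1
            continue
        episodes.append(
            Episode(
                patient_id=pid,
                physician_id=physician,
                visit_date=date,
                t_registration=t_reg if t_reg is not None else t1,
                t_queue_entry=t1,
                t_call=t2,
                t_consult_end=None,
                appointment_flag=appointment,
                patient_type=ptype,
            )
        )

    # chain T3 = next call by the same physician within the same session
    keyed = sorted(episodes, key=lambda e: (e.physician_id, e.visit_date, e.t_call))
    for prev, nxt in zip(keyed, keyed[1:]):
        if (
            prev.physician_id == nxt.physician_id
            and prev.visit_date == nxt.visit_date
            and _session_of(prev.t_call) == _session_of(nxt.t_call)
        ):
            prev.t_consult_end = nxt.t_call
    episodes.sort(key=lambda e: (e.visit_date, e.t_queue_entry, e.patient_id))
    return episodes, report


def episodes_to_frame(episodes: Sequence[Episode]) -> pd.DataFrame:
    """Tabular view of episodes (one row per visit)."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "physician_id": [e.physician_id for e in episodes],
            "visit_date": [e.visit_date for e in episodes],
            "t_registration": [e.t_registration for e in episodes],
            "t_queue_entry": [e.t_queue_entry for e in episodes],
            "t_call": [e.t_call for e in episodes],
            "t_consult_end": [e.t_consult_end for e in episodes],
            "waiting_minutes": [e.waiting_minutes for e in episodes],
            "consultation_minutes": [e.consultation_minutes for e in episodes],
            "appointment_flag": [e.appointment_flag for e in episodes],
            "patient_type": [
                None if e.patient_type is None else e.patient_type.value
                for e in episodes
            ],
        }
    )
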