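"""Discrete-event simulator for an outpatient clinic.

The simulator emulates the operational flow a hospital information
system records: patients register at the front desk (from 08:00),
enter their assigned physician's queue either immediately (appointment)
or after a stochastic delay (walk-in), and are called strictly FIFO by
queue-entry time.  Physicians consult during two daily session windows
(09:00-12:00 and 13:00-17:30 by default), one patient at a time,
running overtime after the afternoon window until the queue clears.

It exists so that every downstream stage — feature engineering,
preprocessing, asymmetric-loss training, DAES selection, explanation —
is testable end-to-end without access to real hospital data.  Defaults
are chosen to produce congestion magnitudes comparable to a crowded
real department (consultations ~5 min capped at 15, mean waits in the
tens of minutes, queues of up to ~20 patients); reproducing any real
department's statistics exactly is a non-goal.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eventlog import (
    Activity,
    EventRecord,
    PatientType,
    reconstruct_episodes,
)

__all__ = ["ClinicConfig", "ConfigError", "SimulatedVisit", "simulate", "summarize"]


class ConfigError(ValueError):
    """Raised for infeasible simulator configurations."""


#: Default per-physician arrivals per hour, keyed by clock hour.  Intake
#: intensifies toward the end of each session (front desks get busier as
#: the morning/afternoon progresses), and patients registering during
#: the 08:00 hour accumulate before consultations start at 09:00.
DEFAULT_ARRIVAL_INTENSITY: dict[int, float] = {
    8: 8.0,
    9: 10.0,
    10: 11.0,
    11: 12.0,
    13: 10.0,
    14: 11.0,
    15: 12.0,
    16: 12.0,
    17: 8.0,
}

# Mean queue-composition ratios of the four visit categories, normalized
# to a proper probability vector.
_RAW_TYPE_WEIGHTS = np.array([0.86, 0.012, 0.03, 0.043])
DEFAULT_PATIENT_TYPE_PROBS: tuple[float, ...] = tuple(
    _RAW_TYPE_WEIGHTS / _RAW_TYPE_WEIGHTS.sum()
)

PATIENT_TYPES = (
    PatientType.RETURN,
    PatientType.NEWLY_VISITING,
    PatientType.FIRST_TIME,
    PatientType.DEPT_FIRST_TIME,
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_duration(spec: Mapping, rng: np.random.Generator, upper: float | None = None) -> float:
    """Draw one duration (minutes) from a distribution spec dict.

    Kinds: ``fixed`` (value), ``exponential`` (mean), ``uniform`` (low,
    high), ``lognormal`` (mean, sd).  ``max`` in the spec (or the
    ``upper`` override, whichever is smaller) truncates by resampling.
    """
    kind = spec.get("kind", "fixed")
    cap = spec.get("max")
    if upper is not None:
        cap = upper if cap is None else min(cap, upper)
    for _ in range(10_000):
        if kind == "fixed":
            x = float(spec["value"])
        elif kind == "exponential":
            x = float(rng.exponential(spec["mean"]))
        elif kind == "uniform":
            x = float(rng.uniform(spec["low"], spec["high"]))
        elif kind == "lognormal":
            mu, sigma = _lognormal_params(spec["mean"], spec["sd"])
            x = float(rng.lognormal(mu, sigma))
        else:
            raise ConfigError(f"unknown distribution kind {kind!r}")
        if cap is None or x <= cap:
            return x
        if kind == "fixed":
            return min(x, cap)  # a fixed value cannot be resampled below a cap
    raise ConfigError(f"truncation at {cap} rejected 10000 draws from {spec!r}")


@dataclass
class ClinicConfig:
    n_physicians: int = 3
    n_days: int = 20
    start_date: _dt.date = _dt.date(2021, 6, 7)
    registration_open: _dt.time = _dt.time(8, 0)
    session_windows: tuple[tuple[_dt.time, _dt.time], ...] = (
        (_dt.time(9, 0), _dt.time(12, 0)),
        (_dt.time(13, 0), _dt.time(17, 30)),
    )
    arrival_intensity: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ARRIVAL_INTENSITY)
    )
    appointment_prob: float = 0.909
    patient_type_probs: Sequence[float] = DEFAULT_PATIENT_TYPE_PROBS
    preliminary_exam_prob: float = 0.10
    #: consultation service time; truncated to (0, 15] by resampling
    consult_dist: Mapping = field(
        default_factory=lambda: {"kind": "lognormal", "mean": 4.7, "sd": 2.7, "max": 15.0}
    )
    #: delay between registration (or exam end) and queue entry, walk-ins
    walkin_queue_delay_dist: Mapping = field(
        default_factory=lambda: {"kind": "exponential", "mean": 10.0}
    )
    #: front-desk processing before an appointment patient is queued
    appointment_queue_delay_dist: Mapping = field(
        default_factory=lambda: {"kind": "uniform", "low": 1 / 60, "high": 0.5}
    )
    #: physician's idle gap between the end of one consultation and the
    #: next call while the queue is non-empty
    idle_gap_dist: Mapping = field(
        default_factory=lambda: {"kind": "exponential", "mean": 0.4, "max": 3.0}
    )
    #: duration of a preliminary examination
    exam_duration_dist: Mapping = field(
        default_factory=lambda: {"kind": "uniform", "low": 1.0, "high": 5.0}
    )
    seed: int = 0
    #: optional deterministic visit script: list of dicts with keys
    #: day (int), physician (int), registration (clock time or "HH:MM:SS"),
    #: appointment (0/1), patient_type (label); replaces random arrivals.
    scripted_visits: Sequence[Mapping] | None = None

    def validate(self) -> None:
        if self.n_physicians < 1 or self.n_days < 1:
            raise ConfigError("n_physicians and n_days must be positive")
        if not 0.0 <= self.appointment_prob <= 1.0:
            raise ConfigError("appointment_prob must lie in [0, 1]")
        if not 0.0 <= self.preliminary_exam_prob <= 1.0:
            raise ConfigError("preliminary_exam_prob must lie in [0, 1]")
        probs = np.asarray(self.patient_type_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("patient_type_probs must be a 4-vector summing to 1")
        if not self.session_windows:
            raise ConfigError("at least one session window is required")
        for start, end in self.session_windows:
            if start >= end:
                raise ConfigError(f"empty session window {start}–{end}")
        if any(rate < 0 for rate in self.arrival_intensity.values()):
            raise ConfigError("arrival intensities must be non-negative")


@dataclass
class SimulatedVisit:
    patient_id: str
    physician_id: str
    registration: _dt.datetime
    appointment_flag: int
    patient_type: PatientType
    exam_time: _dt.datetime | None
    queue_entry: _dt.datetime
    call_time: _dt.datetime | None = None
    service_minutes: float = 0.0


def _dtm(date: _dt.date, minutes: float) -> _dt.datetime:
    """Day-relative minutes-after-midnight to a whole-second timestamp."""
    return _dt.datetime.combine(date, _dt.time()) + _dt.timedelta(
        seconds=int(round(minutes * 60.0))
    )


def _minutes(t: _dt.time) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0


def _one_physician_day(
    config: ClinicConfig,
    date: _dt.date,
    physician_id: str,
    rng: np.random.Generator,
    scripted: Sequence[Mapping] | None,
) -> list[SimulatedVisit]:
    reg_open = _minutes(config.registration_open)
    visits: list[SimulatedVisit] = []

    if scripted is not None:
        raw = []
        for v in scripted:
            t = v["registration"]
            if isinstance(t, str):
                h, m, *s = (int(p) for p in t.split(":"))
                t = _dt.time(h, m, s[0] if s else 0)
            raw.append(
                (
                    _minutes(t),
                    int(v.get("appointment", 1)),
                    PatientType(v.get("patient_type", "return")),
                )
            )
    else:
        raw = []
        for hour in sorted(config.arrival_intensity):
            rate = config.arrival_intensity[hour]
            # arrivals stop when afternoon registration closes
            close = _minutes(config.session_windows[-1][1])
            lo = max(hour * 60.0, reg_open)
            hi = min((hour + 1) * 60.0, close)
            if hi <= lo or rate <= 0:
                continue
            n = rng.poisson(rate * (hi - lo) / 60.0)
            times = np.sort(rng.uniform(lo, hi, size=n))
            for t in times:
                appt = int(rng.random() < config.appointment_prob)
                ptype = PATIENT_TYPES[
                    rng.choice(4, p=np.asarray(config.patient_type_probs, dtype=float))
                ]
                raw.append((float(t), appt, ptype))
        raw.sort(key=lambda r: r[0])

    for i, (reg_min, appt, ptype) in enumerate(raw):
        exam_t = None
        entry_base = reg_min
        if scripted is None and rng.random() < config.preliminary_exam_prob:
            exam_min = reg_min + sample_duration(config.exam_duration_dist, rng)
            exam_t = _dtm(date, exam_min)
            entry_base = exam_min
        delay_dist = (
            config.appointment_queue_delay_dist if appt else config.walkin_queue_delay_dist
        )
        entry_min = entry_base + sample_duration(delay_dist, rng)
        visits.append(
            SimulatedVisit(
                patient_id=f"P{date.strftime('%Y%m%d')}-{physician_id}-{i + 1:03d}",
                physician_id=physician_id,
                registration=_dtm(date, reg_min),
                appointment_flag=appt,
                patient_type=ptype,
                exam_time=exam_t,
                queue_entry=_dtm(date, entry_min),
            )
        )

    # FIFO single-server consultation loop over session windows
    windows = [(_minutes(s), _minutes(e)) for s, e in config.session_windows]
    order = sorted(range(len(visits)), key=lambda i: (visits[i].queue_entry, i))
    next_free = windows[0][0]
    for idx in order:
        v = visits[idx]
        entry_min = (v.queue_entry - _dt.datetime.combine(date, _dt.time())).total_seconds() / 60.0
        call = max(entry_min, next_free, windows[0][0])
        # a call falling in a between-session gap waits for the next window;
        # after the last window's end the physician runs overtime instead
        for (s0, e0), (s1, _e1) in zip(windows, windows[1:]):
            if e0 <= call < s1:
                call = max(entry_min, s1)
        idle = sample_duration(config.idle_gap_dist, rng)
        # service + idle jointly capped at the consultation-time bound so the
        # reconstructed gap between consecutive calls respects the cap
        cap = config.consult_dist.get("max")
        service = sample_duration(
            config.consult_dist, rng, upper=None if cap is None else cap - idle
        )
        v.call_time = _dtm(date, call)
        v.service_minutes = service
        next_free = call + service + idle
    return visits


def simulate(config: ClinicConfig) -> list[EventRecord]:
    """Run the clinic and emit a validated event log.

    The same seed and config always produce a byte-identical log.  Each
    visit emits exactly one Registration, at most one Preliminary
    examination, one Addition into queue and one Call for a
    consultation; calls are strictly FIFO by queue-entry time within
    each physician.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_days * config.n_physicians)

    events: list[tuple[_dt.datetime, str, int, Activity, SimulatedVisit]] = []
    k = 0
    for d in range(config.n_days):
        date = config.start_date + _dt.timedelta(days=d)
        for p in range(config.n_physicians):
            rng = np.random.default_rng(streams[k])
            k += 1
            scripted = None
            if config.scripted_visits is not None:
                scripted = [
                    v
                    for v in config.scripted_visits
                    if int(v.get("day", 0)) == d and int(v.get("physician", 0)) == p
                ]
            visits = _one_physician_day(config, date, f"D{p + 1}", rng, scripted)
            for v in visits:
                events.append((v.registration, v.patient_id, 1, Activity.REGISTRATION, v))
                seq = 2
                if v.exam_time is not None:
                    events.append(
                        (v.exam_time, v.patient_id, seq, Activity.PRELIMINARY_EXAMINATION, v)
                    )
                    seq += 1
                events.append((v.queue_entry, v.patient_id, seq, Activity.ADDITION_INTO_QUEUE, v))
                events.append(
                    (v.call_time, v.patient_id, seq + 1, Activity.CALL_FOR_CONSULTATION, v)
                )

    events.sort(key=lambda e: (e[0], e[1], e[2]))
    records = [
        EventRecord(
            index=i + 1,
            patient_id=e[1],
            physician_id=e[4].physician_id,
            sequence=e[2],
            activity=e[3],
            event_time=e[0],
            appointment=e[4].appointment_flag,
            patient_type=e[4].patient_type,
        )
        for i, e in enumerate(events)
    ]
    return records


def summarize(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Descriptive statistics of a log, in long form.

    Returns a frame with columns ``variable, stat, value`` covering visit
    counts, min/max/mean/sd of waiting and consultation minutes and
    queue length at registration, and category frequencies — the layout
    of a standard clinic descriptives table.
    """
    from .features import FeatureConfig, build_features  # local import, no cycle

    rows: list[tuple[str, str, float]] = []
    episodes, drop = reconstruct_episodes(records)
    rows.append(("n_visits", "count", float(len(episodes))))
    rows.append(("n_dropped", "count", float(drop.total)))
    if not episodes:
        return pd.DataFrame(rows, columns=["variable", "stat", "value"])

    feats = build_features(episodes, FeatureConfig())

    def describe(name: str, values: pd.Series) -> None:
        values = values.dropna()
        if values.empty:
            return
        rows.append((name, "min", float(values.min())))
        rows.append((name, "max", float(values.max())))
        rows.append((name, "mean", float(values.mean())))
        rows.append((name, "sd", float(values.std(ddof=1)) if len(values) > 1 else 0.0))

    describe("waiting_minutes", feats["waiting_minutes"])
    consult = pd.Series([e.consultation_minutes for e in episodes], dtype=float)
    describe("consultation_minutes", consult)
    describe("queue_length", feats["Q_L"])
    for col in ("Q_R", "Q_N", "Q_F", "Q_D", "P_ACT", "P_NP"):
        describe(col, feats[col])
    n = float(len(feats))
    rows.append(("appointment", "share_yes", float(feats["A_S"].mean())))
    rows.append(("smooth_zone", "share_yes", float(feats["T_S"].mean())))
    for ptype in PATIENT_TYPES:
        share = float((feats["patient_type"] == ptype.value).sum() / n)
        rows.append((f"type_{ptype.value}", "share", share))
    return pd.DataFrame(rows, columns=["variable", "stat", "value"])
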