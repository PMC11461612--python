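"""Predictors of waiting time, computed at each patient's registration.

Nine features summarise what the front desk can observe the moment a
patient registers — nothing that happens later may leak in:

* queue factor: ``Q_L`` (length of the assigned physician's queue) and
  the composition ratios ``Q_R``/``Q_N``/``Q_F``/``Q_D`` of returning,
  newly visiting, first-time and department-first-time patients in it;
* patient factor: ``A_S`` (appointment made, 0/1);
* time factor: ``T_S`` (registration within a smooth-flow clock zone);
* physician factor: ``P_ACT`` (mean consultation minutes of the
  physician's consultations that ended in the τ minutes before
  registration) and ``P_NP`` (how many such consultations there were).

Queue membership is the half-open interval [T1, T2): a patient being
called at exactly the anchor time is no longer waiting.  The arriving
patient is not part of their own queue snapshot.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .eventlog import Episode

__all__ = [
    "FeatureConfig",
    "FEATURE_COLUMNS",
    "CONTINUOUS_FEATURES",
    "BINARY_FEATURES",
    "queue_snapshot",
    "physician_window_stats",
    "build_features",
]

FEATURE_COLUMNS = ["Q_L", "Q_R", "Q_N", "Q_F", "Q_D", "A_S", "T_S", "P_ACT", "P_NP"]
CONTINUOUS_FEATURES = ["Q_L", "Q_R", "Q_N", "Q_F", "Q_D", "P_ACT", "P_NP"]
BINARY_FEATURES = ["A_S", "T_S"]

_TYPE_TO_RATIO = {
    "return": "Q_R",
    "newly_visiting": "Q_N",
    "first_time": "Q_F",
    "dept_first_time": "Q_D",
}


@dataclass
class FeatureConfig:
    """τ look-back window and smooth-flow clock zones (half-open)."""

    tau: float = 60.0  # minutes
    smooth_zones: tuple[tuple[_dt.time, _dt.time], ...] = (
        (_dt.time(8, 0), _dt.time(10, 0)),
        (_dt.time(13, 0), _dt.time(15, 0)),
    )

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        zones = sorted(self.smooth_zones)
        for (s0, e0), (s1, _e1) in zip(zones, zones[1:]):
            if e0 > s1:
                raise ValueError("smooth zones must not overlap")
        for s, e in zones:
            if s >= e:
                raise ValueError(f"empty smooth zone {s}–{e}")

    def in_smooth_zone(self, t: _dt.datetime) -> bool:
        clock = t.time()
        return any(s <= clock < e for s, e in self.smooth_zones)


def queue_snapshot(
    episodes: Sequence[Episode], physician_id: str, t: _dt.datetime
) -> list[Episode]:
    """Patients of ``physician_id`` waiting at instant ``t``.

    Exactly the episodes with T1 <= t < T2 — entered the queue, not yet
    called (half-open, so a patient called at exactly ``t`` is out).
    """
    return [
        e
        for e in episodes
        if e.physician_id == physician_id and e.t_queue_entry <= t < e.t_call
    ]


def physician_window_stats(
    episodes: Sequence[Episode],
    physician_id: str,
    t: _dt.datetime,
    tau: float,
) -> tuple[float, int]:
    """(P_ACT, P_NP): the physician's recent consultation record.

    Counts consultations by the physician that *ended* within
    [t - tau, t) and averages their durations; (0, 0) when none did.
    A consultation still running at ``t`` contributes nothing.
    """
    lo = t - _dt.timedelta(minutes=tau)
    durations = [
        e.consultation_minutes
        for e in episodes
        if e.physician_id == physician_id
        and e.t_consult_end is not None
        and lo <= e.t_consult_end < t
    ]
    if not durations:
        return 0.0, 0
    return float(sum(durations) / len(durations)), len(durations)


def build_features(
    episodes: Sequence[Episode], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """One feature row per episode, anchored at its registration time.

    Every snapshot and window statistic uses only events at or before
    the anchor, so the row is computable the moment the patient stands
    at the front desk.  Queue members lacking a patient-type label raise
    a ``ValueError`` rather than silently skewing the ratios.
    """
    if config is None:
        config = FeatureConfig()
    # queue intervals and the tau-window never span midnight here, so
    # grouping by physician-day is exact and keeps the scan linear
    by_day: dict[tuple[str, _dt.date], list[Episode]] = {}
    for e in episodes:
        by_day.setdefault((e.physician_id, e.visit_date), []).append(e)

    rows = []
    for e in episodes:
        t = e.t_registration
        peers = by_day[(e.physician_id, e.visit_date)]
        # the arriving patient is not yet in the queue at their own registration
        queue = [q for q in peers if q is not e and q.t_queue_entry <= t < q.t_call]
        ratios = {"Q_R": 0.0, "Q_N": 0.0, "Q_F": 0.0, "Q_D": 0.0}
        if queue:
            for q in queue:
                if q.patient_type is None:
                    raise ValueError(
                        f"queue member {q.patient_id} on {q.visit_date} lacks a "
                        "patient-type label; ratios would be skewed"
                    )
                ratios[_TYPE_TO_RATIO[q.patient_type.value]] += 1.0
            for k in ratios:
                ratios[k] /= len(queue)
        p_act, p_np = physician_window_stats(peers, e.physician_id, t, config.tau)
        rows.append(
            {
                "patient_id": e.patient_id,
                "physician_id": e.physician_id,
                "registration_time": t,
                "patient_type": None if e.patient_type is None else e.patient_type.value,
                "Q_L": len(queue),
                **ratios,
                "A_S": int(e.appointment_flag),
                "T_S": int(config.in_smooth_zone(t)),
                "P_ACT": p_act,
                "P_NP": p_np,
                "waiting_minutes": e.waiting_minutes,
            }
        )
    columns = [
        "patient_id",
        "physician_id",
        "registration_time",
        "patient_type",
        *FEATURE_COLUMNS,
        "waiting_minutes",
    ]
    return pd.DataFrame(rows, columns=columns)
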