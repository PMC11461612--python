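"""Feature engineering: queue snapshots, physician windows, causality."""

import datetime as dt

import numpy as np
import pytest

import waitcast as wc
from waitcast.eventlog import Episode, PatientType
from waitcast.features import (
    FeatureConfig,
    build_features,
    physician_window_stats,
    queue_snapshot,
)

DAY = dt.date(2020, 8, 3)


def ts(hms: str) -> dt.datetime:
    h, m, s = (int(p) for p in hms.split(":"))
    return dt.datetime.combine(DAY, dt.time(h, m, s))


def make_episode(pid, physician, t1, t2, t3=None, reg=None, ptype="return", appt=1):
    return Episode(
        patient_id=pid,
        physician_id=physician,
        visit_date=DAY,
        t_registration=ts(reg or t1),
        t_queue_entry=ts(t1),
        t_call=ts(t2),
        t_consult_end=None if t3 is None else ts(t3),
        appointment_flag=appt,
        patient_type=PatientType(ptype),
    )


class TestQueueSnapshot:
    def test_dummy_log_snapshot(self, table1_episodes):
        episodes, _ = table1_episodes
        snap = queue_snapshot(episodes, "Physician A", ts("10:20:00"))
        assert {e.patient_id for e in snap} == {"Patient A", "Patient B"}

    def test_before_any_entry_is_empty(self, table1_episodes):
        episodes, _ = table1_episodes
        assert queue_snapshot(episodes, "Physician A", ts("09:00:00")) == []

    def test_call_instant_excluded_half_open(self, table1_episodes):
        episodes, _ = table1_episodes
        snap = queue_snapshot(episodes, "Physician A", ts("10:33:28"))
        assert {e.patient_id for e in snap} == {"Patient B"}


class TestPhysicianWindow:
    def test_empty_window(self):
        eps = [make_episode("a", "D", "09:00:00", "09:05:00", "09:10:00")]
        assert physician_window_stats(eps, "D", ts("11:00:00"), 60.0) == (0.0, 0)

    def test_single_consultation(self):
        eps = [make_episode("a", "D", "09:00:00", "09:05:00", "09:10:00")]
        assert physician_window_stats(eps, "D", ts("09:30:00"), 60.0) == (5.0, 1)

    def test_mean_of_three(self):
        eps = [
            make_episode("a", "D", "09:00:00", "09:00:00", "09:02:00"),
            make_episode("b", "D", "09:00:00", "09:02:00", "09:06:00"),
            make_episode("c", "D", "09:00:00", "09:06:00", "09:12:00"),
        ]
        p_act, p_np = physician_window_stats(eps, "D", ts("09:30:00"), 60.0)
        assert (p_act, p_np) == (4.0, 3)

    def test_consultation_straddling_anchor_contributes_nothing(self):
        eps = [make_episode("a", "D", "09:00:00", "09:05:00", "09:20:00")]
        assert physician_window_stats(eps, "D", ts("09:10:00"), 60.0) == (0.0, 0)


class TestBuildFeatures:
    def test_queue_composition_ratios(self):
        waiting = [
            make_episode("r1", "D", "09:00:00", "11:00:00", ptype="return"),
            make_episode("r2", "D", "09:01:00", "11:05:00", ptype="return"),
            make_episode("n1", "D", "09:02:00", "11:10:00", ptype="newly_visiting"),
        ]
        target = make_episode("x", "D", "09:30:00", "11:20:00", reg="09:30:00")
        row = build_features(waiting + [target]).set_index("patient_id").loc["x"]
        assert row["Q_L"] == 3
        assert row["Q_R"] == pytest.approx(2 / 3)
        assert row["Q_N"] == pytest.approx(1 / 3)
        assert row["Q_F"] == 0 and row["Q_D"] == 0

    @pytest.mark.parametrize("reg, expected", [("09:30:00", 1), ("11:00:00", 0), ("13:00:00", 1), ("15:00:00", 0)])
    def test_smooth_zone_flag(self, reg, expected):
        e = make_episode("x", "D", "11:30:00", "11:40:00", reg=reg)
        # keep queue entry after registration for the afternoon cases
        e.t_queue_entry = e.t_registration
        e.t_call = e.t_registration + dt.timedelta(minutes=10)
        row = build_features([e]).iloc[0]
        assert row["T_S"] == expected

    def test_empty_queue_zero_ratios(self):
        e = make_episode("x", "D", "09:00:00", "09:10:00")
        row = build_features([e]).iloc[0]
        assert row["Q_L"] == 0
        assert row[["Q_R", "Q_N", "Q_F", "Q_D"]].sum() == 0

    def test_unlabeled_queue_member_raises(self):
        waiting = make_episode("w", "D", "09:00:00", "11:00:00")
        waiting.patient_type = None
        target = make_episode("x", "D", "09:30:00", "11:10:00", reg="09:30:00")
        with pytest.raises(ValueError, match="patient-type"):
            build_features([waiting, target])

    def test_ratio_partition_invariant_on_simulated_clinic(self, clinic_features):
        queued = clinic_features[clinic_features["Q_L"] > 0]
        sums = queued[["Q_R", "Q_N", "Q_F", "Q_D"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        empty = clinic_features[clinic_features["Q_L"] == 0]
        assert (empty[["Q_R", "Q_N", "Q_F", "Q_D"]] == 0).all().all()

    def test_causality_future_events_do_not_matter(self, clinic_episodes, clinic_features):
        """Shifting every event that lies after a row's registration time
        must leave that row's features unchanged (sampled rows)."""
        import copy

        rng = np.random.default_rng(0)
        feature_cols = wc.features.FEATURE_COLUMNS
        for idx in rng.choice(len(clinic_episodes), size=12, replace=False):
            anchor_ep = clinic_episodes[idx]
            t = anchor_ep.t_registration
            shifted = []
            for e in clinic_episodes:
                c = copy.copy(e)
                delta = dt.timedelta(hours=1)
                if c.t_call > t:
                    c.t_call = c.t_call + delta
                    if c.t_consult_end is not None:
                        c.t_consult_end = c.t_consult_end + delta
                elif c.t_consult_end is not None and c.t_consult_end > t:
                    c.t_consult_end = c.t_consult_end + delta
                if c.t_queue_entry > t:
                    c.t_queue_entry = min(c.t_queue_entry + delta, c.t_call)
                shifted.append(c)
            original = clinic_features.iloc[idx][feature_cols]
            moved = wc.build_features(shifted).iloc[idx][feature_cols]
            assert (original == moved).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(tau=-5)
        with pytest.raises(ValueError):
            FeatureConfig(smooth_zones=((dt.time(8), dt.time(11)), (dt.time(10), dt.time(12))))
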