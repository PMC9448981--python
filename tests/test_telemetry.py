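"""Replay parsing, derived channels, feature matrix and error score tests."""

import numpy as np
import pytest

from vdtscreen import telemetry
from vdtscreen.telemetry import (
    ERROR_TYPES,
    OUT_OF_ZONE,
    ErrorCounts,
    FeatureMatrix,
    ReplayError,
    ReplayEvent,
    ReplaySession,
    derive_channels,
    parse_replay,
    summarize_variables,
    vdt_error_score,
    write_replay,
)


def make_session(
    session_id="S1",
    n=30,
    rate=10.0,
    speed=None,
    zone_track=None,
    events=(),
    **extra_channels,
):
    """Minimal hand-built session with constant default channels."""
    channels = {
        "speed_mph": np.full(n, 30.0) if speed is None else np.asarray(speed, float),
        "posted_speed_mph": np.full(n, 35.0),
        "lane_offset_m": np.linspace(-0.5, 0.5, n),
        "center_offset_m": np.zeros(n),
        "heading_deg": np.full(n, 90.0),
        "road_heading_deg": np.full(n, 90.0),
        "steering_frac": np.zeros(n),
    }
    channels.update({k: np.asarray(v, float) for k, v in extra_channels.items()})
    if zone_track is None:
        zone_track = np.full(n, OUT_OF_ZONE)
        zone_track[n // 3 : 2 * n // 3] = 0
    return ReplaySession(session_id, rate, channels, np.asarray(zone_track), list(events))


class TestReplayIO:
    def test_round_trip_is_byte_identical(self):
        session = make_session(events=[ReplayEvent(1.0, "red_light_error", 0)])
        text = write_replay(session)
        again = write_replay(parse_replay(text))
        assert text == again

    def test_missing_channel_error_names_field(self):
        session = make_session()
        text = write_replay(session)
        broken = text.replace('"speed_mph":30.0,', "")
        with pytest.raises(ReplayError, match="speed_mph"):
            parse_replay(broken)

    def test_malformed_json(self):
        with pytest.raises(ReplayError, match="malformed"):
            parse_replay("{not json")

    def test_non_uniform_timestamps_rejected(self):
        import json

        obj = json.loads(write_replay(make_session()))
        obj["samples"][3]["t_sec"] = 99.0
        with pytest.raises(ReplayError, match="t_sec"):
            parse_replay(json.dumps(obj))

    def test_sample_count_is_rate_times_duration(self):
        session = make_session(n=6000, rate=10.0)
        assert parse_replay(write_replay(session)).n_samples == 6000

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ReplayError, match="duration"):
            make_session(events=[ReplayEvent(999.0, "teleport", -1)])


class TestDerivedChannels:
    def test_constant_speed_zero_accel_and_jerk(self):
        d = derive_channels(make_session())
        assert np.allclose(d["forward_accel"], 0.0)
        assert np.allclose(d["forward_jerk"], 0.0)

    def test_finite_difference_example(self):
        # speed (10, 12, 12) mph at 10 Hz -> accel (20, 0) mph/s, jerk (-200) mph/s^2
        d = derive_channels(make_session(n=3, speed=[10, 12, 12]))
        assert np.allclose(d["forward_accel"], [20.0, 0.0])
        assert np.allclose(d["forward_jerk"], [-200.0])

    def test_heading_misalignment_wraps(self):
        s = make_session()
        s.channels["heading_deg"][:] = 359.0
        s.channels["road_heading_deg"][:] = 1.0
        assert np.allclose(derive_channels(s)["heading_misalignment"], 2.0)

    def test_below_limit_indicator(self):
        # always 20 mph under the limit -> fully counted at the 15 mph threshold
        s = make_session(speed=np.full(30, 15.0))  # posted 35
        d = derive_channels(s)
        assert np.all(d["below_limit_15"] == 1.0)
        assert np.all(d["below_limit_10"] == 1.0)

    def test_too_short_for_jerk(self):
        with pytest.raises(ReplayError, match="jerk"):
            derive_channels(make_session(n=2))


class TestErrorScore:
    def test_zero_counts_zero_score(self):
        assert vdt_error_score(ErrorCounts({})) == 0.0

    def test_unit_weights(self):
        counts = ErrorCounts(dict(zip(ERROR_TYPES, [2, 0, 1, 0, 0, 0, 0, 0])))
        assert vdt_error_score(counts, dict.fromkeys(ERROR_TYPES, 1.0)) == 3.0

    def test_default_weight_dot_product(self):
        counts = ErrorCounts(dict(zip(ERROR_TYPES, [1, 0, 2, 0, 1, 0, 0, 0])))
        assert vdt_error_score(counts) == 13.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        c1 = ErrorCounts(dict(zip(ERROR_TYPES, rng.integers(0, 5, 8))))
        c2 = ErrorCounts(dict(zip(ERROR_TYPES, rng.integers(0, 5, 8))))
        combined = ErrorCounts({t: c1.counts[t] + c2.counts[t] for t in ERROR_TYPES})
        assert vdt_error_score(combined) == pytest.approx(
            vdt_error_score(c1) + vdt_error_score(c2)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ReplayError, match="negative"):
            ErrorCounts({"teleport": -1})

    def test_incomplete_weights_rejected(self):
        with pytest.raises(ReplayError, match="missing"):
            vdt_error_score(ErrorCounts({}), {"teleport": 1.0})


class TestFeatureMatrix:
    def test_zero_variance_columns_removed_and_logged(self):
        sessions = [make_session(session_id=f"S{i}") for i in range(4)]
        fm = summarize_variables(sessions)
        # identical sessions: everything is constant across participants
        assert len(fm.variable_ids) == 0
        assert len(fm.removed) > 0

    def test_zonal_stats_of_zone_constant_channel(self):
        # channel constant within the zone: min=max=mean=median=constant, sd=0
        n = 30
        zone = np.full(n, OUT_OF_ZONE)
        zone[10:20] = 0
        speed = np.where(zone == 0, 42.0, 13.0)
        sessions = [
            make_session(session_id=f"S{i}", speed=speed, zone_track=zone,
                         probe=np.linspace(i, i + 1, n))
            for i in range(3)
        ]
        fm = summarize_variables(sessions, drop_zero_variance=False)
        for stat, expected in [("min", 42.0), ("max", 42.0), ("mean", 42.0),
                               ("median", 42.0), ("sd", 0.0)]:
            assert fm.values[f"speed_mph|{stat}|zone:0"].iloc[0] == pytest.approx(expected)

    def test_global_stats_use_concatenation_not_zone_means(self):
        n = 30
        zone = np.full(n, OUT_OF_ZONE)
        zone[:6] = 0  # short zone at 10 mph; the rest at 40 mph
        speed = np.where(zone == 0, 10.0, 40.0)
        sessions = [
            make_session(session_id=f"S{i}", speed=speed, zone_track=zone,
                         probe=np.linspace(i, i + 1, n))
            for i in range(2)
        ]
        fm = summarize_variables(sessions, drop_zero_variance=False)
        expected = (6 * 10.0 + 24 * 40.0) / 30  # sample-weighted, not (10+40)/2
        assert fm.values["speed_mph|mean|global"].iloc[0] == pytest.approx(expected)

    def test_column_order_stable_across_runs(self, small_cohort):
        sessions, _, _ = small_cohort
        fm1 = summarize_variables(sessions)
        fm2 = summarize_variables(sessions)
        assert fm1.variable_ids == fm2.variable_ids
        assert fm1.meta["column_index"].tolist() == fm2.meta["column_index"].tolist()

    def test_pct_time_variable_for_always_under_limit(self):
        n = 30
        zone = np.full(n, OUT_OF_ZONE)
        zone[5:25] = 0
        sessions = [
            make_session(session_id=f"S{i}", speed=np.full(n, 15.0), zone_track=zone,
                         probe=np.linspace(i, i + 1, n))
            for i in range(2)
        ]
        fm = summarize_variables(sessions, drop_zero_variance=False)
        assert fm.values["below_limit_15|pct_time|zone:0"].iloc[0] == pytest.approx(1.0)

    def test_error_count_and_score_columns(self):
        events = [ReplayEvent(1.0, "red_light_error", 0), ReplayEvent(1.5, "teleport", -1)]
        sessions = [
            make_session(session_id="S0", events=events, probe=np.linspace(0, 1, 30)),
            make_session(session_id="S1", probe=np.linspace(1, 2, 30)),
        ]
        fm = summarize_variables(sessions, drop_zero_variance=False)
        assert fm.values["error:red_light_error|count|global"].tolist() == [1.0, 0.0]
        assert fm.values["error:red_light_error|count|zone:0"].tolist() == [1.0, 0.0]
        w = telemetry.DEFAULT_ERROR_WEIGHTS
        assert fm.values["vdt_error_score|score|global"].tolist() == [
            w["red_light_error"] + w["teleport"], 0.0]

    def test_read_write_round_trip(self, small_features, tmp_path):
        small_features.write(tmp_path / "fm.csv", tmp_path / "meta.json")
        back = FeatureMatrix.read(tmp_path / "fm.csv", tmp_path / "meta.json")
        assert back.variable_ids == small_features.variable_ids
        assert np.allclose(back.values.to_numpy(), small_features.values.to_numpy())
        assert back.removed == small_features.removed

    def test_missing_zone_policy(self):
        # session 2 never enters zone 1
        n = 30
        zone_a = np.full(n, OUT_OF_ZONE)
        zone_a[:10] = 0
        zone_a[10:20] = 1
        zone_b = np.full(n, OUT_OF_ZONE)
        zone_b[:10] = 0
        s1 = make_session(session_id="S0", zone_track=zone_a, probe=np.linspace(0, 1, n))
        s2 = make_session(session_id="S1", zone_track=zone_b, probe=np.linspace(1, 2, n))
        with pytest.raises(ReplayError, match="zone 1"):
            summarize_variables([s1, s2])
        fm = summarize_variables([s1, s2], missing_zone="nan", drop_zero_variance=False)
        assert np.isnan(fm.values["speed_mph|mean|zone:1"].iloc[1])
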