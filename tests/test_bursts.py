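"""Burst decision rule, event accumulation and the reward state machine."""

import numpy as np
import pytest

from betaburst.artifacts import ArtifactMask
from betaburst.bursts import (
    accumulate_bursts,
    burst_flag,
    replay_schedule,
    reward_controller,
    BurstEvent,
)

FS = 1000.0
CENTERS = np.arange(1.0, 33.0)


def flag_at(power_col, thresholds):
    """Single-time-point flags for a 32-channel power column."""
    return burst_flag(np.asarray(power_col)[:, None], np.asarray(thresholds),
                      CENTERS)[:, 0]


class TestBurstFlag:
    def _field(self, p19, p20, p21, thr20=3.0):
        power = np.zeros(32)
        power[18], power[19], power[20] = p19, p20, p21
        thr = np.full(32, np.inf)
        thr[19] = thr20
        return flag_at(power, thr)

    def test_local_max_above_threshold_flags(self):
        flags = self._field(1.0, 5.0, 2.0)
        assert flags[19]

    def test_larger_neighbour_blocks(self):
        assert not self._field(6.0, 5.0, 2.0)[19]

    def test_threshold_blocks(self):
        assert not self._field(1.0, 5.0, 2.0, thr20=5.0)[19]

    def test_tie_with_neighbour_fails_strict_inequality(self):
        assert not self._field(5.0, 5.0, 2.0)[19]

    def test_edge_channels_never_flag(self):
        power = np.full((32, 10), 1.0)
        power[[0, 31]] = 100.0
        flags = burst_flag(power, np.zeros(32), CENTERS)
        assert not flags[0].any() and not flags[31].any()

    def test_nan_threshold_never_flags(self):
        power = np.zeros((32, 5))
        power[19] = 10.0
        flags = burst_flag(power, np.full(32, np.nan), CENTERS)
        assert not flags.any()

    def test_matches_exhaustive_oracle(self):
        """10^4 random fields against a literal three-condition loop."""
        rng = np.random.default_rng(7)
        power = rng.random((32, 10_000))
        thr = rng.random(32)
        flags = burst_flag(power, thr, CENTERS)
        oracle = np.zeros_like(flags)
        for t in range(power.shape[1]):
            for f in range(1, 31):
                oracle[f, t] = (
                    power[f, t] > power[f - 1, t]
                    and power[f, t] > power[f + 1, t]
                    and power[f, t] > thr[f]
                )
        np.testing.assert_array_equal(flags, oracle)


def make_flags(ms_runs, row=21, n=1000):
    """Flags with [start_ms, stop_ms) runs at one channel (1 kHz clock)."""
    flags = np.zeros((32, n), dtype=bool)
    for a, b in ms_runs:
        flags[row, a:b] = True
    return flags


class TestAccumulate:
    def test_eligible_event(self):
        flags = make_flags([(100, 180)])  # 80 ms at 22 Hz
        events = accumulate_bursts(flags, np.ones((32, 1000)), CENTERS, FS,
                                   target_band=(20.0, 25.0))
        assert len(events) == 1
        ev = events[0]
        assert ev.rewarded and ev.frequency == 22.0
        assert ev.duration_ms == pytest.approx(80.0)

    def test_short_event_recorded_not_eligible(self):
        flags = make_flags([(100, 160)])  # 60 ms
        (ev,) = accumulate_bursts(flags, np.ones((32, 1000)), CENTERS, FS,
                                  target_band=(20.0, 25.0))
        assert not ev.rewarded

    def test_single_gap_splits_runs(self):
        flags = make_flags([(100, 140), (141, 181)])  # 40 ms + 40 ms
        events = accumulate_bursts(flags, np.ones((32, 1000)), CENTERS, FS,
                                   target_band=(20.0, 25.0))
        assert len(events) == 2
        assert not any(e.rewarded for e in events)

    def test_out_of_band_never_eligible(self):
        flags = make_flags([(100, 300)], row=10)  # 200 ms at 11 Hz
        (ev,) = accumulate_bursts(flags, np.ones((32, 1000)), CENTERS, FS,
                                  target_band=(20.0, 25.0))
        assert not ev.rewarded

    def test_band_union_merges_drifting_burst(self):
        """40 ms at 21 Hz then 40 ms at 22 Hz: one eligible event in union
        mode, two ineligible events in per-channel mode."""
        flags = np.zeros((32, 1000), dtype=bool)
        flags[20, 100:140] = True
        flags[21, 140:180] = True
        power = np.ones((32, 1000))
        power[21, 150] = 9.0
        per_channel = accumulate_bursts(flags, power, CENTERS, FS, (20.0, 25.0))
        assert len(per_channel) == 2 and not any(e.rewarded for e in per_channel)
        union = accumulate_bursts(flags, power, CENTERS, FS, (20.0, 25.0),
                                  band_union=True)
        assert len(union) == 1
        assert union[0].rewarded
        assert union[0].frequency == 22.0  # peak-power channel
        assert union[0].peak_sample == 150

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            accumulate_bursts(make_flags([]), np.ones((32, 1000)), CENTERS, FS,
                              target_band=(25.0, 20.0))


def ev(onset_s, dur_ms=80.0, freq=22.0, rewarded=True):
    return BurstEvent(frequency=freq, onset_sample=int(onset_s * FS),
                      duration_ms=dur_ms, peak_power=1.0,
                      peak_sample=int(onset_s * FS) + 40, rewarded=rewarded)


class TestRewardController:
    def test_priming_only(self):
        rewards = reward_controller([], None, session_length=120.0,
                                    sampling_rate=FS)
        assert [r.time for r in rewards] == [0.0, 3.0, 6.0, 9.0, 12.0]

    def test_lockout_suppresses_second(self):
        rewards = reward_controller([ev(20.0), ev(20.2)], None, 120.0, FS)
        assert len(rewards) == 5 + 1

    def test_spaced_events_both_rewarded(self):
        rewards = reward_controller([ev(20.0), ev(25.0)], None, 120.0, FS)
        assert len(rewards) == 5 + 2
        # decision falls at onset + minimum duration + latency
        assert rewards[5].time == pytest.approx(20.0 + 0.070 + 0.002)

    def test_artifact_blocks_reward(self):
        flags = np.zeros(int(120 * FS), dtype=bool)
        flags[int(19.5 * FS) : int(21.5 * FS)] = True
        mask = ArtifactMask(flags=flags, threshold=500.0, pad=0.5,
                            sampling_rate=FS)
        rewards = reward_controller([ev(20.0)], mask, 120.0, FS)
        assert len(rewards) == 5

    def test_ineligible_event_ignored(self):
        rewards = reward_controller([ev(20.0, rewarded=False)], None, 120.0, FS)
        assert len(rewards) == 5

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            reward_controller([], None, 120.0, FS, lockout_s=-1.0)
        with pytest.raises(ValueError):
            reward_controller([ev(30.0), ev(20.0)], None, 120.0, FS)

    def test_no_reward_after_session_end(self):
        rewards = reward_controller([ev(119.99)], None, 120.0, FS)
        assert len(rewards) == 5


def test_sham_replay_reproduces_schedule_exactly():
    schedule = [0.0, 3.0, 17.25, 100.125]
    rewards = replay_schedule(schedule)
    assert [r.time for r in rewards] == schedule
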