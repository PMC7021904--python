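"""Burst decision rule and reward state machine.

A burst at frequency f and time t requires the latched power P(f, t) to
exceed the power of both neighbouring channels and the dynamic 98th
percentile threshold of its own channel.  Runs of contiguous flags become
burst events; events inside the targeted band lasting at least 70 ms are
reward-eligible.  The reward controller delivers 5 priming rewards while
the percentile history fills, then one reward per eligible burst outside
lockout (reward delivery time plus 1 s after any reward or artifact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .artifacts import ArtifactMask

__all__ = [
    "BurstEvent",
    "RewardEvent",
    "burst_flag",
    "accumulate_bursts",
    "reward_controller",
    "replay_schedule",
]


@dataclass(frozen=True)
class BurstEvent:
    frequency: float  # Hz (peak-power channel for band-union events)
    onset_sample: int
    duration_ms: float
    peak_power: float  # uV^2
    peak_sample: int  # sample of the maximal power within the run
    rewarded: bool  # reward-eligible (band + minimum duration)

    def onset_seconds(self, sampling_rate: float) -> float:
        return self.onset_sample / sampling_rate


@dataclass(frozen=True)
class RewardEvent:
    time: float  # s, includes processing latency
    volume: float  # ul
    lockout_until: float  # s


def burst_flag(
    power: np.ndarray, thresholds: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Per-sample burst flags for every channel.

    ``power`` is (n_freqs, n_samples) latched power, ``thresholds`` either a
    per-channel vector or a per-sample (n_freqs, n_samples) track (NaN =
    not ready, never flags).  A channel flags when its power strictly
    exceeds both neighbours and its own threshold; the lowest and highest
    channels have a missing neighbour and never flag.
    """
    power = np.atleast_2d(np.asarray(power, dtype=float))
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 1:
        thresholds = thresholds[:, None]
    if power.shape[0] != len(centers):
        raise ValueError("power rows must match the centre frequencies")
    flags = np.zeros(power.shape, dtype=bool)
    if power.shape[0] < 3:
        return flags
    mid = power[1:-1]
    with np.errstate(invalid="ignore"):
        flags[1:-1] = (
            (mid > power[:-2]) & (mid > power[2:]) & (mid > thresholds[1:-1])
        )
    return flags


def _runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    edges = np.flatnonzero(np.diff(np.r_[False, row, False].astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def accumulate_bursts(
    flags: np.ndarray,
    power: np.ndarray,
    centers: np.ndarray,
    sampling_rate: float,
    target_band: tuple[float, float],
    min_duration_ms: float = 70.0,
    band_union: bool = False,
) -> list[BurstEvent]:
    """Turn contiguous flag runs into burst events, sorted by onset.

    Per-channel gating (default) requires a run to persist at one single
    frequency.  With ``band_union=True`` a run of the OR of all target-band
    flags counts instead, so a burst drifting between adjacent in-band
    channels can still reach the minimum duration; its frequency is the
    peak-power channel.
    """
    lo, hi = target_band
    if lo > hi:
        raise ValueError("empty target band")
    centers = np.asarray(centers, dtype=float)
    in_band = (centers >= lo) & (centers <= hi)
    if band_union and not in_band.any():
        raise ValueError("target band contains no filter centre")
    events: list[BurstEvent] = []

    def make(run: tuple[int, int], row: int | None) -> BurstEvent:
        start, stop = run
        dur_ms = (stop - start) / sampling_rate * 1000.0
        if row is None:  # band-union: frequency of the strongest in-band sample
            seg = power[np.ix_(np.flatnonzero(in_band), np.arange(start, stop))]
            r, c = np.unravel_index(np.argmax(seg), seg.shape)
            freq = centers[np.flatnonzero(in_band)[r]]
            peak = float(seg.max())
            peak_at = start + int(c)
            eligible = dur_ms >= min_duration_ms
        else:
            freq = centers[row]
            seg = power[row, start:stop]
            peak = float(seg.max())
            peak_at = start + int(np.argmax(seg))
            eligible = bool(in_band[row]) and dur_ms >= min_duration_ms
        return BurstEvent(
            frequency=float(freq),
            onset_sample=int(start),
            duration_ms=dur_ms,
            peak_power=peak,
            peak_sample=peak_at,
            rewarded=eligible,
        )

    if band_union:
        union = flags[in_band].any(axis=0)
        events = [make(run, None) for run in _runs(union)]
        # out-of-band channels still produce (ineligible) per-channel events
        for row in np.flatnonzero(~in_band):
            events.extend(make(run, row) for run in _runs(flags[row]))
    else:
        for row in range(flags.shape[0]):
            events.extend(make(run, row) for run in _runs(flags[row]))
    events.sort(key=lambda e: (e.onset_sample, e.frequency))
    return events


def reward_controller(
    events: list[BurstEvent],
    artifacts: ArtifactMask | None,
    session_length: float,
    sampling_rate: float,
    min_duration_ms: float = 70.0,
    latency_s: float = 0.002,
    volume_ul: float = 50.0,
    delivery_rate_ul_s: float = 50.0,
    lockout_s: float = 1.0,
    n_priming: int = 5,
    priming_interval_s: float = 3.0,
) -> list[RewardEvent]:
    """Emit priming and burst-contingent rewards under the lockout rules.

    The reward decision for an eligible burst falls when it has lasted the
    minimum duration, plus the processing latency.  No reward during
    delivery, within ``lockout_s`` after any reward, within the first
    priming period, or inside an artifact-dilated span.
    """
    if lockout_s < 0 or latency_s < 0 or delivery_rate_ul_s <= 0:
        raise ValueError("negative lockout/latency or non-positive delivery rate")
    onsets = [e.onset_sample for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("events must be sorted by onset")
    delivery_s = volume_ul / delivery_rate_ul_s
    rewards: list[RewardEvent] = []
    lockout_until = 0.0
    for k in range(n_priming):
        t = k * priming_interval_s
        if t >= session_length:
            break
        rewards.append(
            RewardEvent(time=t, volume=volume_ul, lockout_until=t + delivery_s + lockout_s)
        )
        lockout_until = t + delivery_s + lockout_s
    flags = artifacts.flags if artifacts is not None else None
    for ev in events:
        if not ev.rewarded:
            continue
        decide = ev.onset_sample / sampling_rate + min_duration_ms / 1000.0 + latency_s
        if decide >= session_length or decide < lockout_until:
            continue
        if flags is not None:
            i = int(decide * sampling_rate)
            if 0 <= i < len(flags) and flags[i]:
                continue
        rewards.append(
            RewardEvent(
                time=decide,
                volume=volume_ul,
                lockout_until=decide + delivery_s + lockout_s,
            )
        )
        lockout_until = decide + delivery_s + lockout_s
    return rewards


def replay_schedule(
    schedule: list[float], volume_ul: float = 50.0, delivery_rate_ul_s: float = 50.0,
    lockout_s: float = 1.0,
) -> list[RewardEvent]:
    """Sham mode: reproduce a recorded reward schedule exactly.

    The subject's own activity is ignored; rewards land at precisely the
    recorded times.
    """
    delivery_s = volume_ul / delivery_rate_ul_s
    return [
        RewardEvent(time=float(t), volume=volume_ul,
                    lockout_until=float(t) + delivery_s + lockout_s)
        for t in schedule
    ]
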