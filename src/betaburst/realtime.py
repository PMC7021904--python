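"""Causal streaming core of the burst detector.

Emulates, offline but strictly causally, what the DSP does per frequency
channel: FIR filtering of the raw trace, three-sample turning-point
(peak/trough) detection on the filtered signal, latching of the squared
extremum amplitude as the running power estimate (half-period time
resolution), and sawtooth phase estimation with group-delay compensation.

All channel outputs stay on the raw sample clock; nothing is resampled.
Chunked streaming through :class:`StreamingFilterBank` is bit-for-bit
identical to whole-signal filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from .filters import FilterBank

__all__ = [
    "SampleStream",
    "ExtremumEvent",
    "TurningPoints",
    "PowerTrack",
    "PhaseTrack",
    "StreamingFilterBank",
    "stream_filter",
    "detect_turning_points",
    "latch_power",
    "estimate_phase",
    "power_matrix",
    "phase_reset_delay",
]

PEAK = 1
TROUGH = -1


@dataclass(frozen=True)
class SampleStream:
    """Uniformly sampled single-channel trace in microvolts."""

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("stream contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate


class ExtremumEvent(NamedTuple):
    sample_index: int  # first sample at which the extremal value is attained
    kind: int  # PEAK (+1) or TROUGH (-1)
    amplitude: float  # filtered-domain amplitude at the extremum
    detect_index: int  # causal emission sample (>= sample_index + 1)


@dataclass(frozen=True)
class TurningPoints:
    """Vectorised container of alternating peak/trough events."""

    index: np.ndarray  # extremum sample indices (plateau -> first sample)
    kind: np.ndarray  # +1 peak / -1 trough, strictly alternating
    amplitude: np.ndarray
    detect_index: np.ndarray  # sample at which the extremum is confirmed

    def __len__(self) -> int:
        return len(self.index)

    def __iter__(self) -> Iterator[ExtremumEvent]:
        for i in range(len(self.index)):
            yield ExtremumEvent(
                int(self.index[i]),
                int(self.kind[i]),
                float(self.amplitude[i]),
                int(self.detect_index[i]),
            )


class StreamingFilterBank:
    """Causal FIR filtering with persistent state, bit-for-bit chunk-safe.

    The last ``order`` input samples are carried across calls and each
    output sample is one ordered dot product with the taps, so feeding the
    signal in chunks of any size reproduces the whole-signal result
    exactly (recursive filter state updates do not have this property in
    floating point).
    """

    def __init__(self, bank: FilterBank):
        self.bank = bank
        self._b = bank.coefficient_matrix()
        self._tail = np.zeros(bank.order)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        """Filter one chunk; returns (n_filters, len(chunk))."""
        chunk = np.asarray(chunk, dtype=float)
        order = self._b.shape[1] - 1
        buf = np.concatenate([self._tail, chunk])
        out = np.empty((self._b.shape[0], chunk.size))
        for i in range(self._b.shape[0]):
            out[i] = np.convolve(buf, self._b[i])[order : order + chunk.size]
        self._tail = buf[-order:].copy()
        return out


def stream_filter(
    bank: FilterBank, stream: SampleStream, chunk_size: int | None = None
) -> np.ndarray:
    """Causally filter a stream through every channel of the bank.

    Returns an (n_filters, n_samples) array on the raw sample clock; row i
    corresponds to ``bank.centers[i]`` and lags the input by the shared
    group delay of N/2 samples.
    """
    if len(stream) <= bank.order:
        raise ValueError(
            f"stream of {len(stream)} samples is shorter than the filter "
            f"order {bank.order}"
        )
    sfb = StreamingFilterBank(bank)
    x = stream.values
    if chunk_size is None:
        return sfb.process(x)
    parts = [sfb.process(x[i : i + chunk_size]) for i in range(0, len(x), chunk_size)]
    return np.concatenate(parts, axis=1)


def detect_turning_points(filtered: np.ndarray) -> TurningPoints:
    """Detect alternating local maxima/minima in a filtered channel.

    A sample is an extremum when its neighbours on both sides (skipping
    plateaus) are lower (peak) or higher (trough); on a plateau the first
    sample is the extremum.  Detection is causal: the event's
    ``detect_index`` is the sample at which the reversal is first
    observable, one sample after the extremum for a non-plateau.
    """
    x = np.asarray(filtered, dtype=float)
    empty = TurningPoints(
        np.empty(0, int), np.empty(0, int), np.empty(0, float), np.empty(0, int)
    )
    if x.size < 3:
        return empty
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return empty  # monotone or constant
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[:-1] != s[1:])  # sign reversal between runs
    if turn.size == 0:
        return empty
    # extremal value first attained one sample after the last diff of the
    # previous run; reversal observable one sample after the next nonzero diff
    idx = nz[turn] + 1
    detect = nz[turn + 1] + 1
    kind = np.where(s[turn] > 0, PEAK, TROUGH).astype(int)
    return TurningPoints(
        index=idx, kind=kind, amplitude=x[idx], detect_index=detect
    )


@dataclass(frozen=True)
class PowerTrack:
    """Stepwise-constant power estimate of one frequency channel (uV^2)."""

    frequency: float
    values: np.ndarray
    update_indices: np.ndarray = field(repr=False)


def latch_power(
    extrema: TurningPoints, length: int, frequency: float = float("nan")
) -> PowerTrack:
    """Hold the squared amplitude of the last detected extremum.

    The track is 0 before the first detection; from each extremum's
    ``detect_index`` the squared extremal amplitude is held until the next
    detection, giving half-period time resolution on an oscillation.
    """
    det = np.asarray(extrema.detect_index, dtype=int)
    if det.size and np.any(np.diff(det) < 0):
        raise ValueError("extrema must be sorted by detection index")
    values = np.zeros(length)
    if det.size:
        power = np.asarray(extrema.amplitude, dtype=float) ** 2
        keep = det < length
        det, power = det[keep], power[keep]
        if det.size:
            bounds = np.append(det, length)
            reps = np.diff(bounds)
            values[det[0] :] = np.repeat(power, reps)
    return PowerTrack(frequency=frequency, values=values, update_indices=det)


def phase_reset_delay(frequency: float, group_delay_s: float) -> float:
    """delta(f) = ceil(d/T) * T - d: time from a detected extremum to the
    next same-kind extremum of the *input* signal, compensating the filter
    group delay d for a channel of period T = 1/f."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    T = 1.0 / frequency
    return float(np.ceil(group_delay_s / T) * T - group_delay_s)


@dataclass(frozen=True)
class PhaseTrack:
    """Sawtooth phase estimate in [0, 2*pi) for one channel."""

    frequency: float
    values: np.ndarray
    reset_delay: float


def estimate_phase(
    extrema: TurningPoints,
    frequency: float,
    group_delay_s: float,
    length: int,
    sampling_rate: float,
) -> PhaseTrack:
    """Sawtooth phase synced to detected extrema with delayed resets.

    The phase ramps at slope 2*pi*f and is reset to 0 (after a peak) or pi
    (after a trough) delta(f) seconds after the extremum, so that the reset
    lands on the next assumed extremum of the undelayed input signal.
    """
    delta = phase_reset_delay(frequency, group_delay_s)
    t = np.arange(length) / sampling_rate
    phase = 2.0 * np.pi * frequency * t  # free-running before the first reset
    reset_times = np.asarray(extrema.index) / sampling_rate + delta
    reset_phase = np.where(np.asarray(extrema.kind) == PEAK, 0.0, np.pi)
    start = np.searchsorted(t, reset_times)
    for k in range(len(start)):
        s = start[k]
        if s >= length:
            break
        stop = start[k + 1] if k + 1 < len(start) else length
        phase[s:stop] = reset_phase[k] + 2.0 * np.pi * frequency * (
            t[s:stop] - reset_times[k]
        )
    return PhaseTrack(
        frequency=frequency, values=np.mod(phase, 2.0 * np.pi), reset_delay=delta
    )


def power_matrix(bank: FilterBank, stream: SampleStream) -> np.ndarray:
    """Latched power of every channel: (n_filters, n_samples) in uV^2.

    Convenience wrapper chaining :func:`stream_filter`,
    :func:`detect_turning_points` and :func:`latch_power` over the bank.
    """
    filtered = stream_filter(bank, stream)
    n = filtered.shape[1]
    out = np.empty_like(filtered)
    for i, fc in enumerate(bank.centers):
        tp = detect_turning_points(filtered[i])
        out[i] = latch_power(tp, n, frequency=fc).values
    return out
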