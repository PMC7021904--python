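"""Online artifact rejection and the dynamic percentile threshold.

High-amplitude LFP deflections (teeth grinding, headstage contact) have
broadband power and would otherwise dominate the power distribution.  The
raw trace is bandpassed 2-250 Hz (2nd-order Butterworth, 12 dB/octave) and
samples exceeding an amplitude threshold (default 500 uV) are flagged
together with everything within +-0.5 s.

The per-frequency burst threshold is the 98th percentile of the most
recent 15 s of artifact-free latched power, recomputed once per second.
Masked stretches are back-filled with the latest earlier artifact-free
values, so the percentile always rests on a full window of clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .realtime import SampleStream

__all__ = [
    "ArtifactMask",
    "ThresholdState",
    "detect_artifacts",
    "update_threshold",
    "dynamic_thresholds",
]


@dataclass(frozen=True)
class ArtifactMask:
    """Per-sample rejection flags (True = rejected)."""

    flags: np.ndarray
    threshold: float
    pad: float
    sampling_rate: float

    @property
    def fraction(self) -> float:
        return float(np.mean(self.flags)) if len(self.flags) else 0.0

    def to_intervals(self) -> list[tuple[float, float]]:
        """Rejected spans as half-open [start_s, end_s) intervals."""
        f = np.asarray(self.flags, dtype=bool)
        edges = np.flatnonzero(np.diff(np.r_[False, f, False].astype(int)))
        starts, ends = edges[::2], edges[1::2]
        return [
            (s / self.sampling_rate, e / self.sampling_rate)
            for s, e in zip(starts, ends)
        ]


def detect_artifacts(
    raw: SampleStream, threshold: float = 500.0, pad: float = 0.5
) -> ArtifactMask:
    """Flag supra-threshold deflections of the 2-250 Hz bandpassed trace.

    A 2nd-order Butterworth bandpass (12 dB/octave per edge) removes spike
    energy above 250 Hz and sensor drift below 2 Hz before the amplitude
    test, then every flagged sample is dilated by +-``pad`` seconds.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    fs = raw.sampling_rate
    if fs <= 500.0:
        raise ValueError("sampling rate must exceed 500 Hz for the 250 Hz edge")
    sos = butter(2, [2.0, 250.0], btype="bandpass", fs=fs, output="sos")
    y = sosfilt(sos, raw.values)
    hits = np.abs(y) > threshold
    flags = _dilate(hits, int(round(pad * fs)))
    return ArtifactMask(flags=flags, threshold=threshold, pad=pad, sampling_rate=fs)


def _dilate(flags: np.ndarray, pad_samples: int) -> np.ndarray:
    if pad_samples <= 0 or not flags.any():
        return flags.copy()
    idx = np.flatnonzero(flags)
    out = np.zeros_like(flags)
    starts = np.maximum(idx - pad_samples, 0)
    ends = np.minimum(idx + pad_samples + 1, len(flags))
    # merge per-hit intervals via difference array
    diff = np.zeros(len(flags) + 1, dtype=int)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    out = np.cumsum(diff[:-1]) > 0
    return out


@dataclass
class ThresholdState:
    """Sliding artifact-free power history and the percentile thresholds.

    ``history`` is a per-frequency FIFO holding the last ``window``
    seconds' worth of artifact-free power samples; appending skips masked
    samples, which is exactly the back-fill rule: rejected spans leave the
    older clean values in place.
    """

    n_freqs: int
    sampling_rate: float
    percentile: float = 98.0
    window: float = 15.0
    update_interval: float = 1.0
    history: np.ndarray = field(init=False, repr=False)
    _filled: int = field(default=0, init=False)
    _pos: int = field(default=0, init=False)
    _since_update: int = field(default=0, init=False)
    threshold: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window <= 0 or self.update_interval <= 0:
            raise ValueError("window and update_interval must be positive")
        self.capacity = int(round(self.window * self.sampling_rate))
        self.history = np.zeros((self.n_freqs, self.capacity))
        self.threshold = np.full(self.n_freqs, np.nan)

    @property
    def ready(self) -> bool:
        """True once a full artifact-free window has been accumulated."""
        return self._filled >= self.capacity and np.all(np.isfinite(self.threshold))

    def _append(self, block: np.ndarray) -> None:
        n = block.shape[1]
        if n >= self.capacity:
            self.history[:] = block[:, -self.capacity :]
            self._pos = 0
            self._filled = self.capacity
            return
        end = self._pos + n
        if end <= self.capacity:
            self.history[:, self._pos : end] = block
        else:
            k = self.capacity - self._pos
            self.history[:, self._pos :] = block[:, :k]
            self.history[:, : end - self.capacity] = block[:, k:]
        self._pos = end % self.capacity
        self._filled = min(self._filled + n, self.capacity)

    def _recompute(self) -> None:
        if self._filled < self.capacity:
            self.threshold = np.full(self.n_freqs, np.nan)  # not ready
        else:
            self.threshold = np.percentile(
                self.history, self.percentile, axis=1, method="linear"
            )


def update_threshold(
    state: ThresholdState, new_power: np.ndarray, mask: np.ndarray | None = None
) -> ThresholdState:
    """Feed a block of per-frequency power into the threshold state.

    ``new_power`` is (n_freqs, n_samples); ``mask`` marks samples to
    exclude (artifacts).  The percentile is recomputed once per
    ``update_interval`` of wall-clock samples fed in (masked or not), as
    the online routine runs on a timer, not on the clean-data count.
    """
    new_power = np.atleast_2d(np.asarray(new_power, dtype=float))
    if new_power.shape[0] != state.n_freqs:
        raise ValueError("power block has wrong number of frequency rows")
    if mask is None:
        mask = np.zeros(new_power.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    step = int(round(state.update_interval * state.sampling_rate))
    n = new_power.shape[1]
    done = 0
    while done < n:
        take = min(step - state._since_update, n - done)
        blk = new_power[:, done : done + take]
        m = mask[done : done + take]
        if not m.all():
            state._append(blk[:, ~m])
        state._since_update += take
        done += take
        if state._since_update >= step:
            state._recompute()
            state._since_update = 0
    return state


def dynamic_thresholds(
    power: np.ndarray,
    mask: np.ndarray | None,
    sampling_rate: float,
    percentile: float = 98.0,
    window: float = 15.0,
    update_interval: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Emulate the once-per-second dynamic threshold over a whole session.

    Returns ``(per_sample, per_update)``: the per-sample threshold track
    (n_freqs, n_samples; NaN while not ready, each update taking effect
    from the following sample) and the per-update threshold matrix
    (n_freqs, n_updates).
    """
    power = np.atleast_2d(np.asarray(power, dtype=float))
    n_freqs, n = power.shape
    state = ThresholdState(
        n_freqs=n_freqs,
        sampling_rate=sampling_rate,
        percentile=percentile,
        window=window,
        update_interval=update_interval,
    )
    step = int(round(update_interval * sampling_rate))
    per_sample = np.full((n_freqs, n), np.nan)
    per_update = []
    for start in range(0, n, step):
        stop = min(start + step, n)
        update_threshold(
            state,
            power[:, start:stop],
            None if mask is None else mask[start:stop],
        )
        if stop - start == step:  # a full interval elapsed -> fresh threshold
            per_update.append(state.threshold.copy())
            if stop < n:
                per_sample[:, stop : min(stop + step, n)] = state.threshold[:, None]
    per_update_arr = (
        np.stack(per_update, axis=1) if per_update else np.empty((n_freqs, 0))
    )
    return per_sample, per_update_arr
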