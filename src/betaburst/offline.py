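"""Offline burst characterization and session-level power statistics.

Offline, bursts are defined on the wavelet time-frequency representation
(TFR): strict local maxima in the time-frequency plane exceeding the
per-frequency 98th power percentile of the session.  Each burst is
described by its peak frequency, frequency span, duration, inter-burst
interval and peak power as a fraction of the session median (FOM).

Session-level statistics:

* beta power change -- the session mean power of each targeted frequency,
  normalised to session 1, averaged over the n targeted frequencies and
  expressed in percent (session 1 is 0 by construction);
* training effect -- the difference-of-differences
  (P9_pre - P9_post) - (P1_pre - P1_post) of mean power around reward
  between the last and first session, per frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import butter, fftconvolve, sosfiltfilt
from scipy.stats import t as t_dist

from .realtime import SampleStream

__all__ = [
    "TFR",
    "morlet_tfr",
    "offline_burst_detect",
    "time_locked_average",
    "beta_power_change",
    "training_effect",
]


@dataclass(frozen=True)
class TFR:
    """Time-frequency power on the sample clock.

    ``power`` has shape (n_freqs, n_times); ``times`` is in seconds at the
    source sampling rate (~1 ms steps for ~1 kHz data).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    method: str
    normalization: str = "none"

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


def _morlet_kernel(freq: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, scaled so a unit-amplitude sinusoid at
    ``freq`` yields power 1."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = env * np.exp(2j * np.pi * freq * t)
    return kernel * (2.0 / env.sum())


def morlet_tfr(
    stream: SampleStream, cycles: float = 7.0, freqs=None
) -> TFR:
    """Morlet-wavelet TFR (power) of a single-channel trace.

    ``cycles`` sets the wavelet width (sigma_t = cycles / (2*pi*f)); seven
    cycles is the conventional offline setting, three cycles the
    short-delay online-equivalent one.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if freqs is None:
        freqs = np.arange(12.0, 33.0)
    freqs = np.asarray(freqs, dtype=float)
    fs = stream.sampling_rate
    if freqs.max() >= fs / 2.0:
        raise ValueError("requested frequency above Nyquist")
    power = np.empty((len(freqs), len(stream)))
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, cycles, fs)
        power[i] = np.abs(fftconvolve(stream.values, kern, mode="same")) ** 2
    return TFR(
        power=power,
        freqs=freqs,
        times=stream.times,
        method=f"morlet-{cycles:g}",
    )


def offline_burst_detect(tfr: TFR, percentile: float = 98.0) -> pd.DataFrame:
    """Detect bursts as supra-percentile local maxima of the TFR.

    A burst is a strict 8-neighbourhood local maximum of the power plane
    exceeding the per-frequency session percentile (plateaus contribute
    their earliest-time, lowest-frequency point).  Per burst:

    * ``peak_frequency`` (Hz) and ``peak_time`` (s);
    * ``span``: contiguous supra-threshold frequency extent (Hz) at peak time;
    * ``duration_ms``: contiguous supra-threshold time extent at peak frequency;
    * ``ibi_ms``: peak-time difference to the previous burst (NaN for the first);
    * ``power_fom``: peak power over the per-frequency session median.
    """
    if tfr.normalization != "none":
        raise ValueError("burst detection requires an un-normalised TFR")
    P = tfr.power
    thr = np.percentile(P, percentile, axis=1)
    med = np.median(P, axis=1)
    supra = P > thr[:, None]
    # strict local maxima with deterministic plateau tie-break: a point
    # survives if no neighbour is larger and no earlier plateau member exists
    maxfilt = ndimage.maximum_filter(P, size=3, mode="constant", cval=-np.inf)
    candidates = (P >= maxfilt) & supra
    labels, nlab = ndimage.label(candidates)
    rows = []
    dt_ms = 1000.0 / tfr.sampling_rate
    for lab in range(1, nlab + 1):
        fi_all, ti_all = np.nonzero(labels == lab)
        k = np.lexsort((fi_all, ti_all))[0]  # earliest time, then lowest freq
        fi, ti = int(fi_all[k]), int(ti_all[k])
        col = supra[:, ti]
        lo = fi
        while lo > 0 and col[lo - 1]:
            lo -= 1
        hi = fi
        while hi < len(col) - 1 and col[hi + 1]:
            hi += 1
        span = tfr.freqs[hi] - tfr.freqs[lo]
        row = supra[fi]
        t0 = ti
        while t0 > 0 and row[t0 - 1]:
            t0 -= 1
        t1 = ti
        while t1 < len(row) - 1 and row[t1 + 1]:
            t1 += 1
        rows.append(
            {
                "peak_frequency": tfr.freqs[fi],
                "peak_time": tfr.times[ti],
                "span": span,
                "duration_ms": (t1 - t0 + 1) * dt_ms,
                "power_fom": P[fi, ti] / med[fi] if med[fi] > 0 else np.inf,
                "peak_power": P[fi, ti],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "peak_frequency", "peak_time", "span", "duration_ms",
            "power_fom", "peak_power",
        ],
    ).sort_values("peak_time", ignore_index=True)
    out["ibi_ms"] = out["peak_time"].diff() * 1000.0
    return out


def time_locked_average(
    raw: SampleStream,
    event_times,
    window: float = 0.25,
    band: tuple[float, float] = (15.0, 30.0),
    align_to_trough: bool = True,
    max_lookback: float = 0.3,
    confidence: float = 0.95,
) -> dict:
    """Average raw-signal windows aligned to the last pre-event beta trough.

    For each event time the trace is bandpassed (zero-phase Butterworth,
    ``band``), the last local minimum of the filtered trace within
    ``max_lookback`` s before the event is found, and a ``window``-second
    raw-signal window centred there is extracted.  Averaging phase-aligned
    windows of heterogeneous bursts produces the deceptive appearance of a
    sustained oscillation; with ``align_to_trough=False`` windows are
    centred on the event times themselves (incoherent averaging control).

    Returns dict with ``times``, ``mean``, ``ci_low``, ``ci_high``,
    ``n_used``, ``skipped``.
    """
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        raise ValueError("need at least one event")
    fs = raw.sampling_rate
    half = int(round(window / 2.0 * fs))
    x = raw.values
    if align_to_trough:
        sos = butter(2, band, btype="bandpass", fs=fs, output="sos")
        filt = sosfiltfilt(sos, x)
    segments, skipped = [], 0
    for te in event_times:
        i_ev = int(round((te - raw.start_time) * fs))
        if align_to_trough:
            i_lo = max(i_ev - int(round(max_lookback * fs)), 1)
            seg = filt[i_lo:i_ev]
            minima = np.flatnonzero(
                (seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:])
            )
            if minima.size == 0:
                skipped += 1  # no preceding trough in range
                continue
            center = i_lo + 1 + minima[-1]
        else:
            center = i_ev
        if center - half < 0 or center + half + 1 > len(x):
            skipped += 1
            continue
        segments.append(x[center - half : center + half + 1])
    if not segments:
        raise ValueError("no usable events (all skipped)")
    seg = np.stack(segments)
    mean = seg.mean(axis=0)
    n = seg.shape[0]
    if n > 1:
        sem = seg.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = t_dist.ppf(0.5 + confidence / 2.0, df=n - 1)
    else:
        sem, tcrit = np.zeros_like(mean), 0.0
    times = (np.arange(-half, half + 1)) / fs
    return {
        "times": times,
        "mean": mean,
        "ci_low": mean - tcrit * sem,
        "ci_high": mean + tcrit * sem,
        "n_used": n,
        "skipped": skipped,
    }


def beta_power_change(sessions: list[np.ndarray]) -> np.ndarray:
    """Per-session percent change of mean targeted-band power vs session 1.

    Each element of ``sessions`` is an (n_target_freqs, T_s) power array
    with artifact epochs already excluded (sessions may differ in T_s).
    For session s the time-mean power of each targeted frequency is
    divided by its session-1 counterpart; the ratios are averaged over
    frequencies and mapped to percent (x100 - 100).  Session 1 is 0.
    """
    if not sessions:
        raise ValueError("need at least one session")
    means = [np.atleast_2d(np.asarray(s, dtype=float)).mean(axis=1) for s in sessions]
    ref = means[0]
    if np.any(ref <= 0):
        raise ValueError("session 1 has non-positive mean power at a target frequency")
    if any(len(m) != len(ref) for m in means):
        raise ValueError("sessions disagree on the number of target frequencies")
    return np.array([float(np.mean(m / ref)) * 100.0 - 100.0 for m in means])


def training_effect(
    p1_pre: np.ndarray,
    p1_post: np.ndarray,
    p9_pre: np.ndarray,
    p9_post: np.ndarray,
) -> np.ndarray:
    """(P9_pre - P9_post) - (P1_pre - P1_post), elementwise per frequency.

    ``pre``/``post`` are mean TFR power over the 200 ms before/after
    reward; a positive value marks frequencies whose pre-reward power gain
    grew with training.
    """
    arrs = [np.asarray(a, dtype=float) for a in (p1_pre, p1_post, p9_pre, p9_post)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("frequency axes of the four means do not match")
    p1_pre, p1_post, p9_pre, p9_post = arrs
    return (p9_pre - p9_post) - (p1_pre - p1_post)
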