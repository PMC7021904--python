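"""Recording I/O, run configuration, and the end-to-end session emulator.

``run_session`` chains the whole pipeline offline but causally: filter
bank -> extrema latching -> artifact mask -> dynamic percentile
thresholds -> neighbour-frequency burst rule -> reward controller (or
sham replay).  Given the same configuration and input, its outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .artifacts import detect_artifacts, dynamic_thresholds
from .bursts import accumulate_bursts, burst_flag, replay_schedule, reward_controller
from .filters import build_bank
from .realtime import SampleStream, power_matrix

logger = logging.getLogger("betaburst")

__all__ = ["RunConfig", "load_recording", "save_trace_csv", "run_session"]

CSV_HEADER = ("time_s", "amplitude_uv")


@dataclass
class RunConfig:
    """Session parameters (all durations in the units of the field name)."""

    sampling_rate: float = 976.5625
    band_low: float = 20.0
    band_high: float = 25.0
    percentile: float = 98.0
    window_s: float = 15.0
    update_s: float = 1.0
    min_duration_ms: float = 70.0
    artifact_uv: float = 500.0
    artifact_pad_s: float = 0.5
    latency_ms: float = 2.0
    volume_ul: float = 50.0
    delivery_rate_ul_s: float = 50.0
    lockout_s: float = 1.0
    band_union: bool = False
    seed: int = 0
    mode: str = "train"  # train | sham
    sham_schedule: list[float] | None = None

    def __post_init__(self) -> None:
        for name in ("window_s", "update_s", "min_duration_ms", "artifact_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.latency_ms < 0 or self.artifact_pad_s < 0:
            raise ValueError("latency and artifact pad must be non-negative")
        if not (2.0 <= self.band_low <= self.band_high <= 31.0):
            raise ValueError(
                "target band must lie within 2-31 Hz (both neighbours needed)"
            )
        if self.mode not in ("train", "sham"):
            raise ValueError("mode must be 'train' or 'sham'")
        if self.mode == "sham" and self.sham_schedule is None:
            raise ValueError("sham mode requires a recorded reward schedule")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def load_recording(path, format: str | None = None) -> SampleStream:
    """Read a single-channel recording (microvolts) from CSV or EDF.

    CSV: two columns ``time_s,amplitude_uv`` with uniform sampling (the
    rate is inferred from the time column; >1% jitter is rejected naming
    the first bad row).  EDF: first channel, rate from the header, values
    converted to microvolts.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != list(CSV_HEADER):
            raise ValueError(
                f"CSV must start with columns {CSV_HEADER}, got {list(df.columns)}"
            )
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("CSV holds fewer than two samples")
        dt = np.diff(t)
        med = float(np.median(dt))
        bad = np.flatnonzero(np.abs(dt - med) > 0.01 * med)
        if bad.size:
            raise ValueError(
                f"irregular sampling: row {bad[0] + 2} steps {dt[bad[0]]:.6g} s "
                f"vs median {med:.6g} s"
            )
        return SampleStream(
            values=df["amplitude_uv"].to_numpy(dtype=float),
            sampling_rate=1.0 / med,
            start_time=float(t[0]),
        )
    if format == "edf":
        try:
            import mne
        except ImportError as err:  # pragma: no cover
            raise ImportError("EDF support requires the 'mne' package") from err
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data(picks=[0])[0] * 1e6  # volts -> microvolts
        return SampleStream(values=data, sampling_rate=float(raw.info["sfreq"]))
    raise ValueError(f"unknown recording format {format!r} (expected csv or edf)")


def save_trace_csv(stream: SampleStream, path) -> None:
    """Write a stream as ``time_s,amplitude_uv`` (times to 6 decimals)."""
    df = pd.DataFrame(
        {"time_s": stream.times, "amplitude_uv": stream.values}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def run_session(
    config: RunConfig, stream: SampleStream, outdir=None
) -> dict:
    """Emulate one closed-loop session on a recorded or synthetic stream.

    Returns a JSON-serialisable report and, when ``outdir`` is given,
    writes ``events.tsv`` (onset_s, frequency_hz, duration_ms, peak_power,
    rewarded), ``rewards.tsv`` (time_s, volume_ul), ``thresholds.tsv``
    (time_s, frequency_hz, threshold) and ``report.json``.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    fs = stream.sampling_rate
    bank = build_bank(sampling_rate=fs)
    if not (bank.centers[0] < config.band_low and config.band_high < bank.centers[-1]):
        raise ValueError("target band outside the filter-bank range")
    logger.info("session start: %d samples at %.4f Hz", len(stream), fs)
    P = power_matrix(bank, stream)
    mask = detect_artifacts(stream, config.artifact_uv, config.artifact_pad_s)
    thr_track, thr_updates = dynamic_thresholds(
        P, mask.flags, fs,
        percentile=config.percentile,
        window=config.window_s,
        update_interval=config.update_s,
    )
    flags = burst_flag(P, thr_track, bank.centers)
    events = accumulate_bursts(
        flags, P, bank.centers, fs,
        target_band=(config.band_low, config.band_high),
        min_duration_ms=config.min_duration_ms,
        band_union=config.band_union,
    )
    session_length = stream.duration
    if config.mode == "sham":
        rewards = replay_schedule(
            config.sham_schedule, config.volume_ul, config.delivery_rate_ul_s,
            config.lockout_s,
        )
    else:
        rewards = reward_controller(
            events, mask, session_length, fs,
            min_duration_ms=config.min_duration_ms,
            latency_s=config.latency_ms / 1000.0,
            volume_ul=config.volume_ul,
            delivery_rate_ul_s=config.delivery_rate_ul_s,
            lockout_s=config.lockout_s,
        )
    band_rows = (bank.centers >= config.band_low) & (bank.centers <= config.band_high)
    clean = ~mask.flags
    mean_band_power = (
        float(P[np.ix_(band_rows, np.flatnonzero(clean))].mean())
        if clean.any()
        else float("nan")
    )
    report = {
        "n_samples": len(stream),
        "sampling_rate": fs,
        "n_bursts": len(events),
        "n_eligible_bursts": int(sum(e.rewarded for e in events)),
        "n_rewards": len(rewards),
        "rejected_fraction": mask.fraction,
        "mean_band_power_uv2": mean_band_power,
        "mode": config.mode,
        "band": [config.band_low, config.band_high],
    }
    events_df = pd.DataFrame(
        [
            {
                "onset_s": e.onset_sample / fs,
                "frequency_hz": e.frequency,
                "duration_ms": e.duration_ms,
                "peak_power": e.peak_power,
                "rewarded": int(e.rewarded),
            }
            for e in events
        ],
        columns=["onset_s", "frequency_hz", "duration_ms", "peak_power", "rewarded"],
    )
    rewards_df = pd.DataFrame(
        [{"time_s": r.time, "volume_ul": r.volume} for r in rewards],
        columns=["time_s", "volume_ul"],
    )
    step = int(round(config.update_s * fs))
    thr_rows = []
    for k in range(thr_updates.shape[1]):
        t_upd = (k + 1) * step / fs
        for i, fc in enumerate(bank.centers):
            thr_rows.append(
                {"time_s": t_upd, "frequency_hz": fc, "threshold": thr_updates[i, k]}
            )
    thr_df = pd.DataFrame(thr_rows, columns=["time_s", "frequency_hz", "threshold"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        events_df.to_csv(outdir / "events.tsv", sep="\t", index=False,
                         float_format="%.6f")
        rewards_df.to_csv(outdir / "rewards.tsv", sep="\t", index=False,
                          float_format="%.6f")
        thr_df.to_csv(outdir / "thresholds.tsv", sep="\t", index=False,
                      float_format="%.6f")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["events"] = events_df
    report["rewards"] = rewards_df
    report["thresholds"] = thr_df
    return report


def export_power_text(path, power: np.ndarray, centers: np.ndarray,
                      sampling_rate: float) -> None:
    """Write a per-frequency power matrix as delimited text (one row per
    frequency, first column the centre in Hz)."""
    mat = np.column_stack([np.asarray(centers, dtype=float), power])
    np.savetxt(path, mat, header=f"sampling_rate={sampling_rate}")


def export_power_hdf5(path, power: np.ndarray, centers: np.ndarray,
                      sampling_rate: float) -> None:
    """Write a per-frequency power matrix to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("power", data=power, compression="gzip")
        ds.attrs["sampling_rate"] = sampling_rate
        fh.create_dataset("frequencies", data=np.asarray(centers, dtype=float))
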