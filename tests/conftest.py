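"""Shared fixtures: the default filter bank, tone generators, and a
minimal synthetic EDF writer (test-only) for exercising the EDF reader."""

from __future__ import annotations

import numpy as np
import pytest

from betaburst.filters import DEFAULT_FS, build_bank
from betaburst.realtime import SampleStream


@pytest.fixture(scope="session")
def bank():
    """The default 32-channel bank at Fs = 976.5625 Hz (built once)."""
    return build_bank()


@pytest.fixture(scope="session")
def spec20(bank):
    return bank.filters[19]  # centre 20 Hz


def tone(freq: float, duration: float = 5.0, amplitude: float = 1.0,
         fs: float = DEFAULT_FS, phase: float = 0.0) -> SampleStream:
    t = np.arange(int(round(duration * fs))) / fs
    return SampleStream(amplitude * np.sin(2.0 * np.pi * freq * t + phase), fs)


def write_minimal_edf(path, data: np.ndarray, samples_per_record: int = 1000,
                      record_duration: float = 1.024) -> None:
    """Write a tiny single-channel EDF file (synthetic test fixture only).

    Physical range +-1000 uV mapped onto the full 16-bit digital range;
    sampling rate = samples_per_record / record_duration.
    """
    n_rec = len(data) // samples_per_record
    hdr = b"0".ljust(8)
    hdr += b"X".ljust(80) + b"X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 + 256).encode().ljust(8)
    hdr += b" " * 44
    hdr += str(n_rec).encode().ljust(8)
    hdr += (f"{record_duration:g}").encode().ljust(8)
    hdr += b"1".ljust(4)
    hdr += b"LFP".ljust(16) + b"".ljust(80) + b"uV".ljust(8)
    hdr += b"-1000".ljust(8) + b"1000".ljust(8)
    hdr += b"-32768".ljust(8) + b"32767".ljust(8)
    hdr += b"".ljust(80) + str(samples_per_record).encode().ljust(8) + b" " * 32
    pmin, pmax = -1000.0, 1000.0
    dig = np.round(
        (data[: n_rec * samples_per_record] - pmin) / (pmax - pmin) * 65535 - 32768
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())
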