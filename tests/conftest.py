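"""Shared fixtures: small synthetic cohorts and a minimal EDF fixture writer."""

import struct

import numpy as np
import pytest

from msdyn.synthetic import SyntheticSpec, make_template_maps, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact noiseless-ish cohort used by several segmentation tests."""
    spec = SyntheticSpec(n_per_group=3, duration=20.0, snr=5.0, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def templates32():
    return make_template_maps(32, 5, seed=7)


def write_minimal_edf(path, data, fs):
    """Write a bare-bones 16-bit EDF file (one data record) for read-back tests.

    ``data`` is (n_channels, n_samples) in microvolt; all channels share ``fs``.
    Fixture generation only -- the package reads EDF through mne.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    header_bytes = 256 * (1 + n_ch)

    def pad(s, width):
        return s.encode("ascii").ljust(width)[:width]

    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    with open(path, "wb") as f:
        f.write(pad("0", 8))
        f.write(pad("X X X X", 80))
        f.write(pad("Startdate 01-JAN-2020 X X X", 80))
        f.write(pad("01.01.20", 8))
        f.write(pad("00.00.00", 8))
        f.write(pad(str(header_bytes), 8))
        f.write(pad("", 44))
        f.write(pad("1", 8))  # one data record
        f.write(pad(f"{n_samp / fs:g}", 8))  # record duration in seconds
        f.write(pad(str(n_ch), 4))
        for i in range(n_ch):
            f.write(pad(f"EEG ch{i}", 16))
        for _ in range(n_ch):
            f.write(pad("", 80))
        for _ in range(n_ch):
            f.write(pad("uV", 8))
        for _ in range(n_ch):
            f.write(pad(f"{phys_min:g}", 8))
        for _ in range(n_ch):
            f.write(pad(f"{phys_max:g}", 8))
        for _ in range(n_ch):
            f.write(pad(str(dig_min), 8))
        for _ in range(n_ch):
            f.write(pad(str(dig_max), 8))
        for _ in range(n_ch):
            f.write(pad("", 80))
        for _ in range(n_ch):
            f.write(pad(str(n_samp), 8))
        for _ in range(n_ch):
            f.write(pad("", 32))
        scale = (dig_max - dig_min) / (phys_max - phys_min)
        for i in range(n_ch):
            dig = np.round((data[i] - phys_min) * scale + dig_min).astype("<i2")
            f.write(struct.pack(f"<{n_samp}h", *dig))
    return path
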