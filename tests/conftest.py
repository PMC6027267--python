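"""Shared fixtures: compact synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from eegintent.synthetic_data import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A shortened protocol (8 trials) for fast unit tests."""
    return SyntheticConfig(n_trials=8)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    """The full 20-trial protocol."""
    return SyntheticConfig()


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg, "S1", seed=7, subject_index=0)


@pytest.fixture(scope="session")
def full_session(default_cfg):
    return generate_session(default_cfg, "S1", seed=1, subject_index=0)


def write_minimal_edf(path, data_uv: np.ndarray, labels, fs: float) -> None:
    """Write a synthetic, minimal EDF file (test utility).

    Supports exactly what the reader tests need: one data record per
    second, 16-bit samples, physical units in microvolts. Not a general
    EDF writer.
    """
    n_sig, n_samp = data_uv.shape
    spr = int(fs)
    n_rec = n_samp // spr
    data_uv = data_uv[:, : n_rec * spr]
    pmin, pmax = -3276.8, 3276.7
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_sig)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_sig), 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(pad(lb, 16) for lb in labels),
            b"".join(pad("AgAgCl electrode", 80) for _ in labels),
            b"".join(pad("uV", 8) for _ in labels),
            b"".join(pad(str(pmin), 8) for _ in labels),
            b"".join(pad(str(pmax), 8) for _ in labels),
            b"".join(pad(str(dmin), 8) for _ in labels),
            b"".join(pad(str(dmax), 8) for _ in labels),
            b"".join(pad("", 80) for _ in labels),
            b"".join(pad(str(spr), 8) for _ in labels),
            b"".join(pad("", 32) for _ in labels),
        ]
    )
    scale = (dmax - dmin) / (pmax - pmin)
    body = bytearray()
    for r in range(n_rec):
        for i in range(n_sig):
            chunk = data_uv[i, r * spr : (r + 1) * spr]
            dig = np.round((chunk - pmin) * scale + dmin).astype("<i2")
            body += dig.tobytes()
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr + bytes(body))
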