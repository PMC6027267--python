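"""EEG preprocessing: common average reference and FIR bandpass filtering.

The common average reference (CAR) removes the potential common to all
electrodes by subtracting, at every sample, the instantaneous mean over
channels:

    e_car_i(t) = e_i(t) - (1/N) * sum_k e_k(t)

Bandpass filtering uses linear-phase (symmetric) windowed-sinc FIR
filters, y[n] = sum_{k=0}^{M-1} b_k x[n-k]. Offline analysis applies
them forward-backward (zero phase); the causal form is available for
real-time parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import EEGRecording

__all__ = [
    "FIRFilterSpec",
    "common_average_reference",
    "design_fir_bandpass",
    "apply_filter",
    "filter_recording",
]


@dataclass(frozen=True)
class FIRFilterSpec:
    """A designed linear-phase FIR bandpass filter.

    ``taps`` are symmetric, giving a constant group delay of
    ``(order - 1) / 2`` samples in causal application.
    """

    low_hz: float
    high_hz: float
    fs: float
    taps: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "taps", np.asarray(self.taps, dtype=float))
        if not 0.0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError("band exceeds Nyquist")
        if not np.allclose(self.taps, self.taps[::-1], atol=1e-12):
            raise ValueError("taps must be symmetric (linear phase)")

    @property
    def order(self) -> int:
        return len(self.taps)

    def to_dict(self) -> dict:
        return {
            "low_hz": self.low_hz,
            "high_hz": self.high_hz,
            "fs": self.fs,
            "taps": self.taps.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FIRFilterSpec":
        return cls(d["low_hz"], d["high_hz"], d["fs"], np.asarray(d["taps"]))


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous mean across all channels.

    Idempotent; after CAR the channel sum is zero at every sample.
    """
    if rec.data.shape[0] < 2:
        raise ValueError("CAR undefined for N=1")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=rec.fs, layout=rec.layout, t0=rec.t0)


# Hamming-window transition width in normalized frequency is ~3.3/M; the
# cutoffs are shifted into the transition band so the passband edges stay
# above -3 dB while 0.5*low / 2*high fall below -20 dB.
_TAPS_FACTOR = 3.3
_LOW_SHIFT = 0.20
_HIGH_SHIFT = 0.275


def design_fir_bandpass(
    low_hz: float,
    high_hz: float,
    fs: float,
    max_taps: int | None = None,
) -> FIRFilterSpec:
    """Design a Hamming windowed-sinc bandpass filter.

    The tap count is the smallest odd integer at or above
    ``3.3 * fs / low_hz`` (the usual toolbox heuristic: about three
    cycles of the lowest passband frequency), optionally capped by
    ``max_taps`` for short signals.
    """
    if not 0.0 < low_hz < high_hz:
        raise ValueError("band edges must satisfy 0 < low < high")
    if high_hz >= fs / 2:
        raise ValueError("band exceeds Nyquist")
    m = int(np.ceil(_TAPS_FACTOR * fs / low_hz))
    if max_taps is not None:
        m = min(m, int(max_taps))
    if m % 2 == 0:
        m += 1
    m = max(m, 5)
    df = _TAPS_FACTOR * fs / m
    lo_c = max(low_hz - _LOW_SHIFT * df, 0.05 * low_hz)
    hi_c = min(high_hz + _HIGH_SHIFT * df, 0.999 * fs / 2)
    taps = sps.firwin(m, [lo_c, hi_c], pass_zero=False, fs=fs, window="hamming")
    return FIRFilterSpec(low_hz=low_hz, high_hz=high_hz, fs=fs, taps=taps)


def apply_filter(
    x: np.ndarray,
    spec: FIRFilterSpec,
    mode: str = "zero_phase",
) -> np.ndarray:
    """Filter a 1-D or (channels x samples) 2-D signal.

    ``causal`` implements y[n] = sum_k b_k x[n-k] with zero-padded
    history (group delay (M-1)/2 samples); ``zero_phase`` applies the
    filter forward and backward over a reflect-padded copy, giving the
    squared magnitude response at zero lag. Output length equals input
    length in both modes.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return _apply_1d(x, spec, mode)
    if x.ndim == 2:
        return np.vstack([_apply_1d(row, spec, mode) for row in x])
    raise ValueError("signal must be 1-D or 2-D")


def _apply_1d(x: np.ndarray, spec: FIRFilterSpec, mode: str) -> np.ndarray:
    n = len(x)
    taps = spec.taps
    m = len(taps)
    if n < m:
        raise ValueError("signal shorter than filter")
    if mode == "causal":
        return sps.fftconvolve(x, taps, mode="full")[:n]
    if mode == "zero_phase":
        pad = min(m, n - 1)
        xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
        delay = (m - 1) // 2
        y = sps.fftconvolve(xp, taps, mode="full")[delay : delay + len(xp)]
        y = sps.fftconvolve(y[::-1], taps, mode="full")[delay : delay + len(xp)][::-1]
        return y[pad : pad + n]
    raise ValueError(f"unknown mode {mode!r}")


def filter_recording(
    rec: EEGRecording,
    spec: FIRFilterSpec,
    mode: str = "zero_phase",
) -> EEGRecording:
    """Apply a designed filter to every channel of a recording."""
    return EEGRecording(
        data=apply_filter(rec.data, spec, mode),
        fs=rec.fs,
        layout=rec.layout,
        t0=rec.t0,
    )
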