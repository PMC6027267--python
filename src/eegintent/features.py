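"""Motion-related EEG features and the time-delayed feature matrix.

Four per-channel feature time series drive the intention classifiers:

* **MRCP amplitude** — the signed 0.1–2.0 Hz filtered trace. Slow
  negative shifts (movement-related cortical potentials) over the motor
  cortex precede and accompany voluntary movement.
* **delta band power** — the 0.1–4.0 Hz filtered trace, squared (uV^2).
* **alpha band power** — the 8–12 Hz filtered trace, squared; alpha
  rhythm over parietal sites attenuates during movement (event-related
  desynchronization).
* **RMS** — root mean square of the band-filtered trace over a trailing
  window (400 ms by default):  RMS(t) = sqrt(mean of e^2 over the N_a
  samples ending at t).

From the selected channels a delay-embedded design matrix is built: the
row at time t concatenates, per channel, the feature at t, t-dt and
t-2*dt (dt = 250 ms by default), so the classifier sees a short history
of the feature dynamics rather than a single instantaneous value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import EEGRecording
from .preprocessing import apply_filter, design_fir_bandpass

__all__ = [
    "BANDS",
    "FeatureSeries",
    "FeatureMatrix",
    "mrcp_amplitude",
    "band_power",
    "rms_series",
    "select_channels",
    "build_feature_matrix",
    "DEFAULT_CHANNEL_OVERRIDES",
]

#: Passband edges (Hz) per feature family.
BANDS = {"mrcp": (0.1, 2.0), "delta": (0.1, 4.0), "alpha": (8.0, 12.0)}

#: Channels the feature plots single out per feature kind: fronto-central
#: leads over motor cortex for the slow/broadband features, parietal
#: leads for alpha.
DEFAULT_CHANNEL_OVERRIDES = {
    "mrcp": ("FC2", "C2"),
    "delta_power": ("FC2", "C2"),
    "rms": ("FC2", "C2"),
    "alpha_power": ("P3", "Pz"),
}


@dataclass
class FeatureSeries:
    """One feature kind on one channel, sampled on the EEG clock."""

    kind: str
    channel: str
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind in ("delta_power", "alpha_power", "rms") and np.any(
            self.values < 0
        ):
            raise ValueError(f"{self.kind} values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """Delay-embedded design matrix over the selected channels.

    Row ``r`` corresponds to sample index ``row_index[r]`` = t and holds,
    for each channel in order, ``[f(t), f(t - L), f(t - 2L)]`` where
    ``L = round(lag_ms * fs / 1000)`` samples. Rows exist only for
    ``t >= (n_lags - 1) * L``.
    """

    rows: np.ndarray
    channels: tuple[str, ...]
    lag_ms: float
    n_lags: int
    fs: float
    row_index: np.ndarray = field(repr=False)

    @property
    def row_times(self) -> np.ndarray:
        return self.row_index / self.fs

    def __len__(self) -> int:
        return len(self.rows)


def _max_taps(n_samples: int) -> int:
    # keep the applicability precondition (signal > 3x taps) satisfiable
    return max(n_samples // 3 - 1, 5)


def _filtered(rec: EEGRecording, band: tuple[float, float]) -> np.ndarray:
    spec = design_fir_bandpass(*band, rec.fs, max_taps=_max_taps(rec.n_samples))
    return apply_filter(rec.data, spec, mode="zero_phase")


def mrcp_amplitude(rec: EEGRecording) -> list[FeatureSeries]:
    """Signed 0.1–2.0 Hz amplitudes (uV), one series per channel."""
    filt = _filtered(rec, BANDS["mrcp"])
    return [
        FeatureSeries("mrcp", ch, filt[i], rec.fs)
        for i, ch in enumerate(rec.layout.names)
    ]


def band_power(rec: EEGRecording, band: str) -> list[FeatureSeries]:
    """Squared band-filtered signal (uV^2); ``band`` is delta or alpha."""
    if band not in ("delta", "alpha"):
        raise ValueError("band must be 'delta' or 'alpha'")
    filt = _filtered(rec, BANDS[band])
    return [
        FeatureSeries(f"{band}_power", ch, filt[i] ** 2, rec.fs)
        for i, ch in enumerate(rec.layout.names)
    ]


def rms_series(
    rec: EEGRecording,
    window_ms: float = 400.0,
    band: tuple[float, float] | None = (0.1, 4.0),
) -> list[FeatureSeries]:
    """Trailing-window RMS of the (band-filtered) signal per channel.

    The window holds ``N_a = round(window_ms * fs / 1000)`` samples and
    ends at the current sample (causal); the first ``N_a - 1`` values use
    the available shorter prefix. ``band=None`` computes RMS on the
    as-given (CAR-only) data.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    n_a = int(round(window_ms * rec.fs / 1000.0))
    if n_a > rec.n_samples:
        raise ValueError("window exceeds signal")
    data = _filtered(rec, band) if band is not None else rec.data
    sq = data**2
    csum = np.cumsum(sq, axis=1)
    n = rec.n_samples
    counts = np.minimum(np.arange(1, n + 1), n_a).astype(float)
    tail = np.zeros_like(csum)
    tail[:, n_a:] = csum[:, :-n_a]
    mean_sq = (csum - tail) / counts
    rms = np.sqrt(np.maximum(mean_sq, 0.0))
    return [
        FeatureSeries("rms", ch, rms[i], rec.fs)
        for i, ch in enumerate(rec.layout.names)
    ]


def discriminability_score(
    values: np.ndarray, labels: np.ndarray
) -> float:
    """Movement-vs-rest separability of one feature series.

    For each movement class c in {+1, -1} present in ``labels``, compute
    |mean(f | c) - mean(f | rest)| / pooled SD; return the larger. A
    channel carrying an event-locked component scores high, a noise-only
    channel near zero.
    """
    rest = values[labels == 0]
    if len(rest) < 2:
        raise ValueError("need rest samples to score channels")
    best = 0.0
    for c in (1, -1):
        grp = values[labels == c]
        if len(grp) < 2:
            continue
        pooled = np.sqrt(0.5 * (np.var(grp, ddof=1) + np.var(rest, ddof=1)))
        if pooled == 0:
            continue
        best = max(best, abs(grp.mean() - rest.mean()) / pooled)
    return best


def select_channels(
    series_by_channel: Mapping[str, FeatureSeries],
    labels: np.ndarray,
    k: int = 2,
    override: Sequence[str] | None = None,
) -> tuple[str, ...]:
    """Pick the k most discriminative channels for one feature kind.

    ``override`` short-circuits the ranking and reproduces a fixed
    channel choice (e.g. the fronto-central FC2/C2 pair for the slow
    features). Otherwise channels are ranked by
    :func:`discriminability_score`; ties break on the channel label so
    the result is independent of input ordering.
    """
    if override is not None:
        return tuple(override)
    if k > len(series_by_channel):
        raise ValueError("k exceeds channel count")
    labels = np.asarray(labels)
    scored = []
    for name, fs_ in series_by_channel.items():
        if len(fs_) != len(labels):
            raise ValueError("series/labels length mismatch")
        scored.append((-discriminability_score(fs_.values, labels), name))
    scored.sort()
    return tuple(name for _, name in scored[:k])


def build_feature_matrix(
    series: Sequence[FeatureSeries],
    lag_ms: float = 250.0,
    n_lags: int = 3,
) -> FeatureMatrix:
    """Delay-embed the selected channels' feature series.

    With the defaults (250 ms, 3 lags) and two channels the rows are
    6-wide: ``[f_ch1(t), f_ch1(t-L), f_ch1(t-2L), f_ch2(t), ...]``.
    """
    if not series:
        raise ValueError("no feature series given")
    fs = series[0].fs
    n = len(series[0])
    if any(s.fs != fs or len(s) != n for s in series):
        raise ValueError("series must share fs and length")
    lag = int(round(lag_ms * fs / 1000.0))
    if lag < 1:
        raise ValueError("lag must be at least one sample")
    start = (n_lags - 1) * lag
    if n <= start:
        raise ValueError("insufficient history")
    idx = np.arange(start, n)
    cols = []
    for s in series:
        for j in range(n_lags):
            cols.append(s.values[idx - j * lag])
    return FeatureMatrix(
        rows=np.column_stack(cols),
        channels=tuple(s.channel for s in series),
        lag_ms=lag_ms,
        n_lags=n_lags,
        fs=fs,
        row_index=idx,
    )
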