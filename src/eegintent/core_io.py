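"""Session data model and on-disk bundle readers/writers.

A recording *session* couples multichannel scalp EEG with the audible-cue
schedule and the synchronized upper-limb kinematics of one subject. On
disk a session is a directory ("bundle") of human-readable files:

``metadata.json``
    subject id, sampling rates, units, reference electrode.
``eeg.csv``
    one column per channel (header row = electrode labels), samples in
    microvolts. An ``eeg.edf`` file may stand in for it when the optional
    EDF reader (mne) is installed.
``schedule.csv``
    cue times in seconds and class codes (+1 arm lifting, -1 hand
    reaching).
``kinematics.csv``
    shoulder and elbow flexion/extension angles in degrees and the hand
    endpoint (x forward, y up, meters, shoulder-centered).
``labels.csv``
    per-sample motion class in {-1, 0, +1}, aligned to the EEG clock.

Kinematics recorded at a lower rate (the motion-capture system's 120 Hz)
are linearly resampled onto the EEG clock when a bundle is read, so an
in-memory :class:`SessionBundle` always carries one common time base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CHANNELS",
    "BundleError",
    "ChannelLayout",
    "EEGRecording",
    "CueSchedule",
    "KinematicsTrace",
    "SessionBundle",
    "read_session",
    "write_session",
    "label_track_from_schedule",
    "resample_to",
]

#: The 16-electrode 10–20 montage used throughout: frontal/central leads
#: over motor cortex plus parietal leads for alpha-band activity.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fz", "F3", "FC2", "FC1", "FC5", "C2", "Cz", "C1",
    "C3", "C5", "T3", "Cp2", "Cp1", "Cp5", "Pz", "P3",
)


class BundleError(ValueError):
    """Raised for malformed, incomplete or inconsistent session bundles."""


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered 10–20 electrode labels plus the recording reference."""

    names: tuple[str, ...] = DEFAULT_CHANNELS
    reference: str = "A2"  # right earlobe

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise BundleError("layout mismatch: duplicate channel names")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float = 500.0
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise BundleError("EEG data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.layout):
            raise BundleError(
                "layout mismatch: "
                f"{self.data.shape[0]} rows vs {len(self.layout)} labels"
            )
        if not self.fs > 0:
            raise BundleError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise BundleError("non-finite data in EEG")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.index(name)]


@dataclass
class CueSchedule:
    """Audible-cue times and class codes (+1 lifting, -1 reaching)."""

    events: list[tuple[float, int]] = field(default_factory=list)
    rest_lead_s: float = 10.0

    def __post_init__(self) -> None:
        self.events = [(float(t), int(c)) for t, c in self.events]
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise BundleError("clock error: cue times not monotone")
        if any(c not in (-1, 1) for _, c in self.events):
            raise BundleError("cue class codes must be +1 or -1")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class KinematicsTrace:
    """Upper-limb kinematics: joint angles (deg) and hand endpoint (m)."""

    fs: float
    shoulder_deg: np.ndarray
    elbow_deg: np.ndarray
    endpoint_xy: np.ndarray

    def __post_init__(self) -> None:
        self.shoulder_deg = np.asarray(self.shoulder_deg, dtype=float)
        self.elbow_deg = np.asarray(self.elbow_deg, dtype=float)
        self.endpoint_xy = np.asarray(self.endpoint_xy, dtype=float)
        n = len(self.shoulder_deg)
        if len(self.elbow_deg) != n or len(self.endpoint_xy) != n:
            raise BundleError("kinematic series lengths differ")
        if self.endpoint_xy.ndim != 2 or self.endpoint_xy.shape[1] != 2:
            raise BundleError("endpoint must be n x 2")
        for a in (self.shoulder_deg, self.elbow_deg):
            if np.any((a < 0.0) | (a > 180.0)):
                raise BundleError("joint angles must lie in [0, 180] deg")

    def __len__(self) -> int:
        return len(self.shoulder_deg)


def resample_to(kin: KinematicsTrace, fs: float, n_samples: int) -> KinematicsTrace:
    """Linearly resample a kinematics trace onto a target clock.

    Total duration is preserved to within one sample period of the
    coarser clock; samples beyond the source duration hold the last
    value.
    """
    t_src = np.arange(len(kin)) / kin.fs
    t_dst = np.arange(n_samples) / fs
    interp = lambda y: np.interp(t_dst, t_src, y)  # noqa: E731
    return KinematicsTrace(
        fs=fs,
        shoulder_deg=interp(kin.shoulder_deg),
        elbow_deg=interp(kin.elbow_deg),
        endpoint_xy=np.column_stack(
            [interp(kin.endpoint_xy[:, 0]), interp(kin.endpoint_xy[:, 1])]
        ),
    )


@dataclass
class SessionBundle:
    """One subject's session: EEG, cues, kinematics and per-sample labels.

    Kinematics and labels are aligned to the EEG clock (same ``fs``, same
    sample count).
    """

    subject_id: str
    eeg: EEGRecording
    schedule: CueSchedule
    kin: KinematicsTrace
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.eeg.n_samples:
            raise BundleError("labels length differs from EEG sample count")
        if len(self.kin) != self.eeg.n_samples:
            raise BundleError("kinematics not aligned to EEG clock")
        if not np.all(np.isin(self.labels, (-1, 0, 1))):
            raise BundleError("labels must lie in {-1, 0, +1}")


# ---------------------------------------------------------------------------
# bundle I/O

_EEG_TEXT = "eeg.csv"
_EEG_EDF = "eeg.edf"
_SCHEDULE = "schedule.csv"
_KIN = "kinematics.csv"
_LABELS = "labels.csv"
_META = "metadata.json"


def write_session(s: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle directory; deterministic byte layout.

    Floating-point series are written with ``repr`` round-trip precision
    so that :func:`read_session` recovers the bundle exactly.
    """
    if not np.all(np.isfinite(s.eeg.data)):
        raise BundleError("non-finite data")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "subject_id": s.subject_id,
        "eeg_fs_hz": s.eeg.fs,
        "kin_fs_hz": s.kin.fs,
        "t0_s": s.eeg.t0,
        "channels": list(s.eeg.layout.names),
        "reference": s.eeg.layout.reference,
        "rest_lead_s": s.schedule.rest_lead_s,
        "units": {"eeg": "uV", "angle": "deg", "endpoint": "m"},
    }
    (path / _META).write_text(json.dumps(meta, indent=2) + "\n")

    fmt = "%.17g"
    pd.DataFrame(s.eeg.data.T, columns=list(s.eeg.layout.names)).to_csv(
        path / _EEG_TEXT, index=False, float_format=fmt
    )
    pd.DataFrame(s.schedule.events, columns=["time_s", "class_code"]).to_csv(
        path / _SCHEDULE, index=False, float_format=fmt
    )
    pd.DataFrame(
        {
            "shoulder_deg": s.kin.shoulder_deg,
            "elbow_deg": s.kin.elbow_deg,
            "endpoint_x_m": s.kin.endpoint_xy[:, 0],
            "endpoint_y_m": s.kin.endpoint_xy[:, 1],
        }
    ).to_csv(path / _KIN, index=False, float_format=fmt)
    pd.DataFrame({"label": s.labels}).to_csv(path / _LABELS, index=False)
    return path


def _read_eeg(path: Path, meta: dict) -> EEGRecording:
    layout = ChannelLayout(tuple(meta["channels"]), meta.get("reference", "A2"))
    if (path / _EEG_TEXT).exists():
        df = pd.read_csv(path / _EEG_TEXT)
        if list(df.columns) != list(layout.names):
            raise BundleError("layout mismatch between eeg.csv and metadata")
        data = df.to_numpy(dtype=float).T
    elif (path / _EEG_EDF).exists():
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional extra
            raise BundleError("incomplete bundle: EDF present but mne not installed") from exc
        raw = mne.io.read_raw_edf(path / _EEG_EDF, preload=True, verbose="error")
        if list(raw.ch_names) != list(layout.names):
            raise BundleError("layout mismatch between eeg.edf and metadata")
        data = raw.get_data() * 1e6  # mne returns volts
        meta = dict(meta, eeg_fs_hz=float(raw.info["sfreq"]))
    else:
        raise BundleError("incomplete bundle: no EEG file")
    return EEGRecording(
        data=data, fs=float(meta["eeg_fs_hz"]), layout=layout,
        t0=float(meta.get("t0_s", 0.0)),
    )


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session bundle written by :func:`write_session`.

    Kinematics stored at a different rate are resampled onto the EEG
    clock.
    """
    path = Path(path)
    if not (path / _META).exists():
        raise BundleError("incomplete bundle: missing metadata.json")
    meta = json.loads((path / _META).read_text())
    for required in (_SCHEDULE, _KIN, _LABELS):
        if not (path / required).exists():
            raise BundleError(f"incomplete bundle: missing {required}")

    eeg = _read_eeg(path, meta)

    sched_df = pd.read_csv(path / _SCHEDULE)
    if len(sched_df) and not sched_df["time_s"].is_monotonic_increasing:
        raise BundleError("clock error: schedule times not monotone")
    schedule = CueSchedule(
        events=list(zip(sched_df["time_s"], sched_df["class_code"].astype(int))),
        rest_lead_s=float(meta.get("rest_lead_s", 10.0)),
    )

    kin_df = pd.read_csv(path / _KIN)
    kin = KinematicsTrace(
        fs=float(meta["kin_fs_hz"]),
        shoulder_deg=kin_df["shoulder_deg"].to_numpy(),
        elbow_deg=kin_df["elbow_deg"].to_numpy(),
        endpoint_xy=kin_df[["endpoint_x_m", "endpoint_y_m"]].to_numpy(),
    )
    if kin.fs != eeg.fs or len(kin) != eeg.n_samples:
        kin = resample_to(kin, eeg.fs, eeg.n_samples)

    labels = pd.read_csv(path / _LABELS)["label"].to_numpy(dtype=int)
    # EDF stores whole one-second records, so the EEG may be up to one
    # second shorter than the stored label track; trim the tail to match
    if eeg.n_samples < len(labels) <= eeg.n_samples + int(eeg.fs):
        labels = labels[: eeg.n_samples]
        kin = KinematicsTrace(
            fs=kin.fs,
            shoulder_deg=kin.shoulder_deg[: eeg.n_samples],
            elbow_deg=kin.elbow_deg[: eeg.n_samples],
            endpoint_xy=kin.endpoint_xy[: eeg.n_samples],
        )
    return SessionBundle(
        subject_id=str(meta["subject_id"]), eeg=eeg, schedule=schedule,
        kin=kin, labels=labels,
    )


# ---------------------------------------------------------------------------
# labeling

def label_track_from_schedule(
    schedule: CueSchedule,
    kin: KinematicsTrace,
    n_samples: int,
    fs: float,
    *,
    movement_windows: Sequence[tuple[float, float]] | None = None,
    vel_thresh_deg_s: float = 10.0,
    hold_ms: float = 200.0,
) -> np.ndarray:
    """Per-sample motion class from the cue schedule and limb motion.

    Each cue's class code is painted over the half-open sample window
    ``[onset, offset)`` of the movement it triggered; everything else,
    including the initial rest lead, is 0. Movement onset/offset default
    to the shoulder-velocity limb-motion detector
    (:func:`eegintent.intention.limb_motion_flag`); explicit windows (in
    seconds) may be passed instead when they are known exactly.
    """
    labels = np.zeros(n_samples, dtype=int)
    duration = n_samples / fs
    for t_cue, _ in schedule.events:
        if t_cue >= duration:
            raise BundleError("schedule overrun: cue beyond session end")
    if not schedule.events:
        return labels

    if movement_windows is not None:
        windows = list(movement_windows)
        if len(windows) != len(schedule.events):
            raise BundleError("one movement window required per cue")
    else:
        from .intention import limb_motion_flag

        moving = limb_motion_flag(
            kin, vel_thresh_deg_s=vel_thresh_deg_s, hold_ms=hold_ms
        )
        # movement windows = maximal True runs of the detector, matched
        # to cues in order of onset
        edges = np.flatnonzero(np.diff(np.r_[0, moving.astype(int), 0]))
        runs = [(on / kin.fs, off / kin.fs) for on, off in zip(edges[::2], edges[1::2])]
        windows = []
        for t_cue, _ in schedule.events:
            cand = [r for r in runs if r[0] >= t_cue]
            if not cand:
                raise BundleError("no detected movement after cue")
            windows.append(cand[0])

    for (t_cue, code), (on, off) in zip(schedule.events, windows):
        i0 = max(int(round(on * fs)), int(round(schedule.rest_lead_s * fs)))
        i1 = min(int(round(off * fs)), n_samples)
        labels[i0:i1] = code
    return labels
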