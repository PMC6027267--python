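"""Stage two: distal-arm kinematics from intention class + shoulder history.

A transhumeral amputee retains only shoulder motion, so elbow angle and
hand endpoint must be synthesized. A motion database pools, from healthy
subjects' sessions, one record per EEG-clock sample inside (and just
around) each movement:

    (subject, class code, shoulder angle at t / t-250 ms / t-500 ms,
     elbow angle, endpoint x, endpoint y)

Two small backprop networks (10 hidden units, 4 inputs: class code plus
the three shoulder angles) regress the elbow angle and the endpoint
(x, y jointly). Training is leave-one-subject-out: the excluded subject
plays the amputee, and the fit is evaluated on their records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._mlp import BackpropNet
from .core_io import SessionBundle

__all__ = [
    "MotionDatabase",
    "EstimatorSpec",
    "MotionEstimator",
    "build_motion_database",
    "train_estimator",
    "estimate",
    "loso_rmse",
]

_COLUMNS = (
    "subject_id", "class_code", "shoulder_now_deg", "shoulder_250_deg",
    "shoulder_500_deg", "elbow_deg", "endpoint_x_m", "endpoint_y_m",
)


@dataclass
class MotionDatabase:
    """Pooled (shoulder history, class) -> (elbow, endpoint) examples."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"motion database missing columns {sorted(missing)}")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["subject_id"]))

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionDatabase":
        return cls(pd.read_csv(path, dtype={"subject_id": str}))


@dataclass
class EstimatorSpec:
    """Configuration for one distal-motion regressor."""

    target: str  # "elbow" | "endpoint"
    excluded_subject: str | None = None
    n_hidden: int = 10
    lr: float = 1.0
    momentum: float = 0.9
    epochs: int = 2000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("elbow", "endpoint"):
            raise ValueError("target must be 'elbow' or 'endpoint'")


def build_motion_database(
    sessions: Sequence[SessionBundle],
    rest_margin_s: float = 0.5,
    history_ms: tuple[float, float] = (250.0, 500.0),
    stride: int = 1,
) -> MotionDatabase:
    """Extract per-sample motion records from labeled sessions.

    Records cover every sample inside a nonzero-label span plus
    ``rest_margin_s`` of adjacent rest on each side (so the estimators
    also see the stationary posture). ``stride`` thins the records to
    every n-th EEG sample; the default keeps all of them. Sessions
    without kinematics are skipped with a warning.
    """
    frames = []
    for s in sessions:
        if s.kin is None or len(s.kin) == 0:
            warnings.warn(f"session {s.subject_id}: no kinematics, skipped")
            continue
        fs = s.eeg.fs
        lag1 = int(round(history_ms[0] * fs / 1000.0))
        lag2 = int(round(history_ms[1] * fs / 1000.0))
        margin = int(round(rest_margin_s * fs))
        nz = s.labels != 0
        keep = nz.copy()
        edges = np.flatnonzero(np.diff(np.r_[0, nz.astype(int), 0]))
        for on, off in zip(edges[::2], edges[1::2]):
            keep[max(on - margin, 0) : min(off + margin, len(keep))] = True
        idx = np.flatnonzero(keep)[:: max(int(stride), 1)]
        idx = idx[idx >= lag2]  # history strictly from past/current samples
        sh = s.kin.shoulder_deg
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "class_code": s.labels[idx],
                    "shoulder_now_deg": sh[idx],
                    "shoulder_250_deg": sh[idx - lag1],
                    "shoulder_500_deg": sh[idx - lag2],
                    "elbow_deg": s.kin.elbow_deg[idx],
                    "endpoint_x_m": s.kin.endpoint_xy[idx, 0],
                    "endpoint_y_m": s.kin.endpoint_xy[idx, 1],
                }
            )
        )
    if not frames:
        return MotionDatabase(pd.DataFrame(columns=list(_COLUMNS)))
    return MotionDatabase(pd.concat(frames, ignore_index=True))


_INPUT_COLS = ["class_code", "shoulder_now_deg", "shoulder_250_deg", "shoulder_500_deg"]


@dataclass
class MotionEstimator:
    """A fitted distal-motion regressor with its input/target scaling."""

    spec: EstimatorSpec
    net: BackpropNet = field(repr=False)
    in_min: np.ndarray
    in_max: np.ndarray
    out_min: np.ndarray
    out_max: np.ndarray
    train_subjects: tuple[str, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.in_max > self.in_min, self.in_max - self.in_min, 1.0)
        if np.any(X < self.in_min - 1e-9) or np.any(X > self.in_max + 1e-9):
            warnings.warn("input outside training range; clipping")
            X = np.clip(X, self.in_min, self.in_max)
        xz = (X - self.in_min) / span
        out01 = self.net.forward(xz)
        return self.out_min + out01 * (self.out_max - self.out_min)


def _target_cols(target: str) -> list[str]:
    return ["elbow_deg"] if target == "elbow" else ["endpoint_x_m", "endpoint_y_m"]


def train_estimator(db: MotionDatabase, spec: EstimatorSpec) -> MotionEstimator:
    """Fit one regressor on all subjects except ``spec.excluded_subject``.

    Inputs are min/max scaled to [0, 1] using training statistics;
    targets likewise (the sigmoid output is mapped back to native units
    on prediction, so outputs stay within the training target range).
    """
    rec = db.records
    if spec.excluded_subject is not None:
        rec = rec[rec["subject_id"] != spec.excluded_subject]
    if not len(rec):
        raise ValueError("empty training set")
    X = rec[_INPUT_COLS].to_numpy(dtype=float)
    Y = rec[_target_cols(spec.target)].to_numpy(dtype=float)
    in_min, in_max = X.min(axis=0), X.max(axis=0)
    out_min, out_max = Y.min(axis=0), Y.max(axis=0)
    in_span = np.where(in_max > in_min, in_max - in_min, 1.0)
    out_span = np.where(out_max > out_min, out_max - out_min, 1.0)
    net = BackpropNet(
        X.shape[1], spec.n_hidden, Y.shape[1], lr=spec.lr,
        momentum=spec.momentum, epochs=spec.epochs, tol=spec.tol,
        seed=spec.seed,
    ).fit((X - in_min) / in_span, (Y - out_min) / out_span)
    return MotionEstimator(
        spec=spec, net=net, in_min=in_min, in_max=in_max,
        out_min=out_min, out_max=out_max,
        train_subjects=tuple(pd.unique(rec["subject_id"])),
    )


def estimate(
    est: MotionEstimator,
    class_code: int,
    shoulder_now: float,
    shoulder_250: float,
    shoulder_500: float,
) -> float | tuple[float, float]:
    """Predict elbow angle (deg) or endpoint (x, y in m) for one query."""
    if class_code not in (-1, 0, 1):
        raise ValueError("class_code must be -1, 0 or +1")
    out = est.predict(
        np.array([[class_code, shoulder_now, shoulder_250, shoulder_500]])
    )[0]
    if est.spec.target == "elbow":
        return float(out[0])
    return float(out[0]), float(out[1])


def loso_rmse(
    db: MotionDatabase,
    target: str,
    seed: int = 0,
    epochs: int = 2000,
) -> dict[str, float]:
    """Leave-one-subject-out RMSE per held-out subject, in native units.

    For ``endpoint`` the RMSE is the per-axis RMSE averaged over x and y.
    """
    out: dict[str, float] = {}
    for subj in db.subjects:
        spec = EstimatorSpec(target=target, excluded_subject=subj,
                             seed=seed, epochs=epochs)
        est = train_estimator(db, spec)
        held = db.records[db.records["subject_id"] == subj]
        X = held[_INPUT_COLS].to_numpy(dtype=float)
        Y = held[_target_cols(target)].to_numpy(dtype=float)
        pred = est.predict(X)
        rmse_axes = np.sqrt(np.mean((pred - Y) ** 2, axis=0))
        out[subj] = float(np.mean(rmse_axes))
    return out
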