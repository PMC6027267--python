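"""Stage one: three-class motion-intention classifiers and gating.

A classifier maps each delay-embedded feature row to one of three
classes, coded +1 (arm lifting), -1 (hand reaching), 0 (rest). Two
families are provided:

* a single-hidden-layer perceptron trained by error backpropagation
  (sigmoidal hidden and output units; 30 hidden units for a single
  feature kind, 80 for the combined four-feature matrix), whose
  continuous output in [-1, 1] is discretized at +-0.5;
* a k-nearest-neighbor classifier whose neighbor count, metric and vote
  rule (majority or similarity-weighted, Sim = 1/(1+d)) are chosen by
  5-fold cross-validation on the training partition.

Because a prosthesis must never move when the residual limb is still,
the classifier output is *gated* against a shoulder-velocity limb-motion
detector: whenever the limb is not moving the final prediction is Rest,
otherwise the classifier's prediction stands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import medfilt
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors

from ._mlp import BackpropNet
from .core_io import KinematicsTrace
from .features import FeatureMatrix

__all__ = [
    "MLPSpec",
    "KNNSpec",
    "TrainedIntentionModel",
    "GatingRule",
    "train_mlp",
    "predict_continuous",
    "discretize",
    "train_knn",
    "predict_knn",
    "limb_motion_flag",
    "gate",
    "chronological_split",
]

CLASS_CODES = (-1, 0, 1)


@dataclass
class MLPSpec:
    """Configuration of the backprop intention network."""

    n_inputs: int
    n_hidden: int = 30
    lr: float = 1.0
    momentum: float = 0.9
    epochs: int = 800
    tol: float = 1e-6
    seed: int = 0


@dataclass
class KNNSpec:
    """A resolved k-nn configuration (after CV model selection)."""

    k: int
    metric: str = "euclidean"
    vote: str = "majority"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.vote not in ("majority", "similarity_weighted"):
            raise ValueError("vote must be majority or similarity_weighted")


@dataclass
class TrainedIntentionModel:
    """A fitted intention classifier with its scaler and data record."""

    kind: str  # "mlp" | "knn"
    spec: MLPSpec | KNNSpec
    feature_kind: str = ""
    train_fraction: float = 0.8
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    net: BackpropNet | None = field(default=None, repr=False)
    train_X: np.ndarray | None = field(default=None, repr=False)
    train_y: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_inputs(self) -> int:
        return len(self.scaler_mean)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError("feature dimension mismatch")
        return (X - self.scaler_mean) / self.scaler_std

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "kind": self.kind,
            "feature_kind": self.feature_kind,
            "train_fraction": self.train_fraction,
            "spec": self.spec.__dict__,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
        }
        if self.kind == "mlp":
            d["net"] = {
                "n_inputs": self.net.n_inputs,
                "n_hidden": self.net.n_hidden,
                "n_outputs": self.net.n_outputs,
                "seed": self.net.seed,
                "w1": self.net.w1.tolist(),
                "b1": self.net.b1.tolist(),
                "w2": self.net.w2.tolist(),
                "b2": self.net.b2.tolist(),
            }
        else:
            d["train_X"] = self.train_X.tolist()
            d["train_y"] = self.train_y.tolist()
        path.write_text(json.dumps(d))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedIntentionModel":
        d = json.loads(Path(path).read_text())
        if d["kind"] == "mlp":
            spec = MLPSpec(**d["spec"])
            nd = d["net"]
            net = BackpropNet(nd["n_inputs"], nd["n_hidden"], nd["n_outputs"],
                              seed=nd["seed"])
            net.w1 = np.asarray(nd["w1"])
            net.b1 = np.asarray(nd["b1"])
            net.w2 = np.asarray(nd["w2"])
            net.b2 = np.asarray(nd["b2"])
            return cls(
                kind="mlp", spec=spec, feature_kind=d["feature_kind"],
                train_fraction=d["train_fraction"],
                scaler_mean=np.asarray(d["scaler_mean"]),
                scaler_std=np.asarray(d["scaler_std"]), net=net,
            )
        spec = KNNSpec(**d["spec"])
        return cls(
            kind="knn", spec=spec, feature_kind=d["feature_kind"],
            train_fraction=d["train_fraction"],
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_std=np.asarray(d["scaler_std"]),
            train_X=np.asarray(d["train_X"]),
            train_y=np.asarray(d["train_y"], dtype=int),
        )


def chronological_split(n: int, train_fraction: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """First-80%/last-20% row split.

    Chronological rather than random: adjacent delay-embedded rows share
    samples, so a random split would leak training data into the test
    set.
    """
    cut = int(round(n * train_fraction))
    idx = np.arange(n)
    return idx[:cut], idx[cut:]


def _as_rows(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.rows
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# MLP

def train_mlp(
    X,
    y: np.ndarray,
    spec: MLPSpec | None = None,
    feature_kind: str = "",
) -> TrainedIntentionModel:
    """Fit the backprop network on (rows, class codes).

    Targets are the class codes themselves (+1 lifting, -1 reaching,
    0 rest) mapped onto the output sigmoid's [0, 1] range. Inputs are
    z-scored with statistics of the given (training) rows; the scaler is
    stored with the model.
    """
    rows = _as_rows(X)
    y = np.asarray(y)
    if len(rows) != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels")
    if spec is None:
        spec = MLPSpec(n_inputs=rows.shape[1])
    if spec.n_inputs != rows.shape[1]:
        raise ValueError("feature dimension mismatch")
    mean = rows.mean(axis=0)
    std = rows.std(axis=0)
    std[std == 0] = 1.0
    net = BackpropNet(
        spec.n_inputs, spec.n_hidden, 1, lr=spec.lr, momentum=spec.momentum,
        epochs=spec.epochs, tol=spec.tol, seed=spec.seed,
    ).fit((rows - mean) / std, (y + 1.0) / 2.0)
    return TrainedIntentionModel(
        kind="mlp", spec=spec, feature_kind=feature_kind,
        scaler_mean=mean, scaler_std=std, net=net,
    )


def predict_continuous(m: TrainedIntentionModel, X) -> np.ndarray:
    """Continuous network output in [-1, 1] (2*sigmoid - 1)."""
    if m.kind != "mlp":
        raise ValueError("continuous output requires an MLP model")
    rows = m._scale(_as_rows(X))
    return 2.0 * m.net.forward(rows).ravel() - 1.0


def discretize(
    values: np.ndarray, thresholds: tuple[float, float] = (-0.5, 0.5)
) -> np.ndarray:
    """Map continuous outputs to class codes; ties go to rest."""
    lo, hi = thresholds
    if lo >= hi:
        raise ValueError("thresholds must be ordered")
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape, dtype=int)
    out[values < lo] = -1
    out[values > hi] = 1
    return out


# ---------------------------------------------------------------------------
# k-nn

DEFAULT_K_GRID = tuple(range(1, 26, 2))
DEFAULT_METRICS = ("euclidean", "cityblock", "cosine")
DEFAULT_VOTES = ("majority", "similarity_weighted")


def _vote(
    neigh_y: np.ndarray, neigh_d: np.ndarray, vote: str
) -> np.ndarray:
    """Resolve neighbor labels (n_queries x k) into class predictions.

    Majority counts members per class (Sim-weighting uses
    Sim = 1/(1+d)). Ties break toward rest (0) when rest is among the
    tied classes, else toward the smallest class code.
    """
    n = len(neigh_y)
    scores = np.zeros((n, len(CLASS_CODES)))
    if vote == "majority":
        w = np.ones_like(neigh_d)
    else:
        w = 1.0 / (1.0 + neigh_d)
    for ci, c in enumerate(CLASS_CODES):
        scores[:, ci] = np.where(neigh_y == c, w, 0.0).sum(axis=1)
    best = scores.max(axis=1, keepdims=True)
    tied = scores >= best - 1e-12
    # preference order under ties: rest, then -1, then +1
    pref = np.array([CLASS_CODES.index(0), CLASS_CODES.index(-1), CLASS_CODES.index(1)])
    pick = np.full(n, -1, dtype=int)
    for p in pref[::-1]:
        pick = np.where(tied[:, p], p, pick)
    return np.array(CLASS_CODES)[pick]


def _knn_predict_raw(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    spec: KNNSpec,
) -> np.ndarray:
    k = min(spec.k, len(train_X))
    nn = NearestNeighbors(n_neighbors=k, metric=spec.metric).fit(train_X)
    dist, ind = nn.kneighbors(query_X)
    return _vote(train_y[ind], dist, spec.vote)


def train_knn(
    X,
    y: np.ndarray,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    metrics: Sequence[str] = DEFAULT_METRICS,
    votes: Sequence[str] = DEFAULT_VOTES,
    n_folds: int = 5,
    feature_kind: str = "",
) -> TrainedIntentionModel:
    """Select (k, metric, vote) by 5-fold CV and store the training set.

    The grid is scanned for the lowest cross-validated misclassification
    rate; ties break toward smaller k, then metric order, then vote
    order, so selection is deterministic. Inputs are z-scored with the
    training statistics.
    """
    rows = _as_rows(X)
    y = np.asarray(y, dtype=int)
    if len(rows) != len(y):
        raise ValueError("X and y length mismatch")
    if not (len(k_grid) and len(metrics) and len(votes)):
        raise ValueError("empty search grid")
    if len(rows) < n_folds:
        raise ValueError("fewer rows than folds")
    mean = rows.mean(axis=0)
    std = rows.std(axis=0)
    std[std == 0] = 1.0
    Xz = (rows - mean) / std

    kmax = min(max(k_grid), len(rows) - 1)
    errors: dict[tuple[int, str, str], float] = {}
    folds = list(KFold(n_splits=n_folds, shuffle=False).split(Xz))
    for metric in metrics:
        for tr, va in folds:
            kk = min(kmax, len(tr))
            nn = NearestNeighbors(n_neighbors=kk, metric=metric).fit(Xz[tr])
            dist, ind = nn.kneighbors(Xz[va])
            ny, nd = y[tr][ind], dist
            for k in k_grid:
                if k > kk:
                    continue
                for vote in votes:
                    pred = _vote(ny[:, :k], nd[:, :k], vote)
                    key = (k, metric, vote)
                    errors[key] = errors.get(key, 0.0) + float(np.sum(pred != y[va]))
    ranked = sorted(
        errors.items(),
        key=lambda kv: (kv[1], kv[0][0], metrics.index(kv[0][1]), votes.index(kv[0][2])),
    )
    k_best, metric_best, vote_best = ranked[0][0]
    spec = KNNSpec(k=k_best, metric=metric_best, vote=vote_best)
    return TrainedIntentionModel(
        kind="knn", spec=spec, feature_kind=feature_kind,
        scaler_mean=mean, scaler_std=std, train_X=Xz, train_y=y,
    )


def predict_knn(m: TrainedIntentionModel, X) -> np.ndarray:
    """Class predictions of a fitted k-nn model."""
    if m.kind != "knn":
        raise ValueError("model is not k-nn")
    return _knn_predict_raw(m.train_X, m.train_y, m._scale(_as_rows(X)), m.spec)


# ---------------------------------------------------------------------------
# limb-motion detection and gating

def limb_motion_flag(
    kin: KinematicsTrace,
    vel_thresh_deg_s: float = 10.0,
    hold_ms: float = 200.0,
    gap_merge_ms: float = 250.0,
    smooth_ms: float = 100.0,
) -> np.ndarray:
    """Detect residual-limb (shoulder) motion from the angle trace.

    The shoulder angle is median-filtered (5 samples) to reject
    single-sample jitter, moving-average smoothed over ``smooth_ms``
    (marker jitter would otherwise swamp the derivative), and
    differentiated by central difference over the same span before
    thresholding on absolute angular velocity. Sub-threshold gaps
    shorter than ``gap_merge_ms`` are bridged (the velocity dips through
    zero at the movement turnaround), then only excursions sustained for
    at least ``hold_ms`` survive.
    """
    ang = medfilt(kin.shoulder_deg, kernel_size=5)
    w = max(int(round(smooth_ms * kin.fs / 1000.0)), 1)
    kernel = np.ones(w) / w
    pad = np.r_[np.full(w, ang[0]), ang, np.full(w, ang[-1])]
    ang = np.convolve(pad, kernel, mode="same")[w:-w]
    half = max(w // 2, 1)
    vel = np.empty_like(ang)
    vel[half:-half] = (ang[2 * half :] - ang[: -2 * half]) * kin.fs / (2 * half)
    vel[:half] = vel[half]
    vel[-half:] = vel[-half - 1]
    above = np.abs(vel) > vel_thresh_deg_s
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    runs = list(zip(edges[::2], edges[1::2]))
    # bridge short sub-threshold gaps (debounce) ...
    merge = max(int(round(gap_merge_ms * kin.fs / 1000.0)), 1)
    merged: list[list[int]] = []
    for on, off in runs:
        if merged and on - merged[-1][1] <= merge:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    # ... then drop runs shorter than the hold window
    hold = max(int(round(hold_ms * kin.fs / 1000.0)), 1)
    flag = np.zeros(len(above), dtype=bool)
    for on, off in merged:
        if off - on >= hold:
            flag[on:off] = True
    return flag


@dataclass(frozen=True)
class GatingRule:
    """The six-row comparison table between classifier output and limb motion.

    Keys are (predicted class code, limb moving?); values the final
    class. With the limb at rest every prediction maps to Rest; with the
    limb moving the classifier's prediction stands (Rest included).
    """

    table: tuple = (
        ((0, False), 0),
        ((-1, False), 0),
        ((1, False), 0),
        ((0, True), 0),
        ((-1, True), -1),
        ((1, True), 1),
    )

    def apply(self, pred: np.ndarray, moving: np.ndarray) -> np.ndarray:
        mapping = dict(self.table)
        pred = np.asarray(pred, dtype=int)
        moving = np.asarray(moving, dtype=bool)
        if pred.shape != moving.shape:
            raise ValueError("pred and moving must have equal length")
        out = np.empty_like(pred)
        for (p, mv), final in mapping.items():
            out[(pred == p) & (moving == mv)] = final
        return out


def gate(pred: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Apply the default gating table (final = Rest unless limb moves)."""
    return GatingRule().apply(pred, moving)
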