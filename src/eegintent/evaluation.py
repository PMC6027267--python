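"""Accuracy, chance level, binomial significance and the study runner.

Decoding accuracy alone is uninterpretable in a three-class problem with
unbalanced rest time, so every report carries a chance level — either
the largest class prior or an empirical permutation estimate — and a
one-sided exact binomial p-value for accuracy above chance. Per-subject
accuracies aggregate as mean +- population SD, rounded half-up to one
decimal for table reporting.
"""

from __future__ import annotations

import json
import time
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from . import intention as intent
from .core_io import SessionBundle, read_session
from .features import DEFAULT_CHANNEL_OVERRIDES
from .motion_estimation import build_motion_database, loso_rmse
from .preprocessing import common_average_reference
from .synthetic_data import SyntheticConfig, generate_study, null_world

__all__ = [
    "EvaluationReport",
    "classification_accuracy",
    "chance_level",
    "binomial_significance",
    "aggregate_accuracy_table",
    "PipelineConfig",
    "run_pipeline",
    "extract_feature_series",
    "evaluate_session",
]

FEATURE_KINDS = ("mrcp", "delta_power", "alpha_power", "rms")


def classification_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent of samples where prediction equals the true class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if len(pred) == 0:
        raise ValueError("empty series")
    return 100.0 * float(np.mean(pred == truth))


def chance_level(
    truth: np.ndarray,
    method: str = "prior_max",
    n_perm: int = 200,
    seed=0,
    pred: np.ndarray | None = None,
) -> float:
    """Chance accuracy (percent) for a label series.

    ``prior_max``: accuracy of always answering the most frequent class.
    ``permutation``: mean accuracy of the given predictions against
    label-shuffled copies of the truth — an empirical chance level that
    accounts for the predictor's own output distribution.
    """
    truth = np.asarray(truth)
    if len(truth) == 0:
        raise ValueError("empty truth")
    if method == "prior_max":
        _, counts = np.unique(truth, return_counts=True)
        return 100.0 * counts.max() / len(truth)
    if method == "permutation":
        if pred is None:
            raise ValueError("permutation chance needs predictions")
        rng = np.random.default_rng(seed)
        accs = [
            classification_accuracy(pred, rng.permutation(truth))
            for _ in range(n_perm)
        ]
        return float(np.mean(accs))
    raise ValueError(f"unknown method {method!r}")


def binomial_significance(accuracy: float, chance: float, n: int) -> float:
    """One-sided exact binomial tail P(X >= k) at success prob chance/100.

    ``k`` is the observed number of correct samples,
    round(accuracy * n / 100).
    """
    if not 0 <= chance < 100:
        raise ValueError("chance must lie in [0, 100)")
    if n < 1:
        raise ValueError("need at least one sample")
    k = int(round(accuracy * n / 100.0))
    return float(stats.binom.sf(k - 1, n, chance / 100.0))


def _round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return np.floor(x * scale + 0.5) / scale


def aggregate_accuracy_table(per_subject: list[float]) -> tuple[float, float]:
    """Mean and population SD of per-subject accuracies, 1-decimal."""
    if not len(per_subject):
        raise ValueError("empty accuracy list")
    arr = np.asarray(per_subject, dtype=float)
    return _round_half_up(arr.mean()), _round_half_up(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# report

@dataclass
class EvaluationReport:
    """Per-subject decoding result for one feature/classifier pair."""

    subject_id: str
    feature_kind: str
    classifier_kind: str
    accuracy_pct: float
    chance_pct: float
    p_value: float
    confusion: list  # 3x3, rows = truth (-1, 0, +1), cols = prediction
    n_test: int
    ungated_accuracy_pct: float = float("nan")
    classifier_config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)


def confusion_matrix3(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    codes = (-1, 0, 1)
    out = np.zeros((3, 3), dtype=int)
    for i, ct in enumerate(codes):
        for j, cp in enumerate(codes):
            out[i, j] = int(np.sum((truth == ct) & (pred == cp)))
    return out


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Study configuration for :func:`run_pipeline`.

    ``sessions`` may list bundle paths; when empty, ``n_subjects``
    synthetic sessions are generated. ``row_stride`` thins the
    delay-embedded rows (stride in EEG samples) before classification;
    the default keeps one row every 4 samples (125 rows/s at 500 Hz).
    """

    sessions: list = field(default_factory=list)
    n_subjects: int = 5
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    null_world: bool = False
    feature_kinds: tuple = FEATURE_KINDS
    combined: bool = False
    classifiers: tuple = ("mlp",)
    lag_ms: float = 250.0
    n_lags: int = 3
    row_stride: int = 4
    train_fraction: float = 0.8
    mlp_epochs: int = 800
    chance_method: str = "prior_max"
    n_perm: int = 100
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)


def extract_feature_series(
    car_rec, kind: str
) -> dict[str, feat.FeatureSeries]:
    """All-channel series of one feature kind from a CAR-corrected recording."""
    if kind == "mrcp":
        series = feat.mrcp_amplitude(car_rec)
    elif kind == "delta_power":
        series = feat.band_power(car_rec, "delta")
    elif kind == "alpha_power":
        series = feat.band_power(car_rec, "alpha")
    elif kind == "rms":
        series = feat.rms_series(car_rec)
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return {s.channel: s for s in series}


def _feature_matrix_for(
    session: SessionBundle,
    kinds: tuple,
    cfg: PipelineConfig,
    series_cache: dict,
) -> feat.FeatureMatrix:
    mats = []
    for kind in kinds:
        by_ch = series_cache[kind]
        chans = feat.select_channels(
            by_ch, session.labels, k=2,
            override=DEFAULT_CHANNEL_OVERRIDES.get(kind),
        )
        m = feat.build_feature_matrix(
            [by_ch[c] for c in chans], lag_ms=cfg.lag_ms, n_lags=cfg.n_lags
        )
        mats.append(m)
    rows = np.hstack([m.rows for m in mats])
    first = mats[0]
    return feat.FeatureMatrix(
        rows=rows,
        channels=tuple(c for m in mats for c in m.channels),
        lag_ms=cfg.lag_ms,
        n_lags=cfg.n_lags,
        fs=first.fs,
        row_index=first.row_index,
    )


def evaluate_session(
    session: SessionBundle,
    feature_kinds: tuple,
    classifier: str,
    cfg: PipelineConfig,
    series_cache: dict | None = None,
    feature_label: str | None = None,
) -> EvaluationReport:
    """Train/test one feature-set x classifier pair on one session.

    CAR -> features -> channel selection -> delay embedding ->
    chronological 80/20 split -> classify -> gate against limb motion ->
    accuracy, chance, binomial p.
    """
    if series_cache is None:
        car = common_average_reference(session.eeg)
        series_cache = {k: extract_feature_series(car, k) for k in feature_kinds}
    fm = _feature_matrix_for(session, feature_kinds, cfg, series_cache)

    rows = fm.rows[:: cfg.row_stride]
    idx = fm.row_index[:: cfg.row_stride]
    y = session.labels[idx]
    tr, te = intent.chronological_split(len(rows), cfg.train_fraction)

    n_inputs = rows.shape[1]
    if classifier == "mlp":
        n_hidden = 80 if len(feature_kinds) > 1 else 30
        spec = intent.MLPSpec(
            n_inputs=n_inputs, n_hidden=n_hidden, epochs=cfg.mlp_epochs,
            seed=cfg.seed,
        )
        model = intent.train_mlp(rows[tr], y[tr], spec)
        cont = intent.predict_continuous(model, rows[te])
        pred = intent.discretize(cont)
        config = {"n_hidden": n_hidden, "epochs": cfg.mlp_epochs}
    elif classifier == "knn":
        model = intent.train_knn(rows[tr], y[tr])
        pred = intent.predict_knn(model, rows[te])
        config = asdict(model.spec)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    moving = intent.limb_motion_flag(session.kin)[idx[te]]
    gated = intent.gate(pred, moving)
    truth = y[te]
    acc = classification_accuracy(gated, truth)
    chance = chance_level(
        truth, cfg.chance_method, n_perm=cfg.n_perm, seed=cfg.seed, pred=gated
    )
    p = binomial_significance(acc, min(chance, 99.999), len(truth))
    return EvaluationReport(
        subject_id=session.subject_id,
        feature_kind=feature_label or "+".join(feature_kinds),
        classifier_kind=classifier,
        accuracy_pct=acc,
        chance_pct=chance,
        p_value=p,
        confusion=confusion_matrix3(truth, gated).tolist(),
        n_test=len(truth),
        ungated_accuracy_pct=classification_accuracy(pred, truth),
        classifier_config=config,
    )


def run_pipeline(
    config: PipelineConfig | str | Path,
    log=None,
) -> list[EvaluationReport]:
    """Run the full study described by a configuration.

    Returns one report per (subject, feature set, classifier). Failures
    are re-raised with the stage and subject named.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    log = log or (lambda msg: print(msg, file=sys.stderr))

    if config.sessions:
        sessions = [read_session(p) for p in config.sessions]
    else:
        syn = null_world(config.synthetic) if config.null_world else config.synthetic
        sessions = generate_study(syn, config.n_subjects, config.seed)

    reports: list[EvaluationReport] = []
    for session in sessions:
        t0 = time.perf_counter()
        try:
            car = common_average_reference(session.eeg)
        except Exception as exc:
            raise RuntimeError(f"[preprocessing] {session.subject_id}: {exc}") from exc
        kinds_needed = set(config.feature_kinds)
        if config.combined:
            kinds_needed = set(FEATURE_KINDS)
        try:
            cache = {k: extract_feature_series(car, k) for k in kinds_needed}
        except Exception as exc:
            raise RuntimeError(f"[features] {session.subject_id}: {exc}") from exc
        log(
            f"{session.subject_id}: features extracted in "
            f"{time.perf_counter() - t0:.1f}s"
        )
        jobs: list[tuple[tuple, str]] = [((k,), k) for k in config.feature_kinds]
        if config.combined:
            jobs.append((FEATURE_KINDS, "combined"))
        for kinds, label in jobs:
            for clf in config.classifiers:
                t1 = time.perf_counter()
                try:
                    rep = evaluate_session(
                        session, kinds, clf, config, series_cache=cache,
                        feature_label=label,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"[classification] {session.subject_id}/{label}/{clf}: {exc}"
                    ) from exc
                reports.append(rep)
                log(
                    f"{session.subject_id} {label:12s} {clf}: "
                    f"acc={rep.accuracy_pct:5.1f}% chance={rep.chance_pct:5.1f}% "
                    f"p={rep.p_value:.2e} ({time.perf_counter() - t1:.1f}s)"
                )
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports; one row per (subject, feature, classifier)."""
    return pd.DataFrame([r.to_dict() for r in reports])


def summary_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Feature x classifier table of mean +- SD accuracy over subjects."""
    df = reports_to_frame(reports)
    rows = []
    for (clf, kind), grp in df.groupby(["classifier_kind", "feature_kind"]):
        mean, sd = aggregate_accuracy_table(grp["accuracy_pct"].tolist())
        rows.append(
            {
                "classifier": clf,
                "feature": kind,
                "mean_accuracy_pct": mean,
                "sd_pct": sd,
                "n_subjects": len(grp),
            }
        )
    return pd.DataFrame(rows)


def plot_prediction_trace(
    times: np.ndarray,
    pred: np.ndarray,
    truth: np.ndarray,
    path: str | Path,
    title: str = "",
) -> Path:
    """Write a continuous prediction-vs-motion trace image.

    Both series use the class coding (+1 lifting, -1 reaching, 0 rest).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(times, truth, lw=1.5, label="subject motion")
    ax.plot(times, pred, lw=0.8, alpha=0.8, label="prediction")
    ax.set_xlabel("time (s)")
    ax.set_yticks([-1, 0, 1])
    ax.set_yticklabels(["reaching", "rest", "lifting"])
    ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def motion_estimation_summary(
    sessions: list[SessionBundle], seed: int = 0, epochs: int = 2000,
    stride: int = 4,
) -> dict:
    """Leave-one-subject-out RMSEs of the stage-two estimators."""
    db = build_motion_database(sessions, stride=stride)
    elbow = loso_rmse(db, "elbow", seed=seed, epochs=epochs)
    endpoint = loso_rmse(db, "endpoint", seed=seed, epochs=epochs)
    return {
        "elbow_rmse_deg": elbow,
        "endpoint_rmse_m": endpoint,
        "elbow_rmse_deg_mean": float(np.mean(list(elbow.values()))),
        "endpoint_rmse_m_mean": float(np.mean(list(endpoint.values()))),
        "n_records": len(db),
    }
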