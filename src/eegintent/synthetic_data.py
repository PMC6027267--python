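"""Synthetic EEG + kinematics sessions with the structure the pipeline assumes.

No public recording of this cue-paced lifting/reaching protocol exists,
so every stage is exercised on simulated sessions that reproduce the
statistical signatures the method relies on:

* a cue schedule with an initial 10 s rest, 20 trials (10 per motion,
  random order) and inter-cue gaps drawn from {5, 6} s;
* event-locked slow negative potentials (MRCP) over FC2/C2 — a
  half-cosine negative ramp rising from 1.5 s before movement onset to a
  class-specific peak at onset, decaying over the movement — with the
  two classes separated by amplitude and by their lateral weighting of
  the FC2/C2 pair;
* a parietal (P3/Pz) alpha oscillation attenuated during movement
  (event-related desynchronization);
* 1/f-shaped background noise on all channels (the difficulty dial:
  raising ``noise_rms_uv`` degrades every feature);
* kinematic templates — minimum-jerk shoulder excursions; a constant,
  fully extended elbow for lifting; a dip-then-extend elbow and an
  endpoint that rises to its plateau within the first 20 degrees of
  shoulder motion for reaching; the return phase mirrors the outbound.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    DEFAULT_CHANNELS,
    ChannelLayout,
    CueSchedule,
    EEGRecording,
    KinematicsTrace,
    SessionBundle,
    label_track_from_schedule,
    resample_to,
)

__all__ = [
    "SyntheticConfig",
    "generate_schedule",
    "generate_kinematics",
    "generate_eeg",
    "generate_session",
    "generate_study",
    "null_world",
]

LIFT, REACH = 1, -1


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; defaults are the study conditions."""

    # protocol
    n_trials: int = 20
    rest_lead_s: float = 10.0
    gap_choices_s: tuple[float, ...] = (5.0, 6.0)
    fs: float = 500.0
    kin_fs: float = 120.0
    tail_s: float = 3.0
    # movement timing
    onset_latency_s: float = 0.4  # audible cue -> movement onset
    movement_dur_s: dict = field(
        default_factory=lambda: {LIFT: 2.0, REACH: 2.4}
    )
    # EEG signatures
    mrcp_amp_uv: dict = field(default_factory=lambda: {LIFT: 8.0, REACH: 12.0})
    mrcp_weights: dict = field(
        default_factory=lambda: {LIFT: {"FC2": 1.0, "C2": 0.8},
                                 REACH: {"FC2": 0.8, "C2": 1.0}}
    )
    mrcp_rise_s: float = 1.5
    alpha_base_uv: float = 10.0
    alpha_freq_hz: float = 10.0
    alpha_atten: float = 0.4  # amplitude factor during movement
    alpha_channels: tuple[str, ...] = ("P3", "Pz")
    alpha_ramp_s: float = 0.3
    noise_rms_uv: float = 5.0
    noise_exponent: float = 1.0
    # kinematic templates
    shoulder_rest_deg: float = 5.0
    shoulder_max_deg: float = 90.0
    elbow_extended_deg: float = 175.0
    reach_dip_depth_deg: float = 50.0
    reach_dip_span_deg: float = 60.0  # elbow back to extended by this shoulder angle
    endpoint_plateau_deg: float = 20.0
    arm_length_m: float = 0.6
    angle_noise_deg: float = 0.5  # Gaussian, clipped at 3 sigma
    # inter-subject template variability (uniform half-ranges)
    subject_amp_jitter: float = 0.2
    subject_elbow_jitter_deg: float = 2.0
    subject_dip_jitter_deg: float = 5.0
    subject_arm_jitter_m: float = 0.03

    def session_duration_s(self, schedule: CueSchedule) -> float:
        last = schedule.events[-1][0] if schedule.events else self.rest_lead_s
        return (
            last + self.onset_latency_s
            + max(self.movement_dur_s.values()) + self.tail_s
        )


def null_world(cfg: SyntheticConfig | None = None) -> SyntheticConfig:
    """The no-signal control: flat MRCP, no alpha attenuation.

    Kinematics (and hence gating and labels) are untouched, so any
    residual decoding accuracy above chance must come from information
    leaks rather than EEG content.
    """
    cfg = cfg or SyntheticConfig()
    return replace(cfg, mrcp_amp_uv={LIFT: 0.0, REACH: 0.0}, alpha_atten=1.0)


# ---------------------------------------------------------------------------
# schedule

def generate_schedule(cfg: SyntheticConfig, seed) -> CueSchedule:
    """Randomized balanced cue schedule under the trial protocol."""
    if cfg.n_trials % 2:
        raise ValueError("unbalanced schedule: n_trials must be even")
    rng = np.random.default_rng(seed)
    order = np.array([LIFT] * (cfg.n_trials // 2) + [REACH] * (cfg.n_trials // 2))
    rng.shuffle(order)
    gaps = rng.choice(cfg.gap_choices_s, size=cfg.n_trials - 1)
    times = cfg.rest_lead_s + np.r_[0.0, np.cumsum(gaps)]
    return CueSchedule(
        events=list(zip(times, order.tolist())), rest_lead_s=cfg.rest_lead_s
    )


# ---------------------------------------------------------------------------
# kinematics

def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3 * u**2 - 2 * u**3


@dataclass(frozen=True)
class _SubjectTemplates:
    """Per-subject perturbation of the kinematic/EEG templates."""

    amp_scale: float = 1.0
    elbow_extended_deg: float = 175.0
    dip_depth_deg: float = 50.0
    arm_length_m: float = 0.6


def _subject_templates(cfg: SyntheticConfig, rng: np.random.Generator) -> _SubjectTemplates:
    return _SubjectTemplates(
        amp_scale=1.0 + rng.uniform(-cfg.subject_amp_jitter, cfg.subject_amp_jitter),
        elbow_extended_deg=cfg.elbow_extended_deg
        + rng.uniform(-cfg.subject_elbow_jitter_deg, cfg.subject_elbow_jitter_deg),
        dip_depth_deg=cfg.reach_dip_depth_deg
        + rng.uniform(-cfg.subject_dip_jitter_deg, cfg.subject_dip_jitter_deg),
        arm_length_m=cfg.arm_length_m
        + rng.uniform(-cfg.subject_arm_jitter_m, cfg.subject_arm_jitter_m),
    )


def _movement_window(cfg: SyntheticConfig, t_cue: float, code: int) -> tuple[float, float]:
    on = t_cue + cfg.onset_latency_s
    return on, on + cfg.movement_dur_s[code]


def _shoulder_excursion(cfg: SyntheticConfig, phase: np.ndarray) -> np.ndarray:
    """Shoulder angle above rest for movement phase in [0, 1]; the return
    mirrors the outbound around the midpoint."""
    out = _minimum_jerk(phase * 2)  # reaches 1 at phase 0.5
    back = _minimum_jerk((1 - phase) * 2)
    rise = cfg.shoulder_max_deg - cfg.shoulder_rest_deg
    return rise * np.where(phase <= 0.5, out, back)


def _reach_elbow(cfg: SyntheticConfig, tpl: _SubjectTemplates, theta_rel: np.ndarray) -> np.ndarray:
    """Dip-then-extend elbow template as a function of shoulder excursion."""
    u = np.clip(theta_rel / cfg.reach_dip_span_deg, 0.0, 1.0)
    return tpl.elbow_extended_deg - tpl.dip_depth_deg * np.sin(np.pi * u)


def generate_kinematics(
    schedule: CueSchedule,
    cfg: SyntheticConfig,
    seed,
    templates: _SubjectTemplates | None = None,
) -> KinematicsTrace:
    """Kinematics at the motion-capture rate for a cue schedule."""
    rng = np.random.default_rng(seed)
    tpl = templates or _SubjectTemplates(
        elbow_extended_deg=cfg.elbow_extended_deg,
        dip_depth_deg=cfg.reach_dip_depth_deg,
        arm_length_m=cfg.arm_length_m,
    )
    n = int(round(cfg.session_duration_s(schedule) * cfg.kin_fs))
    t = np.arange(n) / cfg.kin_fs

    shoulder = np.full(n, cfg.shoulder_rest_deg)
    elbow = np.full(n, tpl.elbow_extended_deg)
    L = tpl.arm_length_m
    rest_xy = np.array([0.0, -L])
    endpoint = np.tile(rest_xy, (n, 1))

    for t_cue, code in schedule.events:
        on, off = _movement_window(cfg, t_cue, code)
        sel = (t >= on) & (t < off)
        phase = (t[sel] - on) / (off - on)
        theta_rel = _shoulder_excursion(cfg, phase)
        shoulder[sel] = cfg.shoulder_rest_deg + theta_rel
        if code == LIFT:
            # straight arm rotating about the shoulder
            th = np.radians(cfg.shoulder_rest_deg + theta_rel)
            endpoint[sel, 0] = L * np.sin(th)
            endpoint[sel, 1] = -L * np.cos(th)
        else:
            elbow[sel] = _reach_elbow(cfg, tpl, theta_rel)
            s = _smoothstep(theta_rel / cfg.endpoint_plateau_deg)
            target_xy = np.array([L, 0.0])
            endpoint[sel, 0] = rest_xy[0] + (target_xy[0] - rest_xy[0]) * s
            endpoint[sel, 1] = rest_xy[1] + (target_xy[1] - rest_xy[1]) * s

    sig = cfg.angle_noise_deg
    if sig > 0:
        clip = 3.0 * sig
        shoulder = shoulder + np.clip(rng.normal(0, sig, n), -clip, clip)
        elbow = elbow + np.clip(rng.normal(0, sig, n), -clip, clip)
        endpoint = endpoint + np.clip(
            rng.normal(0, sig * 2e-3, (n, 2)), -clip * 2e-3, clip * 2e-3
        )
    return KinematicsTrace(
        fs=cfg.kin_fs,
        shoulder_deg=np.clip(shoulder, 0.0, 180.0),
        elbow_deg=np.clip(elbow, 0.0, 180.0),
        endpoint_xy=endpoint,
    )


# ---------------------------------------------------------------------------
# EEG

def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _mrcp_template(cfg: SyntheticConfig, t: np.ndarray, t_cue: float,
                   code: int) -> np.ndarray:
    """Half-cosine negative ramp peaking (most negative) at movement onset."""
    on, off = _movement_window(cfg, t_cue, code)
    rise0 = on - cfg.mrcp_rise_s
    out = np.zeros_like(t)
    rising = (t >= rise0) & (t < on)
    u = (t[rising] - rise0) / cfg.mrcp_rise_s
    out[rising] = -0.5 * (1 - np.cos(np.pi * u))
    decay = (t >= on) & (t < off)
    v = (t[decay] - on) / (off - on)
    out[decay] = -0.5 * (1 + np.cos(np.pi * v))
    return out


def generate_eeg(
    schedule: CueSchedule,
    kin: KinematicsTrace,
    cfg: SyntheticConfig,
    seed,
    templates: _SubjectTemplates | None = None,
) -> EEGRecording:
    """16-channel EEG: 1/f noise + MRCP on FC2/C2 + parietal alpha."""
    rng = np.random.default_rng(seed)
    tpl = templates or _SubjectTemplates()
    layout = ChannelLayout(DEFAULT_CHANNELS)
    n = int(round(len(kin) / kin.fs * cfg.fs))
    t = np.arange(n) / cfg.fs
    data = np.vstack(
        [
            _pink_noise(rng, n, cfg.fs, cfg.noise_exponent, cfg.noise_rms_uv)
            for _ in layout.names
        ]
    )

    # event-locked slow potentials over the fronto-central pair
    mrcp_sum = {ch: np.zeros(n) for ch in ("FC2", "C2")}
    move_env = np.zeros(n)  # 1 inside movement windows (for alpha ERD)
    for t_cue, code in schedule.events:
        shape = _mrcp_template(cfg, t, t_cue, code)
        amp = cfg.mrcp_amp_uv[code] * tpl.amp_scale
        for ch in ("FC2", "C2"):
            mrcp_sum[ch] += amp * cfg.mrcp_weights[code][ch] * shape
        on, off = _movement_window(cfg, t_cue, code)
        ramp = cfg.alpha_ramp_s
        move_env += np.clip((t - on) / ramp, 0, 1) * np.clip((off - t) / ramp, 0, 1)
    move_env = np.clip(move_env, 0.0, 1.0)
    for ch, tr in mrcp_sum.items():
        data[layout.index(ch)] += tr

    # parietal alpha with movement-locked attenuation
    for ch in cfg.alpha_channels:
        phase0 = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + (cfg.alpha_atten - 1.0) * move_env
        data[layout.index(ch)] += (
            cfg.alpha_base_uv
            * envelope
            * np.sin(2 * np.pi * cfg.alpha_freq_hz * t + phase0)
        )
    return EEGRecording(data=data, fs=cfg.fs, layout=layout)


# ---------------------------------------------------------------------------
# full sessions

def generate_session(
    cfg: SyntheticConfig,
    subject_id: str,
    seed,
    subject_index: int = 0,
) -> SessionBundle:
    """One subject's complete labeled session.

    Subject-level template perturbations and all per-session noise are
    derived from ``(seed, subject_index)``, so a study regenerates
    identically from one integer seed.
    """
    ss = np.random.SeedSequence([int(seed), int(subject_index)])
    s_tpl, s_sched, s_kin, s_eeg = ss.spawn(4)
    tpl = _subject_templates(cfg, np.random.default_rng(s_tpl))
    schedule = generate_schedule(cfg, s_sched)
    kin120 = generate_kinematics(schedule, cfg, s_kin, templates=tpl)
    eeg = generate_eeg(schedule, kin120, cfg, s_eeg, templates=tpl)
    kin = resample_to(kin120, eeg.fs, eeg.n_samples)
    labels = label_track_from_schedule(schedule, kin, eeg.n_samples, eeg.fs)
    return SessionBundle(
        subject_id=subject_id, eeg=eeg, schedule=schedule, kin=kin,
        labels=labels,
    )


def generate_study(
    cfg: SyntheticConfig,
    n_subjects: int,
    seed,
) -> list[SessionBundle]:
    """Sessions for ``n_subjects`` subjects named S1..Sn."""
    return [
        generate_session(cfg, f"S{i + 1}", seed, subject_index=i)
        for i in range(n_subjects)
    ]
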