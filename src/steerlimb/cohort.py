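"""Synthetic cohorts of steering trials with known ground truth.

The generator produces trials whose EMG channels are amplitude-modulated
band-limited noise carriers riding on direction-dependent activation
envelopes.  For muscle *i* with gains ``g_cw``/``g_ccw``, lead ``d_ms`` and
baseline ``b``, the true envelope is::

    e_i(t) = max(0, b + tone·u_i(t)
                 + g_cw · max(torque(t + d), 0)
                 + g_ccw · max(-torque(t + d), 0))

where the advance by ``d`` makes muscle activity precede the torque when
``d_ms > 0``, and ``u_i`` is a slow unit-variance fluctuation standing in
for tonic activity that does not track the steering torque.  The raw
channel is ``e_i(t) · sigma_i · w_i(t)`` with ``w_i`` unit-variance Gaussian
noise band-passed to 20-450 Hz.  Ground truth (envelopes, realized gains and
leads) is returned alongside so every downstream stage has a recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import ArmMode, Task, Trial, channel_labels, write_trial
from .errors import ConfigError

#: Surface-EMG carrier band (Hz).
CARRIER_BAND = (20.0, 450.0)

#: Scale of the additive delay jitter: sd = subject_variability * 100 ms.
DELAY_JITTER_SCALE_MS = 100.0

_ANGLE_GAIN = 30.0  # deg per (N*m * s); plumbing only
_ANGLE_LEAK = 0.2  # 1/s


@dataclass(frozen=True)
class MuscleSpec:
    """Generative parameters for one muscle channel."""

    g_cw: float  # gain coupling clockwise torque magnitude to the envelope
    g_ccw: float  # gain for counterclockwise torque
    d_ms: float = 0.0  # lead time; envelope precedes torque when positive
    b: float = 0.02  # baseline envelope, mV
    sigma: float = 1.0  # carrier noise scale (multiplies the envelope)

    def validate(self) -> "MuscleSpec":
        vals = (self.g_cw, self.g_ccw, self.d_ms, self.b, self.sigma)
        if not all(np.isfinite(v) for v in vals):
            raise ConfigError(f"non-finite MuscleSpec field: {self}")
        if self.g_cw < 0 or self.g_ccw < 0 or self.b < 0:
            raise ConfigError("gains and baseline must be >= 0")
        if self.sigma <= 0:
            raise ConfigError("sigma must be > 0")
        return self


def default_muscle_specs() -> tuple[MuscleSpec, ...]:
    """Ten-muscle montage with two prime movers per side, mid-tier helpers,
    and weakly coupled channels; gains in [0.1, 1.0], leads in [-100, 500] ms."""
    rows = [
        (0.60, 0.85, 300.0),
        (0.50, 0.75, 250.0),
        (0.40, 0.45, 150.0),
        (0.45, 0.35, 100.0),
        (0.25, 0.20, 50.0),
        (0.85, 0.55, 300.0),
        (0.75, 0.50, 250.0),
        (0.20, 0.25, 0.0),
        (0.15, 0.15, -50.0),
        (0.10, 0.12, 0.0),
    ]
    return tuple(MuscleSpec(g_cw=c, g_ccw=cc, d_ms=d) for c, cc, d in rows)


@dataclass
class SimulationConfig:
    n_subjects: int
    duration_s: float = 60.0
    fs: float = 1000.0
    task: Task = Task.ACTIVE
    arm_mode: ArmMode = ArmMode.BOTH
    hand_position: str = "0300"
    muscle_specs: tuple[MuscleSpec, ...] = field(default_factory=default_muscle_specs)
    torque_amplitude: float = 2.0  # N*m
    torque_period_s: float = 10.0  # active task steering period
    disturbance_bandwidth_Hz: float = 0.5  # passive task disturbance low-pass corner
    tone_scale: float = 0.1  # mV; tonic fluctuation amplitude shared by all muscles
    tone_bandwidth_Hz: float = 1.0
    subject_variability: float = 0.1  # relative jitter on gains and delays
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.arm_mode = ArmMode(self.arm_mode)
        self.muscle_specs = tuple(self.muscle_specs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def validate(self) -> "SimulationConfig":
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_samples < 1000:
            raise ConfigError("duration_s * fs must be >= 1000 samples")
        if len(self.muscle_specs) != 10:
            raise ConfigError("exactly 10 muscle specs are required")
        for spec in self.muscle_specs:
            spec.validate()
        if not any(s.g_cw + s.g_ccw + s.b > 0 for s in self.muscle_specs):
            raise ConfigError("at least one muscle must have g_cw + g_ccw + b > 0")
        if self.subject_variability < 0 or self.tone_scale < 0:
            raise ConfigError("subject_variability and tone_scale must be >= 0")
        return self


def _unit_variance_noise(rng: np.random.Generator, n: int, sos: np.ndarray) -> np.ndarray:
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _advance(x: np.ndarray, d: int) -> np.ndarray:
    """out[t] = x[t + d] with zero padding at the edges (d may be negative)."""
    out = np.zeros_like(x)
    if d == 0:
        out[:] = x
    elif d > 0:
        out[: x.size - d] = x[d:]
    else:
        out[-d:] = x[: x.size + d]
    return out


def generate_torque(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one trial's torque and angle series.

    Active task: zero-mean sum of two sines with period ``torque_period_s``,
    alternating clockwise/counterclockwise episodes of equal total duration.
    Passive task: band-limited Gaussian disturbance low-passed at
    ``disturbance_bandwidth_Hz``.  The angle is a scaled leaky integral of
    the torque (carried for completeness; unused by the analyses).
    """
    config.validate()
    if config.torque_amplitude <= 0:
        raise ConfigError(f"torque_amplitude must be > 0, got {config.torque_amplitude}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if config.task is Task.ACTIVE:
        t = np.arange(n) / config.fs
        # random starting phase per trial: subjects do not steer in lockstep,
        # and identical waveforms across a cohort would turn estimator
        # quirks into a shared systematic bias
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = 2.0 * np.pi * t / config.torque_period_s + phase
        torque = config.torque_amplitude * (np.sin(theta) + 0.5 * np.sin(2.0 * theta))
    else:
        sos = signal.butter(
            4, config.disturbance_bandwidth_Hz, btype="lowpass", fs=config.fs, output="sos"
        )
        torque = _unit_variance_noise(rng, n, sos) * (config.torque_amplitude / 2.0)
    dt = 1.0 / config.fs
    angle = signal.lfilter([_ANGLE_GAIN * dt], [1.0, -(1.0 - _ANGLE_LEAK * dt)], torque)
    return torque, angle


def generate_emg(
    config: SimulationConfig,
    torque: np.ndarray,
    rng: np.random.Generator | None = None,
    specs: tuple[MuscleSpec, ...] | None = None,
) -> tuple[np.ndarray, dict]:
    """Generate the 10-channel EMG matrix for one trial.

    Returns ``(emg, truth)`` where ``truth`` carries the noise-free
    envelopes (channel x sample) and the specs actually used, for
    recovery tests against ground truth.
    """
    config.validate()
    if config.fs < 1000.0:
        raise ConfigError("fs must be >= 1000 Hz to represent the 20-450 Hz carrier band")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if specs is None:
        specs = config.muscle_specs
    if not any(s.g_cw + s.g_ccw + s.b > 0 for s in specs):
        raise ConfigError("no active muscle: all g_cw + g_ccw + b are zero")
    torque = np.asarray(torque, dtype=float)
    n = torque.size
    sos_carrier = signal.butter(4, CARRIER_BAND, btype="bandpass", fs=config.fs, output="sos")
    sos_tone = signal.butter(
        2, config.tone_bandwidth_Hz, btype="lowpass", fs=config.fs, output="sos"
    )

    emg = np.empty((len(specs), n))
    envelopes = np.empty((len(specs), n))
    for i, spec in enumerate(specs):
        d = int(round(spec.d_ms * config.fs / 1000.0))
        shifted = _advance(torque, d)
        env = spec.b + spec.g_cw * np.maximum(shifted, 0.0) + spec.g_ccw * np.maximum(
            -shifted, 0.0
        )
        if config.tone_scale > 0:
            env = env + config.tone_scale * _unit_variance_noise(rng, n, sos_tone)
        else:
            # keep the stream position deterministic regardless of tone_scale
            rng.standard_normal(n)
        env = np.maximum(env, 0.0)
        carrier = _unit_variance_noise(rng, n, sos_carrier)
        envelopes[i] = env
        emg[i] = env * (spec.sigma * carrier)

    truth = {"envelopes": envelopes, "specs": tuple(specs)}
    return emg, truth


def _jitter_specs(
    specs: tuple[MuscleSpec, ...], variability: float, rng: np.random.Generator
) -> tuple[MuscleSpec, ...]:
    # multiplicative log-normal on gains (stays positive), additive Gaussian on delays
    out = []
    for spec in specs:
        g_cw = spec.g_cw * rng.lognormal(0.0, variability)
        g_ccw = spec.g_ccw * rng.lognormal(0.0, variability)
        d_ms = spec.d_ms + rng.normal(0.0, variability * DELAY_JITTER_SCALE_MS)
        out.append(replace(spec, g_cw=g_cw, g_ccw=g_ccw, d_ms=d_ms))
    return tuple(out)


def generate_cohort(config: SimulationConfig) -> tuple[list[Trial], pd.DataFrame]:
    """Generate ``n_subjects`` trials plus a ground-truth parameter table.

    Per-subject parameters are jittered with seed-derived substreams, so a
    fixed seed yields a byte-identical cohort.
    """
    config.validate()
    if config.torque_amplitude <= 0:
        raise ConfigError("torque_amplitude must be > 0")
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    labels = channel_labels(config.arm_mode)
    trials: list[Trial] = []
    gt_rows = []
    for s_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject_id = f"S{s_idx + 1:02d}"
        specs = _jitter_specs(config.muscle_specs, config.subject_variability, rng)
        torque, angle = generate_torque(config, rng)
        emg, truth = generate_emg(config, torque, rng, specs=specs)
        time = np.arange(config.n_samples) / config.fs
        trial = Trial(
            subject_id=subject_id,
            arm_mode=config.arm_mode,
            hand_position=config.hand_position,
            task=config.task,
            fs=config.fs,
            time=time,
            torque=torque,
            angle=angle,
            emg=emg,
            channel_labels=labels,
        ).validate()
        trials.append(trial)
        for label, spec in zip(labels, truth["specs"]):
            gt_rows.append(
                {
                    "subject_id": subject_id,
                    "muscle": label,
                    "g_cw": spec.g_cw,
                    "g_ccw": spec.g_ccw,
                    "d_ms": spec.d_ms,
                    "b": spec.b,
                    "sigma": spec.sigma,
                }
            )
    return trials, pd.DataFrame(gt_rows)


def write_cohort(trials: list[Trial], ground_truth: pd.DataFrame, out_dir: str | Path) -> None:
    """Write one CSV + meta sidecar per subject plus ``ground_truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial(trial, out_dir / f"{trial.subject_id}.csv")
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, lineterminator="\n")
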