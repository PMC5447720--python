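"""Synthetic paired EMG / kinematics sessions.

Generates two-session recordings with the statistical structure the decoding
pipeline assumes: quasi-rhythmic 4-DoF joint-angle repetitions separated by
short rests, eight nonnegative muscle activations driven linearly by angle
deviations and angular velocities, amplitude-modulated band-limited Gaussian
carriers (hence super-Gaussian active EMG), a diagonally dominant linear
crosstalk mixture, additive Gaussian baseline noise, and a mild per-channel
gain drift applied to the second session only.

The movement templates are minimum-jerk rest->peak->rest profiles.  Four
motion identities (M1..M4) differ in their amplitude/sign pattern over
(SAA, SFE, SPS, EFE) and in per-DoF peak timing, emulating coordinated arm
movements such as hand-to-mouth, hand-to-shoulder and sagittal/coronal arm
raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recordings import DOF_LABELS, EmgRecording, MotionRecording

__all__ = [
    "SimulationConfig",
    "SyntheticSession",
    "generate_motion_trial",
    "activation_from_kinematics",
    "synthesize_emg",
    "generate_session",
    "default_crosstalk_matrix",
    "default_activation_gains",
    "MOTION_TEMPLATES",
]

N_MUSCLES = 8
N_DOFS = 4

MUSCLE_LABELS = (
    "biceps",
    "triceps",
    "deltoid_ant",
    "pectoralis",
    "deltoid_mid",
    "deltoid_post",
    "trapezius",
    "teres_major",
)

# Per motion: peak amplitude in degrees and peak-time fraction for each DoF
# (SAA, SFE, SPS, EFE).  Distinct per-DoF peak timing keeps the four angle
# profiles linearly independent within a trial, so the muscle drive has an
# effective rank of ~4 rather than 1.
MOTION_TEMPLATES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    # hand-to-mouth (drinking): elbow-dominant with shoulder assist
    "M1": {"amplitude": (25.0, 55.0, -45.0, 95.0), "peak_frac": (0.45, 0.40, 0.55, 0.50)},
    # hand to ipsilateral shoulder in the sagittal plane
    "M2": {"amplitude": (8.0, 45.0, -30.0, 120.0), "peak_frac": (0.50, 0.42, 0.58, 0.48)},
    # arm raise in the sagittal plane (shoulder flexion dominant)
    "M3": {"amplitude": (10.0, 150.0, 25.0, 25.0), "peak_frac": (0.50, 0.50, 0.40, 0.35)},
    # arm raise in the coronal plane (shoulder abduction dominant)
    "M4": {"amplitude": (150.0, 12.0, -25.0, 30.0), "peak_frac": (0.50, 0.45, 0.40, 0.60)},
}


def default_crosstalk_matrix(n: int = N_MUSCLES) -> np.ndarray:
    """Diagonally dominant nonnegative mixing matrix.

    Crosstalk decays with electrode distance, modelled here as decay with
    channel-index separation.  Every row's diagonal strictly exceeds the sum
    of its off-diagonal entries.
    """
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = abs(i - j)
            if d == 0:
                m[i, j] = 1.0
            elif d == 1:
                m[i, j] = 0.12
            elif d == 2:
                m[i, j] = 0.05
            else:
                m[i, j] = 0.02
    return m


def default_activation_gains() -> np.ndarray:
    """8 muscles x (4 angle deviations + 4 angular velocities) gain matrix.

    Muscles are arranged as agonist/antagonist pairs per DoF: muscle 2d pulls
    with the positive deviation of angle d, muscle 2d+1 against it, each with
    a small velocity term (concentric/eccentric asymmetry) and a weak
    cross-DoF coupling to the next angle.  Units: 1/deg for angle terms,
    s/deg for velocity terms, giving activations of order one at full range.
    """
    g = np.zeros((N_MUSCLES, 2 * N_DOFS))
    for d in range(N_DOFS):
        ago, ant = 2 * d, 2 * d + 1
        g[ago, d] = 0.014
        g[ant, d] = -0.014
        g[ago, N_DOFS + d] = 0.0012
        g[ant, N_DOFS + d] = -0.0012
        g[ago, (d + 1) % N_DOFS] = 0.004
        g[ant, (d + 1) % N_DOFS] = -0.004
    return g


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic two-session experiment."""

    seed: int = 0
    n_repetitions: int = 15
    rest_duration_s: float = 3.0
    rep_duration_s: float = 2.0
    amp_jitter_frac: float = 0.10
    duration_jitter_frac: float = 0.10
    motion_id: str = "M1"
    emg_rate_hz: int = 1000
    motion_rate_hz: int = 50
    n_channels: int = N_MUSCLES
    crosstalk_matrix: np.ndarray = field(default_factory=default_crosstalk_matrix)
    activation_gain_matrix: np.ndarray = field(default_factory=default_activation_gains)
    tonic_offset: float = 0.0
    baseline_noise_sd: float = 0.05
    inter_session_gain_drift: np.ndarray = field(
        default_factory=lambda: np.array([1.15, 0.88, 1.10, 0.90, 1.12, 0.85, 1.08, 0.92])
    )
    initial_posture_deg: np.ndarray = field(default_factory=lambda: np.zeros(N_DOFS))

    def __post_init__(self) -> None:
        self.crosstalk_matrix = np.asarray(self.crosstalk_matrix, dtype=float)
        self.activation_gain_matrix = np.asarray(self.activation_gain_matrix, dtype=float)
        self.inter_session_gain_drift = np.asarray(self.inter_session_gain_drift, dtype=float)
        self.initial_posture_deg = np.asarray(self.initial_posture_deg, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.motion_id not in MOTION_TEMPLATES:
            raise ValueError(
                f"unknown motion_id {self.motion_id!r}; expected one of "
                f"{sorted(MOTION_TEMPLATES)}"
            )
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.rest_duration_s < 0 or self.rep_duration_s <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.amp_jitter_frac <= 0.15):
            raise ValueError("amp_jitter_frac must lie in [0, 0.15]")
        if self.emg_rate_hz % self.motion_rate_hz != 0:
            raise ValueError("emg_rate_hz must be an integer multiple of motion_rate_hz")
        n = self.n_channels
        c = self.crosstalk_matrix
        if c.shape != (n, n):
            raise ValueError(f"crosstalk_matrix must be {n}x{n}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("crosstalk_matrix must be nonnegative")
        off = c.sum(axis=1) - np.diag(c)
        if np.any(np.diag(c) <= off):
            raise ValueError("crosstalk_matrix must be strictly diagonally dominant by rows")
        if self.activation_gain_matrix.shape != (n, 2 * N_DOFS):
            raise ValueError(
                f"activation_gain_matrix must be {n}x{2 * N_DOFS}, "
                f"got {self.activation_gain_matrix.shape}"
            )
        if self.inter_session_gain_drift.shape != (n,):
            raise ValueError("inter_session_gain_drift must have one factor per channel")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be nonnegative")

    @property
    def upsample_factor(self) -> int:
        return self.emg_rate_hz // self.motion_rate_hz


@dataclass
class SyntheticSession:
    """One generated session: EMG, motion, and bookkeeping the pipeline may
    not see (ground-truth muscle activations)."""

    emg: EmgRecording
    motion: MotionRecording
    ground_truth_activations: np.ndarray | None  # muscles x T_emg, nonnegative
    repetition_intervals: list[tuple[int, int]]  # motion-rate sample indices
    config: SimulationConfig | None = None
    session_index: int = 1


def _min_jerk_rise(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile from 0 to 1 on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def minimum_jerk_bump(tau: np.ndarray, peak_frac: float) -> np.ndarray:
    """Smooth rest->peak->rest profile on tau in [0, 1], peaking at
    ``peak_frac`` with value 1 and zero velocity/acceleration at both ends
    and at the peak."""
    tau = np.asarray(tau, dtype=float)
    rise = _min_jerk_rise(tau / peak_frac)
    fall = _min_jerk_rise((1.0 - tau) / (1.0 - peak_frac))
    return np.where(tau <= peak_frac, rise, fall)


def _trial_rng(config: SimulationConfig, rep_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(stream), int(rep_index), 7919])
    )


def generate_motion_trial(
    config: SimulationConfig, rep_index: int, stream: int = 1
) -> np.ndarray:
    """One movement repetition: 4 x n_samples joint angles (deg) at motion rate.

    Each repetition shares the motion template but draws per-DoF peak
    amplitude jitter (uniform within ±amp_jitter_frac) and an overall
    duration jitter.  The trial starts and ends exactly at the configured
    initial posture.
    """
    if not (0 <= rep_index < config.n_repetitions):
        raise ValueError(f"rep_index {rep_index} out of range")
    tmpl = MOTION_TEMPLATES[config.motion_id]
    rng = _trial_rng(config, rep_index, stream)
    amp_factor = 1.0 + config.amp_jitter_frac * rng.uniform(-1.0, 1.0, size=N_DOFS)
    dur_factor = 1.0 + config.duration_jitter_frac * rng.uniform(-1.0, 1.0)
    duration = config.rep_duration_s * dur_factor
    n = int(round(duration * config.motion_rate_hz)) + 1
    tau = np.linspace(0.0, 1.0, n)
    angles = np.empty((N_DOFS, n))
    for d in range(N_DOFS):
        amp = tmpl["amplitude"][d] * amp_factor[d]
        angles[d] = config.initial_posture_deg[d] + amp * minimum_jerk_bump(
            tau, tmpl["peak_frac"][d]
        )
    return angles


def activation_from_kinematics(
    angles_deg: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Map a 4-DoF angle series (motion rate) to 8 nonnegative muscle
    activations at the EMG rate.

    activation_m(t) = max(0, sum_j G[m, j] * drive_j(t)) + tonic, where the
    drive stacks angle deviations from the initial posture (deg) and angular
    velocities (deg/s, first differences).  The motion-rate result is
    upsampled to the EMG rate by linear interpolation.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.ndim != 2 or angles_deg.shape[0] != N_DOFS:
        raise ValueError(f"angles must be {N_DOFS} x T, got {angles_deg.shape}")
    if not np.all(np.isfinite(angles_deg)):
        raise ValueError("angles contain NaN or Inf")
    dev = angles_deg - config.initial_posture_deg[:, None]
    vel = np.diff(angles_deg, axis=1, prepend=angles_deg[:, :1]) * config.motion_rate_hz
    drive = config.activation_gain_matrix @ np.vstack([dev, vel])
    act = np.maximum(drive, 0.0) + config.tonic_offset

    t_motion = np.arange(angles_deg.shape[1]) / config.motion_rate_hz
    n_emg = angles_deg.shape[1] * config.upsample_factor
    t_emg = np.arange(n_emg) / config.emg_rate_hz
    out = np.empty((config.n_channels, n_emg))
    for m in range(config.n_channels):
        out[m] = np.interp(t_emg, t_motion, act[m])
    return out


def _bandlimited_carriers(
    n_channels: int, n_samples: int, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the surface-EMG band
    (10-400 Hz)."""
    sos = signal.butter(3, [10.0, 400.0], btype="bandpass", fs=rate_hz, output="sos")
    white = rng.standard_normal((n_channels, n_samples))
    carriers = signal.sosfiltfilt(sos, white, axis=1)
    sd = carriers.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return carriers / sd


def synthesize_emg(
    activations: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> EmgRecording:
    """Amplitude-modulate band-limited carriers by the muscle activations and
    mix them through the crosstalk matrix.

    source_m(t) = activation_m(t) * carrier_m(t);
    channel_c(t) = sum_m crosstalk[c, m] * source_m(t) + baseline noise.

    Active-segment sources are super-Gaussian (positive excess kurtosis)
    because the Gaussian carrier is multiplied by a time-varying envelope.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.shape[0] != config.n_channels:
        raise ValueError("activations must have one row per muscle")
    if np.any(activations < 0):
        raise ValueError("activations must be nonnegative")
    n = activations.shape[1]
    carriers = _bandlimited_carriers(config.n_channels, n, config.emg_rate_hz, rng)
    sources = activations * carriers
    mixed = config.crosstalk_matrix @ sources
    if config.baseline_noise_sd > 0:
        mixed = mixed + config.baseline_noise_sd * rng.standard_normal(mixed.shape)
    return EmgRecording(mixed, float(config.emg_rate_hz), MUSCLE_LABELS[: config.n_channels])


def generate_session(config: SimulationConfig, session_index: int = 1) -> SyntheticSession:
    """Assemble a full session: repetitions separated by rest gaps.

    Session 2 applies the configured per-channel gain drift to the EMG,
    emulating electrode/physiology change between sessions; motion templates
    and jitters are redrawn per session (different random stream) as a
    subject never repeats a movement identically.
    """
    if session_index not in (1, 2):
        raise ValueError("session_index must be 1 or 2")
    rest_n = int(round(config.rest_duration_s * config.motion_rate_hz))
    rest_block = np.tile(config.initial_posture_deg[:, None], (1, rest_n))

    segments: list[np.ndarray] = []
    intervals: list[tuple[int, int]] = []
    cursor = 0
    for rep in range(config.n_repetitions):
        trial = generate_motion_trial(config, rep, stream=session_index)
        segments.append(trial)
        intervals.append((cursor, cursor + trial.shape[1]))
        cursor += trial.shape[1]
        if rest_n:
            segments.append(rest_block)
            cursor += rest_n
    angles = np.concatenate(segments, axis=1)

    motion = MotionRecording(
        angles, float(config.motion_rate_hz), DOF_LABELS, intervals
    )
    activations = activation_from_kinematics(angles, config)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(session_index), 104729])
    )
    emg = synthesize_emg(activations, config, rng)
    if session_index == 2:
        emg = EmgRecording(
            emg.samples * config.inter_session_gain_drift[:, None],
            emg.rate_hz,
            emg.channel_labels,
        )
    return SyntheticSession(emg, motion, activations, intervals, config, session_index)
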