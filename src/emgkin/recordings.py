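"""Typed containers for raw and processed recordings.

Two time-series containers travel through the whole pipeline: a multichannel
surface-EMG recording sampled at 1 kHz and a 4-DoF joint-angle recording
sampled at 50 Hz.  Joint angles are expressed in degrees and ordered as
(SAA, SFE, SPS, EFE): shoulder abduction/adduction, shoulder
flexion/extension, shoulder pronation/supination, elbow flexion/extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOF_LABELS: tuple[str, ...] = ("SAA", "SFE", "SPS", "EFE")

DEFAULT_EMG_RATE_HZ = 1000.0
DEFAULT_MOTION_RATE_HZ = 50.0


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or Inf values")


@dataclass
class EmgRecording:
    """Multichannel EMG samples at a fixed rate.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitude in arbitrary units.
    rate_hz : float
        Sampling rate, typically 1000 Hz.
    channel_labels : tuple of str
        One label per channel.
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_EMG_RATE_HZ
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("EMG samples must be a 2-D (channels x time) array")
        _check_finite("EMG samples", self.samples)
        if self.rate_hz <= 0:
            raise ValueError("EMG rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i + 1}" for i in range(self.samples.shape[0])
            )
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def copy(self) -> "EmgRecording":
        return EmgRecording(self.samples.copy(), self.rate_hz, self.channel_labels)


@dataclass
class MotionRecording:
    """4-DoF joint-angle time series at a fixed rate.

    ``repetition_intervals`` holds ``(start, end)`` sample index pairs (at the
    motion rate, end exclusive) marking movement repetitions; the gaps between
    them are rest.
    """

    angles_deg: np.ndarray
    rate_hz: float = DEFAULT_MOTION_RATE_HZ
    dof_labels: tuple[str, ...] = DOF_LABELS
    repetition_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 2:
            raise ValueError("angles must be a 2-D (DoF x time) array")
        _check_finite("joint angles", self.angles_deg)
        if self.rate_hz <= 0:
            raise ValueError("motion rate must be positive")
        if tuple(self.dof_labels) != DOF_LABELS:
            raise ValueError(f"dof_labels must be {DOF_LABELS} in this fixed order")
        for start, end in self.repetition_intervals:
            if not (0 <= start < end <= self.angles_deg.shape[1]):
                raise ValueError(f"repetition interval ({start}, {end}) out of range")

    @property
    def n_dofs(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.angles_deg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def copy(self) -> "MotionRecording":
        return MotionRecording(
            self.angles_deg.copy(),
            self.rate_hz,
            self.dof_labels,
            list(self.repetition_intervals),
        )
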