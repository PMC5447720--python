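"""Windowed MAV features and feature/target alignment and scaling.

The mean absolute value (MAV) of each decomposed EMG component is computed
in 40 ms windows with 50% overlap.  At a 1 kHz EMG rate this yields a 20 ms
hop, i.e. a 50 Hz feature rate that matches the motion sampling rate by
construction.  Windows are causal: each frame's value is stamped with its
window-end time, so no lookahead is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import MotionRecording

__all__ = [
    "FeatureSeries",
    "sliding_mav",
    "align_features_to_motion",
    "TargetScaler",
    "InputScaler",
    "scale_targets",
]

WINDOW_MS = 40.0
OVERLAP_FRACTION = 0.5


@dataclass
class FeatureSeries:
    """MAV per component per frame, with frame-end timestamps."""

    values: np.ndarray  # (k, n_frames), nonnegative
    frame_rate_hz: float
    frame_times_s: np.ndarray  # (n_frames,), window-end times, increasing
    window_ms: float = WINDOW_MS
    overlap_fraction: float = OVERLAP_FRACTION

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def sliding_mav(
    components: np.ndarray,
    rate_hz: float = 1000.0,
    window_ms: float = WINDOW_MS,
    overlap: float = OVERLAP_FRACTION,
) -> FeatureSeries:
    """Mean absolute value over sliding windows.

    Frame ``f`` covers samples ``[f*hop, f*hop + W)`` with ``W`` the window
    length and ``hop = W * (1 - overlap)`` samples; the number of frames is
    ``floor((T - W) / hop) + 1``.
    """
    x = np.atleast_2d(np.asarray(components, dtype=float))
    window = int(round(window_ms * rate_hz / 1000.0))
    hop = int(round(window * (1.0 - overlap)))
    if window < 1 or hop < 1:
        raise ValueError("window and hop must be at least one sample")
    t = x.shape[1]
    if t < window:
        raise ValueError(f"need at least {window} samples for one window, got {t}")
    n_frames = (t - window) // hop + 1
    windows = np.lib.stride_tricks.sliding_window_view(np.abs(x), window, axis=1)
    values = windows[:, ::hop, :][:, :n_frames, :].mean(axis=2)
    frame_times = (np.arange(n_frames) * hop + window) / rate_hz
    return FeatureSeries(values, rate_hz / hop, frame_times, window_ms, overlap)


def align_features_to_motion(
    features: FeatureSeries, motion: MotionRecording
) -> tuple[np.ndarray, np.ndarray]:
    """Pair feature frames one-to-one with motion samples.

    Each frame is paired with the motion sample nearest its window-end time;
    frames whose nearest sample falls outside the motion recording, and
    motion samples never paired (overhang at either end), are dropped.
    Returns ``(X, Y)`` with ``X`` of shape (n_pairs, k) and ``Y`` of shape
    (n_pairs, n_dofs).
    """
    if abs(features.frame_rate_hz - motion.rate_hz) > 1e-9:
        raise ValueError(
            f"feature frame rate {features.frame_rate_hz} Hz does not match "
            f"motion rate {motion.rate_hz} Hz"
        )
    idx = np.rint(features.frame_times_s * motion.rate_hz).astype(int)
    keep = (idx >= 0) & (idx < motion.n_samples)
    if not np.any(keep):
        raise ValueError("feature frames and motion samples do not overlap in time")
    x = features.values[:, keep].T
    y = motion.angles_deg[:, idx[keep]].T
    return x, y


@dataclass
class TargetScaler:
    """Per-DoF min-max scaling of joint angles to the training range.

    Fitted on training rows only; the inverse restores degrees exactly.
    Test-time angles outside the training range map outside [0, 1].
    """

    minimum: np.ndarray
    span: np.ndarray
    labels: tuple[str, ...]

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.minimum) / self.span

    def inverse(self, y_scaled: np.ndarray) -> np.ndarray:
        return y_scaled * self.span + self.minimum

    def to_dict(self) -> dict:
        return {
            "minimum": self.minimum.tolist(),
            "span": self.span.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetScaler":
        return cls(
            np.asarray(d["minimum"], float),
            np.asarray(d["span"], float),
            tuple(d["labels"]),
        )


def scale_targets(
    y_train: np.ndarray, labels: tuple[str, ...] = ("SAA", "SFE", "SPS", "EFE")
) -> tuple[np.ndarray, TargetScaler]:
    """Fit a per-DoF min-max scaler on training targets and apply it."""
    y_train = np.asarray(y_train, dtype=float)
    lo = y_train.min(axis=0)
    hi = y_train.max(axis=0)
    span = hi - lo
    for d, s in enumerate(span):
        if s <= 0:
            name = labels[d] if d < len(labels) else f"DoF {d}"
            raise ValueError(f"target {name} is constant in the training data")
    scaler = TargetScaler(lo, span, tuple(labels))
    return scaler.transform(y_train), scaler


@dataclass
class InputScaler:
    """Z-score standardization of feature columns, fitted on training rows."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x_train: np.ndarray) -> "InputScaler":
        x_train = np.asarray(x_train, dtype=float)
        sd = x_train.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(x_train.mean(axis=0), sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "InputScaler":
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float))
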