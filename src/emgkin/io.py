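"""Session file I/O: paired CSV time series plus a JSON manifest.

A session on disk is a directory with
``emg.csv`` (``time_s`` + one column per EMG channel),
``motion.csv`` (``time_s`` + SAA, SFE, SPS, EFE in degrees),
``reps.csv`` (``rep_start_s``, ``rep_end_s``) and
``manifest.json`` (seed and a full echo of the simulation config, so every
artifact carries its provenance).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import DOF_LABELS, EmgRecording, MotionRecording
from .synth import SimulationConfig, SyntheticSession

__all__ = [
    "write_session",
    "read_session",
    "config_to_dict",
    "config_from_dict",
]


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for key, value in d.items():
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(**d)


def write_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write one session to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emg, motion = session.emg, session.motion

    emg_df = pd.DataFrame({"time_s": emg.times_s})
    for label, row in zip(emg.channel_labels, emg.samples):
        emg_df[label] = row
    emg_df.to_csv(out / "emg.csv", index=False, float_format="%.10g")

    motion_df = pd.DataFrame({"time_s": motion.times_s})
    for label, row in zip(motion.dof_labels, motion.angles_deg):
        motion_df[label] = row
    motion_df.to_csv(out / "motion.csv", index=False, float_format="%.10g")

    reps = np.asarray(session.repetition_intervals, dtype=float)
    reps_df = pd.DataFrame(
        {
            "rep_start_s": reps[:, 0] / motion.rate_hz,
            "rep_end_s": reps[:, 1] / motion.rate_hz,
        }
    )
    reps_df.to_csv(out / "reps.csv", index=False, float_format="%.10g")

    manifest = {
        "session_index": session.session_index,
        "emg_rate_hz": emg.rate_hz,
        "motion_rate_hz": motion.rate_hz,
        "config": config_to_dict(session.config) if session.config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _estimate_rate(times: np.ndarray, what: str) -> float:
    spacing = np.median(np.diff(times))
    if spacing <= 0:
        raise ValueError(f"{what} timestamps are not increasing")
    rate = 1.0 / spacing
    jitter = np.max(np.abs(np.diff(times) - spacing))
    if jitter > 0.01 * spacing:
        raise ValueError(
            f"{what} timestamps are irregular (median rate {rate:.6g} Hz, "
            f"max spacing deviation {jitter:.3g} s)"
        )
    return rate


def read_session(
    emg_path: str | Path,
    motion_path: str | Path,
    reps_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    expected_emg_rate_hz: float = 1000.0,
    expected_motion_rate_hz: float = 50.0,
) -> SyntheticSession:
    """Read a session back from its CSV files with format validation."""
    emg_df = pd.read_csv(emg_path)
    if "time_s" not in emg_df.columns:
        raise ValueError(f"{emg_path}: missing required column 'time_s'")
    channel_cols = [c for c in emg_df.columns if c != "time_s"]
    if not channel_cols:
        raise ValueError(f"{emg_path}: no EMG channel columns found")
    emg_rate = _estimate_rate(emg_df["time_s"].to_numpy(), "EMG")
    if abs(emg_rate - expected_emg_rate_hz) > 2e-4 * expected_emg_rate_hz:
        raise ValueError(
            f"{emg_path}: timestamps imply {emg_rate:.6g} Hz, "
            f"expected {expected_emg_rate_hz:g} Hz"
        )
    samples = emg_df[channel_cols].to_numpy().T
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{emg_path}: EMG samples contain NaN/Inf")
    emg = EmgRecording(samples, expected_emg_rate_hz, tuple(channel_cols))

    motion_df = pd.read_csv(motion_path)
    missing = [c for c in ("time_s", *DOF_LABELS) if c not in motion_df.columns]
    if missing:
        raise ValueError(f"{motion_path}: missing required column(s) {missing}")
    motion_rate = _estimate_rate(motion_df["time_s"].to_numpy(), "motion")
    if abs(motion_rate - expected_motion_rate_hz) > 2e-4 * expected_motion_rate_hz:
        raise ValueError(
            f"{motion_path}: timestamps imply {motion_rate:.6g} Hz, "
            f"expected {expected_motion_rate_hz:g} Hz"
        )
    angles = motion_df[list(DOF_LABELS)].to_numpy().T

    intervals: list[tuple[int, int]] = []
    if reps_path is not None:
        reps_df = pd.read_csv(reps_path)
        missing = [c for c in ("rep_start_s", "rep_end_s") if c not in reps_df.columns]
        if missing:
            raise ValueError(f"{reps_path}: missing required column(s) {missing}")
        intervals = [
            (int(round(s * expected_motion_rate_hz)), int(round(e * expected_motion_rate_hz)))
            for s, e in zip(reps_df["rep_start_s"], reps_df["rep_end_s"])
        ]
    motion = MotionRecording(angles, expected_motion_rate_hz, DOF_LABELS, intervals)

    config = None
    session_index = 1
    if manifest_path is not None and Path(manifest_path).exists():
        manifest = json.loads(Path(manifest_path).read_text())
        session_index = int(manifest.get("session_index", 1))
        if manifest.get("config"):
            config = config_from_dict(manifest["config"])
    return SyntheticSession(emg, motion, None, intervals, config, session_index)


def read_session_dir(session_dir: str | Path) -> SyntheticSession:
    """Read a session directory written by :func:`write_session`."""
    d = Path(session_dir)
    return read_session(
        d / "emg.csv", d / "motion.csv", d / "reps.csv", d / "manifest.json"
    )
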