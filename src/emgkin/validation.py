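"""Cross-validation protocols and the pooled R² performance index.

The score pools squared residuals over all DoFs and samples before forming
the ratio (it is *not* the mean of per-DoF R² values):

    R² = 1 - sum_i sum_t (yhat_i(t) - y_i(t))² / sum_i sum_t (y_i(t) - ybar_i)²

with ybar_i the per-DoF time average of the measured angles.  Two protocols
are provided: intra-session (leave-p-out: the chronologically last p of the
session's repetitions are held out, probing estimation in continued movement
repetitions) and inter-session (train on all of session 1, test on all of
session 2, probing EMG non-stationarity across sessions).  Test data can
additionally be scored on its first half (short-term) and last half
(middle-term) to expose drift of accuracy over the test duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decomposition import IcaModel, PcaModel, fit_ica, fit_pca, project_pca, unmix
from .estimator import TrainingConfig, apply_estimator, fit_estimator
from .features import align_features_to_motion, sliding_mav
from .preprocess import bandpass_emg, lowpass_motion
from .recordings import EmgRecording, MotionRecording
from .synth import SyntheticSession

__all__ = [
    "pooled_r2",
    "global_r2",
    "ValidationSplit",
    "EvaluationReport",
    "make_intra_split",
    "make_inter_split",
    "short_middle_split",
    "split_session_frames",
    "run_validation",
]


def pooled_r2(measured: np.ndarray, estimated: np.ndarray) -> float:
    """Pooled coefficient of determination over a D x N pair of series."""
    y = np.atleast_2d(np.asarray(measured, dtype=float))
    yhat = np.atleast_2d(np.asarray(estimated, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: measured {y.shape} vs estimated {yhat.shape}")
    if y.shape[1] < 1:
        raise ValueError("need at least one sample")
    means = y.mean(axis=1, keepdims=True)
    denom = float(np.sum((y - means) ** 2))
    if denom <= 0:
        raise ValueError("measured series has zero total variance")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / denom


# conventional name in the myoelectric-control literature: the "global R²"
# pooled across all joint angles
global_r2 = pooled_r2


@dataclass
class ValidationSplit:
    """Repetition-level train/test assignment."""

    mode: str  # "intra" | "inter"
    train_rep_indices: list[int]
    test_rep_indices: list[int]
    p: int

    def __post_init__(self) -> None:
        if self.mode not in ("intra", "inter"):
            raise ValueError("mode must be 'intra' or 'inter'")
        if self.mode == "intra" and set(self.train_rep_indices) & set(self.test_rep_indices):
            raise ValueError("intra-session train and test repetitions must be disjoint")


def make_intra_split(
    session: SyntheticSession,
    p: int = 7,
    seed: int | None = None,
    randomize: bool = False,
) -> ValidationSplit:
    """Hold out ``p`` repetitions of one session for testing.

    By default the *last* p repetitions in session order are the test set
    (continued-movement evaluation); ``randomize=True`` draws a seeded
    random subset instead, for sensitivity checks.
    """
    n = len(session.repetition_intervals)
    if not (0 < p < n):
        raise ValueError(f"p must lie in (0, {n}), got {p}")
    reps = list(range(n))
    if randomize:
        rng = np.random.default_rng(seed)
        test = sorted(rng.choice(n, size=p, replace=False).tolist())
    else:
        test = reps[n - p :]
    train = [r for r in reps if r not in test]
    return ValidationSplit("intra", train, test, p)


def make_inter_split(s1: SyntheticSession, s2: SyntheticSession) -> ValidationSplit:
    """Train on every repetition of session 1, test on every repetition of
    session 2."""
    for s, idx in ((s1, 1), (s2, 2)):
        if s.config is None:
            raise ValueError(f"session {idx} carries no config")
    c1, c2 = s1.config, s2.config
    if (
        c1.motion_id != c2.motion_id
        or c1.n_repetitions != c2.n_repetitions
        or c1.emg_rate_hz != c2.emg_rate_hz
        or c1.motion_rate_hz != c2.motion_rate_hz
    ):
        raise ValueError("sessions must share motion_id, repetition count and rates")
    n1 = len(s1.repetition_intervals)
    n2 = len(s2.repetition_intervals)
    return ValidationSplit("inter", list(range(n1)), list(range(n2)), n2)


def short_middle_split(n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the first (short-term) and last (middle-term) halves.

    Splits at floor(F/2); with an odd frame count the extra frame goes to
    the middle-term half.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames to split")
    half = n_frames // 2
    idx = np.arange(n_frames)
    return idx[:half], idx[half:]


def _slice_session(
    emg: EmgRecording, motion: MotionRecording, start: int, end: int
) -> tuple[EmgRecording, MotionRecording]:
    """Cut a motion-sample range [start, end) out of a paired recording."""
    factor = int(round(emg.rate_hz / motion.rate_hz))
    emg_cut = EmgRecording(
        emg.samples[:, start * factor : end * factor], emg.rate_hz, emg.channel_labels
    )
    intervals = [
        (max(s - start, 0), e - start)
        for s, e in motion.repetition_intervals
        if s >= start and e <= end
    ]
    motion_cut = MotionRecording(
        motion.angles_deg[:, start:end], motion.rate_hz, motion.dof_labels, intervals
    )
    return emg_cut, motion_cut


def split_session_frames(
    session: SyntheticSession, split: ValidationSplit
) -> tuple[tuple[EmgRecording, MotionRecording], tuple[EmgRecording, MotionRecording]]:
    """Partition one session's timeline into train and test blocks.

    Repetitions are contiguous in time and each rest gap is attributed to
    the repetition preceding it, so a blocked last-p split cuts the session
    at a single boundary.  Rest frames are retained on both sides.
    """
    if split.mode != "intra":
        raise ValueError("frame splitting applies to intra-session splits")
    first_test = min(split.test_rep_indices)
    if split.test_rep_indices != list(
        range(first_test, len(session.repetition_intervals))
    ):
        raise ValueError("frame splitting requires a blocked (trailing) test set")
    boundary = session.repetition_intervals[first_test][0]
    n = session.motion.n_samples
    return (
        _slice_session(session.emg, session.motion, 0, boundary),
        _slice_session(session.emg, session.motion, boundary, n),
    )


@dataclass
class EvaluationReport:
    """All scores of one validation run plus the provenance needed to redo it."""

    r2_global: float
    r2_per_dof: list[float]
    r2_short_term: float
    r2_middle_term: float
    r2_trajectory: float | None
    n_samples: int
    n_dofs: int
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "r2_global": self.r2_global,
            "r2_per_dof": self.r2_per_dof,
            "r2_short_term": self.r2_short_term,
            "r2_middle_term": self.r2_middle_term,
            "r2_trajectory": self.r2_trajectory,
            "n_samples": self.n_samples,
            "n_dofs": self.n_dofs,
            "meta": self.meta,
        }
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            d["r2_global"],
            list(d["r2_per_dof"]),
            d["r2_short_term"],
            d["r2_middle_term"],
            d["r2_trajectory"],
            int(d["n_samples"]),
            int(d["n_dofs"]),
            d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _prepare(session: SyntheticSession) -> tuple[EmgRecording, MotionRecording]:
    return bandpass_emg(session.emg), lowpass_motion(session.motion)


def run_validation(
    sessions: list[SyntheticSession],
    decomp: str = "ica",
    strategy: str = "smlp",
    mode: str = "intra",
    p: int = 7,
    seed: int = 0,
    variance_threshold: float = 0.95,
    train_cfg: TrainingConfig | None = None,
    chain=None,
    predict_fn=None,
    return_details: bool = False,
):
    """Execute the full decode-and-score pipeline on preprocessed sessions.

    ``sessions`` is ``[session]`` for intra mode or ``[session1, session2]``
    for inter mode.  ``chain`` (a ``KinematicChain``) enables trajectory-level
    scoring of the end-effector.  ``predict_fn`` is a diagnostic hook
    ``(X_train, Y_train, X_test, Y_test) -> predictions`` replacing the MLP
    stage (e.g. an oracle upper bound in tests).
    """
    if decomp not in ("ica", "pca"):
        raise ValueError("decomp must be 'ica' or 'pca'")
    if mode == "intra":
        if len(sessions) != 1:
            raise ValueError("intra mode takes exactly one session")
        emg, motion = _prepare(sessions[0])
        prepared = SyntheticSession(
            emg, motion, sessions[0].ground_truth_activations,
            sessions[0].repetition_intervals, sessions[0].config,
            sessions[0].session_index,
        )
        split = make_intra_split(prepared, p)
        (train_emg, train_motion), (test_emg, test_motion) = split_session_frames(
            prepared, split
        )
    elif mode == "inter":
        if len(sessions) != 2:
            raise ValueError("inter mode takes exactly two sessions")
        split = make_inter_split(sessions[0], sessions[1])
        train_emg, train_motion = _prepare(sessions[0])
        test_emg, test_motion = _prepare(sessions[1])
    else:
        raise ValueError("mode must be 'intra' or 'inter'")

    pca = fit_pca(train_emg, variance_threshold)
    model: PcaModel | IcaModel
    if decomp == "ica":
        model = fit_ica(pca, project_pca(pca, train_emg), seed=seed)
        comps_train = unmix(model, train_emg)
        comps_test = unmix(model, test_emg)
    else:
        model = pca
        comps_train = project_pca(pca, train_emg)
        comps_test = project_pca(pca, test_emg)

    x_train, y_train = align_features_to_motion(
        sliding_mav(comps_train, train_emg.rate_hz), train_motion
    )
    x_test, y_test = align_features_to_motion(
        sliding_mav(comps_test, test_emg.rate_hz), test_motion
    )

    converged = model.converged if isinstance(model, IcaModel) else True
    est = None
    if predict_fn is not None:
        pred = np.asarray(predict_fn(x_train, y_train, x_test, y_test), dtype=float)
    else:
        est = fit_estimator(
            x_train, y_train, strategy, train_cfg or TrainingConfig(seed=seed), model
        )
        pred = apply_estimator(est, x_test)

    r2_glob = pooled_r2(y_test.T, pred.T)
    per_dof = [pooled_r2(y_test[:, d], pred[:, d]) for d in range(y_test.shape[1])]
    first, last = short_middle_split(y_test.shape[0])
    r2_short = pooled_r2(y_test[first].T, pred[first].T)
    r2_middle = pooled_r2(y_test[last].T, pred[last].T)

    r2_traj = None
    if chain is not None:
        from .kinematics import forward_kinematics, trajectory_r2  # avoids a cycle

        r2_traj = trajectory_r2(
            forward_kinematics(chain, y_test.T), forward_kinematics(chain, pred.T)
        )

    report = EvaluationReport(
        r2_glob,
        per_dof,
        r2_short,
        r2_middle,
        r2_traj,
        int(y_test.shape[0]),
        int(y_test.shape[1]),
        meta={
            "mode": mode,
            "decomp": decomp,
            "strategy": strategy,
            "p": split.p,
            "seed": seed,
            "variance_threshold": variance_threshold,
            "n_components": pca.k,
            "ica_converged": bool(converged),
            "train_reps": split.train_rep_indices,
            "test_reps": split.test_rep_indices,
        },
    )
    if return_details:
        return report, {
            "estimator": est,
            "decomposition": model,
            "x_test": x_test,
            "y_test": y_test,
            "pred": pred,
        }
    return report
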