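"""Forward kinematics of the 4-DoF shoulder-elbow chain.

The torso-fixed frame has its origin at the shoulder center: x points to the
subject's right (lateral), y anterior (forward), z up.  In the reference
pose the arm hangs along -z.  The shoulder rotation is the intrinsic
sequence SAA (about the anterior y axis), SFE (about the lateral x axis),
SPS (about the humerus long axis, z); the elbow adds EFE about the
humerus-fixed flexion axis (x).  The wrist is fixed, so the wrist-joint
center is the end-effector:

    p = R_sh [0, 0, -L1]' + R_sh R_x(EFE) [0, 0, -L2]'

All angles are in degrees, lengths in meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .recordings import MotionRecording
from .validation import pooled_r2

__all__ = [
    "KinematicChain",
    "forward_kinematics",
    "trajectory_from_angles",
    "trajectory_r2",
]


@dataclass
class KinematicChain:
    """Segment lengths of the modelled arm (shoulder->elbow, elbow->wrist)."""

    upper_arm_length: float = 0.30
    forearm_length: float = 0.27

    def __post_init__(self) -> None:
        if self.upper_arm_length <= 0 or self.forearm_length <= 0:
            raise ValueError("segment lengths must be positive")


def forward_kinematics(chain: KinematicChain, angles_deg: np.ndarray) -> np.ndarray:
    """End-effector position(s) for angle input (4,) or (4, F).

    Returns shape (3,) or (3, F) in the torso frame (meters).
    """
    a = np.asarray(angles_deg, dtype=float)
    squeeze = a.ndim == 1
    a = a.reshape(4, -1)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    saa, sfe, sps, efe = a
    n = a.shape[1]
    r_sh = Rotation.from_euler("YXZ", np.column_stack([saa, sfe, sps]), degrees=True)
    r_el = Rotation.from_euler("X", efe[:, None], degrees=True)
    upper = np.tile([0.0, 0.0, -chain.upper_arm_length], (n, 1))
    fore = np.tile([0.0, 0.0, -chain.forearm_length], (n, 1))
    pos = r_sh.apply(upper) + (r_sh * r_el).apply(fore)
    return pos[0] if squeeze else pos.T


def trajectory_from_angles(chain: KinematicChain, motion: MotionRecording) -> np.ndarray:
    """Per-frame forward kinematics: 3 x F end-effector trajectory."""
    if motion.n_dofs != 4:
        raise ValueError("motion must have 4 DoFs")
    return forward_kinematics(chain, motion.angles_deg)


def trajectory_r2(measured_traj: np.ndarray, estimated_traj: np.ndarray) -> float:
    """Pooled coefficient of determination over the x, y, z coordinates.

    Same pooled index as the joint-angle score, with the three Cartesian
    coordinates taking the place of the DoFs.
    """
    measured_traj = np.asarray(measured_traj, dtype=float)
    if measured_traj.ndim != 2 or measured_traj.shape[0] != 3:
        raise ValueError("trajectories must be 3 x F")
    return pooled_r2(measured_traj, estimated_traj)
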