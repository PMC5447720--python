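"""Multilayer-perceptron joint-angle regression trained by Levenberg-Marquardt.

The network maps k EMG-component MAV features to joint angles through three
hidden layers of five tanh neurons and a linear output layer.  Two training
strategies are supported: a single multi-output network estimating all four
angles jointly (sMLP) and four single-output networks, one per angle (mMLPs).

Training minimizes the sum-of-squares loss with full-batch
Levenberg-Marquardt: the Jacobian of all residuals with respect to all
weights is computed analytically by back-propagation, and the damped normal
equations ``(J'J + lambda I) dtheta = -J'r`` are solved each step.  The
damping factor interpolates between Gauss-Newton (lambda -> 0) and scaled
gradient descent (lambda -> inf); it shrinks after an accepted step and
grows after a rejected one, so the sequence of accepted losses is strictly
decreasing.  With a few hundred parameters and a few thousand frames the
exact Jacobian is cheap, which is why no stochastic approximation is used.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decomposition import IcaModel, PcaModel, project_pca, unmix
from .features import InputScaler, TargetScaler, scale_targets, sliding_mav
from .recordings import DOF_LABELS, EmgRecording, MotionRecording

__all__ = [
    "MlpNetwork",
    "TrainingConfig",
    "TrainedEstimator",
    "init_network",
    "forward",
    "train_lm",
    "fit_estimator",
    "predict",
    "predict_frames",
    "estimator_checksum",
]

HIDDEN_LAYERS = (5, 5, 5)


@dataclass
class MlpNetwork:
    """Feed-forward network: tanh hidden layers, linear output."""

    weights: list[np.ndarray]  # weights[l]: (n_{l-1}, n_l)
    biases: list[np.ndarray]  # biases[l]: (n_l,)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    def unpack(self, theta: np.ndarray) -> None:
        pos = 0
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[i] = theta[pos : pos + w.size].reshape(w.shape)
            pos += w.size
            self.biases[i] = theta[pos : pos + b.size].copy()
            pos += b.size

    def copy(self) -> "MlpNetwork":
        return MlpNetwork([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlpNetwork":
        return cls(
            [np.asarray(w, float) for w in d["weights"]],
            [np.asarray(b, float) for b in d["biases"]],
        )


@dataclass
class TrainingConfig:
    """Levenberg-Marquardt hyperparameters (all scale-free)."""

    seed: int = 0
    max_epochs: int = 200
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 0.1
    grad_tol: float = 1e-7
    loss_tol: float = 1e-10

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.lm_lambda_init, self.grad_tol, self.loss_tol) <= 0:
            raise ValueError("training parameters must be positive")
        if not (self.lm_lambda_up > 1.0 > self.lm_lambda_down > 0.0):
            raise ValueError("need lm_lambda_up > 1 > lm_lambda_down > 0")


def init_network(n_in: int, n_out: int, seed: int) -> MlpNetwork:
    """Seeded uniform initialization in +-1/sqrt(fan_in) per layer."""
    sizes = (n_in, *HIDDEN_LAYERS, n_out)
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(a)
        weights.append(rng.uniform(-bound, bound, size=(a, b)))
        biases.append(rng.uniform(-bound, bound, size=b))
    return MlpNetwork(weights, biases)


def _forward_cached(net: MlpNetwork, x: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer, input included (last layer linear)."""
    acts = [np.asarray(x, dtype=float)]
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = acts[-1] @ w + b
        acts.append(z if l == n_layers - 1 else np.tanh(z))
    return acts


def forward(net: MlpNetwork, x: np.ndarray) -> np.ndarray:
    """Feed-forward prediction: (F, n_in) -> (F, n_out)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"input must be (F, {net.layer_sizes[0]}), got {x.shape}"
        )
    return _forward_cached(net, x)[-1]


def _jacobian(net: MlpNetwork, acts: list[np.ndarray]) -> np.ndarray:
    """Analytic Jacobian of network outputs w.r.t. all parameters.

    Returns shape (F * n_out, n_params), residual-major in sample order.
    """
    f = acts[0].shape[0]
    n_out = acts[-1].shape[1]
    n_layers = len(net.weights)
    # deltas[l][f, o, j] = d out[f, o] / d z_l[f, j]
    deltas: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    deltas[-1] = np.broadcast_to(np.eye(n_out), (f, n_out, n_out)).copy()
    for l in range(n_layers - 2, -1, -1):
        back = deltas[l + 1] @ net.weights[l + 1].T  # (F, n_out, n_l)
        deltas[l] = back * (1.0 - acts[l + 1] ** 2)[:, None, :]
    blocks = []
    for l in range(n_layers):
        jw = np.einsum("fi,foj->foij", acts[l], deltas[l]).reshape(f, n_out, -1)
        blocks.append(jw)
        blocks.append(deltas[l])
    return np.concatenate(blocks, axis=2).reshape(f * n_out, net.n_params)


def train_lm(
    net: MlpNetwork,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig | None = None,
) -> tuple[MlpNetwork, list[float]]:
    """Full-batch Levenberg-Marquardt training.

    Returns the trained network and the loss log (sum of squared residuals
    after each accepted step, initial loss first); the logged sequence is
    strictly decreasing by construction.
    """
    cfg = cfg or TrainingConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    net = net.copy()
    if x.shape[0] < net.n_params / 10:
        warnings.warn(
            f"only {x.shape[0]} training rows for {net.n_params} parameters; "
            "the fit is badly underdetermined",
            RuntimeWarning,
            stacklevel=2,
        )

    theta = net.pack()
    acts = _forward_cached(net, x)
    r = (acts[-1] - y).ravel()
    loss = float(r @ r)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss at initialization")
    log = [loss]
    lam = cfg.lm_lambda_init
    eye = np.eye(net.n_params)

    for _ in range(cfg.max_epochs):
        if loss <= cfg.loss_tol:
            break
        jac = _jacobian(net, acts)
        grad = jac.T @ r
        if np.max(np.abs(grad)) < cfg.grad_tol:
            break
        hess = jac.T @ jac
        accepted = False
        while lam < 1e12:
            try:
                step = np.linalg.solve(hess + lam * eye, -grad)
            except np.linalg.LinAlgError:
                lam *= cfg.lm_lambda_up
                continue
            trial = theta + step
            net.unpack(trial)
            trial_acts = _forward_cached(net, x)
            trial_r = (trial_acts[-1] - y).ravel()
            trial_loss = float(trial_r @ trial_r)
            if np.isfinite(trial_loss) and trial_loss < loss:
                theta, acts, r, loss = trial, trial_acts, trial_r, trial_loss
                lam = max(lam * cfg.lm_lambda_down, 1e-15)
                log.append(loss)
                accepted = True
                break
            lam *= cfg.lm_lambda_up
        if not accepted:
            break  # damping exhausted: stationary point to working precision
    net.unpack(theta)
    return net, log


@dataclass
class TrainedEstimator:
    """Frozen end-to-end decoder: decomposition + scalers + network(s)."""

    strategy: str  # "smlp" | "mmlps"
    networks: list[MlpNetwork]
    decomposition: PcaModel | IcaModel | None
    input_scaler: InputScaler
    target_scaler: TargetScaler
    training_logs: list[list[float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("smlp", "mmlps"):
            raise ValueError("strategy must be 'smlp' or 'mmlps'")
        n_expected = 1 if self.strategy == "smlp" else len(DOF_LABELS)
        if len(self.networks) != n_expected:
            raise ValueError(
                f"{self.strategy} requires {n_expected} network(s), got {len(self.networks)}"
            )

    def to_dict(self) -> dict:
        dec: dict | None = None
        if isinstance(self.decomposition, IcaModel):
            dec = {"kind": "ica", "model": self.decomposition.to_dict()}
        elif isinstance(self.decomposition, PcaModel):
            dec = {"kind": "pca", "model": self.decomposition.to_dict()}
        return {
            "strategy": self.strategy,
            "networks": [n.to_dict() for n in self.networks],
            "decomposition": dec,
            "input_scaler": self.input_scaler.to_dict(),
            "target_scaler": self.target_scaler.to_dict(),
            "training_logs": self.training_logs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedEstimator":
        dec = d.get("decomposition")
        decomposition: PcaModel | IcaModel | None = None
        if dec is not None:
            decomposition = (
                IcaModel.from_dict(dec["model"])
                if dec["kind"] == "ica"
                else PcaModel.from_dict(dec["model"])
            )
        return cls(
            d["strategy"],
            [MlpNetwork.from_dict(n) for n in d["networks"]],
            decomposition,
            InputScaler.from_dict(d["input_scaler"]),
            TargetScaler.from_dict(d["target_scaler"]),
            [list(map(float, log)) for log in d["training_logs"]],
            int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEstimator":
        return cls.from_dict(json.loads(Path(path).read_text()))


def estimator_checksum(est: TrainedEstimator) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(est.to_dict(), sort_keys=True).encode())
    return h.hexdigest()


def fit_estimator(
    x: np.ndarray,
    y: np.ndarray,
    strategy: str = "smlp",
    cfg: TrainingConfig | None = None,
    decomposition: PcaModel | IcaModel | None = None,
) -> TrainedEstimator:
    """Fit scalers and network(s) on aligned training features/angles.

    ``x`` is (F, k) raw MAV features; ``y`` is (F, 4) angles in degrees.
    sMLP trains one (k, 5, 5, 5, 4) network; mMLPs trains four
    (k, 5, 5, 5, 1) networks with per-DoF seed offsets so the four
    initializations differ.
    """
    cfg = cfg or TrainingConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(DOF_LABELS):
        raise ValueError(f"Y must have {len(DOF_LABELS)} columns")
    input_scaler = InputScaler.fit(x)
    xs = input_scaler.transform(x)
    ys, target_scaler = scale_targets(y)

    networks: list[MlpNetwork] = []
    logs: list[list[float]] = []
    if strategy == "smlp":
        net = init_network(x.shape[1], y.shape[1], cfg.seed)
        net, log = train_lm(net, xs, ys, cfg)
        networks.append(net)
        logs.append(log)
    elif strategy == "mmlps":
        for d in range(y.shape[1]):
            dof_cfg = TrainingConfig(
                seed=cfg.seed + d,
                max_epochs=cfg.max_epochs,
                lm_lambda_init=cfg.lm_lambda_init,
                lm_lambda_up=cfg.lm_lambda_up,
                lm_lambda_down=cfg.lm_lambda_down,
                grad_tol=cfg.grad_tol,
                loss_tol=cfg.loss_tol,
            )
            net = init_network(x.shape[1], 1, dof_cfg.seed)
            net, log = train_lm(net, xs, ys[:, d], dof_cfg)
            networks.append(net)
            logs.append(log)
    else:
        raise ValueError("strategy must be 'smlp' or 'mmlps'")
    return TrainedEstimator(
        strategy, networks, decomposition, input_scaler, target_scaler, logs, cfg.seed
    )


def _estimator_outputs(est: TrainedEstimator, xs: np.ndarray) -> np.ndarray:
    if est.strategy == "smlp":
        return forward(est.networks[0], xs)
    return np.column_stack([forward(net, xs)[:, 0] for net in est.networks])


def apply_estimator(est: TrainedEstimator, x_raw: np.ndarray) -> np.ndarray:
    """Raw MAV features (F, k) -> angle estimates in degrees (F, 4)."""
    xs = est.input_scaler.transform(np.asarray(x_raw, dtype=float))
    return est.target_scaler.inverse(_estimator_outputs(est, xs))


def predict_frames(
    est: TrainedEstimator, emg: EmgRecording
) -> tuple[np.ndarray, np.ndarray]:
    """Run the frozen chain on (already band-pass filtered) EMG.

    Returns ``(frame_times_s, angles_deg)`` with angles of shape (F, 4).
    """
    if est.decomposition is None:
        raise ValueError("estimator has no decomposition model attached")
    if isinstance(est.decomposition, IcaModel):
        comps = unmix(est.decomposition, emg)
    else:
        comps = project_pca(est.decomposition, emg)
    feats = sliding_mav(comps, emg.rate_hz)
    return feats.frame_times_s, apply_estimator(est, feats.values.T)


def predict(est: TrainedEstimator, emg: EmgRecording) -> tuple[MotionRecording, np.ndarray]:
    """Estimate the 4-DoF angle trajectory (50 Hz) from filtered EMG.

    Returns the estimated ``MotionRecording`` together with the frame
    timestamps (window-end times, seconds).  Pure function of the frozen
    estimator and the input: repeated calls give identical output.
    """
    times, angles = predict_frames(est, emg)
    motion = MotionRecording(angles.T, rate_hz=1.0 / (times[1] - times[0]))
    return motion, times
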