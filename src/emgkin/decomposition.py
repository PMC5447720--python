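"""PCA dimension reduction and ICA unmixing of multichannel EMG.

Both transforms are fitted on *training* EMG only and then frozen: test-time
calls apply the stored channel means, projection, whitening scales and
unmixing matrix without updating any statistic.  PCA retains the smallest
number of components whose cumulative eigenvalue fraction reaches the
variance threshold (default 95%).  ICA runs a fixed-point negentropy
maximization (log-cosh contrast, symmetric decorrelation) on the whitened
principal components — whitening reuses the PCA eigenvalues, so ICA is
strictly a rotation on top of the PCA subspace.

Because ICA is intrinsically permutation- and sign-ambiguous, recovered
components are put in a reproducible canonical form: ordered by the variance
each component explains when back-projected into channel space, with the
sign chosen so the largest-magnitude channel loading of each component is
positive.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .recordings import EmgRecording

__all__ = [
    "PcaModel",
    "IcaModel",
    "fit_pca",
    "project_pca",
    "components_for_variance",
    "fit_ica",
    "unmix",
    "amari_index",
    "model_checksum",
]


def components_for_variance(eigenvalues: np.ndarray, threshold: float) -> int:
    """Smallest k whose cumulative eigenvalue fraction reaches ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("variance threshold must lie in (0, 1]")
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < -1e-12 * max(1.0, ev.max(initial=0.0))):
        raise ValueError("eigenvalues must be nonnegative")
    total = ev.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    frac = np.cumsum(ev) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


@dataclass
class PcaModel:
    """Training-fitted PCA: channel means, orthonormal projection, spectrum."""

    channel_means: np.ndarray  # (n_channels,)
    projection: np.ndarray  # (k, n_channels), rows orthonormal
    eigenvalues: np.ndarray  # all n_channels eigenvalues, descending
    variance_threshold: float
    k: int

    def to_dict(self) -> dict:
        return {
            "channel_means": self.channel_means.tolist(),
            "projection": self.projection.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_threshold": self.variance_threshold,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            np.asarray(d["channel_means"], dtype=float),
            np.asarray(d["projection"], dtype=float),
            np.asarray(d["eigenvalues"], dtype=float),
            float(d["variance_threshold"]),
            int(d["k"]),
        )


@dataclass
class IcaModel:
    """Training-fitted ICA on top of an owned, frozen PCA model."""

    pca: PcaModel
    unmixing: np.ndarray  # (k, k), applied to whitened principal components
    component_order: np.ndarray  # permutation applied to raw ICA rows
    component_signs: np.ndarray  # +/-1 per (reordered) component
    converged: bool = True
    n_iter: int = 0
    seed: int = 0
    identifiable: bool = True

    @property
    def k(self) -> int:
        return self.pca.k

    @property
    def whitening_scales(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.pca.eigenvalues[: self.k])

    @property
    def channel_space_unmixing(self) -> np.ndarray:
        """k x n_channels matrix mapping centered channels to ICs."""
        return (self.unmixing * self.whitening_scales) @ self.pca.projection

    def to_dict(self) -> dict:
        return {
            "pca": self.pca.to_dict(),
            "unmixing": self.unmixing.tolist(),
            "component_order": self.component_order.tolist(),
            "component_signs": self.component_signs.tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "seed": int(self.seed),
            "identifiable": bool(self.identifiable),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IcaModel":
        return cls(
            PcaModel.from_dict(d["pca"]),
            np.asarray(d["unmixing"], dtype=float),
            np.asarray(d["component_order"], dtype=int),
            np.asarray(d["component_signs"], dtype=float),
            bool(d["converged"]),
            int(d["n_iter"]),
            int(d["seed"]),
            bool(d.get("identifiable", True)),
        )


def save_model(model: PcaModel | IcaModel, path: str | Path) -> None:
    kind = "ica" if isinstance(model, IcaModel) else "pca"
    Path(path).write_text(json.dumps({"kind": kind, "model": model.to_dict()}, indent=1))


def load_model(path: str | Path) -> PcaModel | IcaModel:
    d = json.loads(Path(path).read_text())
    cls = IcaModel if d["kind"] == "ica" else PcaModel
    return cls.from_dict(d["model"])


def model_checksum(model: PcaModel | IcaModel) -> str:
    """Stable digest of every fitted array; used to assert the
    frozen-transform contract (no statistic updated at test time)."""
    h = hashlib.sha256()
    h.update(json.dumps(model.to_dict(), sort_keys=True).encode())
    return h.hexdigest()


def fit_pca(train_emg: EmgRecording, variance_threshold: float = 0.95) -> PcaModel:
    """Fit PCA on training EMG and pick k for the variance threshold.

    Eigen-decomposes the sample covariance (ddof=1).  Components with
    non-positive eigenvalues (rank deficiency) are never retained.
    """
    x = train_emg.samples
    n_ch, t = x.shape
    if t < n_ch:
        raise ValueError(f"need at least {n_ch} samples to fit PCA, got {t}")
    means = x.mean(axis=1)
    xc = x - means[:, None]
    cov = (xc @ xc.T) / (t - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(n_ch):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    k = components_for_variance(eigvals, variance_threshold)
    k = min(k, int(np.sum(eigvals > 0)))
    return PcaModel(means, eigvecs[:, :k].T.copy(), eigvals, variance_threshold, k)


def project_pca(model: PcaModel, emg: EmgRecording) -> np.ndarray:
    """Project EMG onto the training-fitted subspace: k x T component series."""
    if emg.n_channels != model.channel_means.shape[0]:
        raise ValueError(
            f"expected {model.channel_means.shape[0]} channels, got {emg.n_channels}"
        )
    return model.projection @ (emg.samples - model.channel_means[:, None])


def _whiten(model: PcaModel, components: np.ndarray) -> np.ndarray:
    scales = np.sqrt(model.eigenvalues[: model.k])
    if np.any(scales <= 0):
        raise ValueError("cannot whiten: retained eigenvalue is not positive")
    return components / scales[:, None]


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(w @ w.T)
    if np.any(s <= 0):
        raise np.linalg.LinAlgError("degenerate unmixing iterate")
    return (u * (1.0 / np.sqrt(s))) @ u.T @ w


def fit_ica(
    pca: PcaModel,
    train_components: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> IcaModel:
    """Negentropy-maximizing fixed-point ICA on whitened PCA components.

    Uses the log-cosh contrast (g = tanh, a = 1) with symmetric (parallel)
    decorrelation.  If the fixed-point iteration does not reach ``tol``
    within ``max_iter`` sweeps a warning is raised and the best iterate is
    returned with ``converged=False``.  Independently of convergence, the
    model is flagged ``identifiable=False`` when no recovered component's
    log-cosh contrast differs from the Gaussian expectation beyond sampling
    noise (for Gaussian sources the rotation is undetermined).
    """
    k = pca.k
    x = np.asarray(train_components, dtype=float)
    if x.shape[0] != k:
        raise ValueError(f"expected {k} component rows, got {x.shape[0]}")
    xw = _whiten(pca, x)
    t = xw.shape[1]

    rng = np.random.default_rng(seed)
    w = rng.standard_normal((k, k))
    w = _sym_decorrelate(w)

    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        wx = w @ xw
        g = np.tanh(wx)
        g_prime = 1.0 - g**2
        w_new = (g @ xw.T) / t - g_prime.mean(axis=1)[:, None] * w
        w_new = _sym_decorrelate(w_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0)))
        w = w_new
        if delta < tol:
            converged = True
            n_iter = it
            break
    if not converged:
        warnings.warn(
            f"ICA fixed-point iteration did not converge in {max_iter} sweeps "
            "(sources may be non-identifiable, e.g. Gaussian); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    # identifiability: a component is informative only if its log-cosh
    # contrast deviates from the Gaussian expectation beyond sampling noise
    gauss_expectation = 0.374567207491438  # E[log cosh nu], nu ~ N(0, 1)
    y = w @ xw
    logcosh = np.log(np.cosh(y))
    deviation = np.abs(logcosh.mean(axis=1) - gauss_expectation)
    noise_scale = 5.0 * logcosh.std(axis=1) / np.sqrt(t)
    identifiable = bool(np.any(deviation > noise_scale))
    if not identifiable:
        warnings.warn(
            "no component shows non-Gaussian structure beyond sampling noise; "
            "the ICA rotation is not identifiable",
            RuntimeWarning,
            stacklevel=2,
        )

    # canonical form: order by back-projected channel-space variance,
    # sign by the largest-magnitude channel loading
    scales = np.sqrt(pca.eigenvalues[:k])
    loadings = pca.projection.T @ (scales[:, None] * w.T)  # n_channels x k
    power = np.sum(loadings**2, axis=0)
    order = np.argsort(power)[::-1]
    signs = np.ones(k)
    for j_out, j in enumerate(order):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            signs[j_out] = -1.0
    unmixing = (signs[:, None] * w[order])
    return IcaModel(
        pca, unmixing, order.astype(int), signs, converged, n_iter, seed, identifiable
    )


def unmix(model: IcaModel, emg: EmgRecording) -> np.ndarray:
    """Apply the frozen PCA projection, whitening and ICA rotation: k x T ICs."""
    comps = project_pca(model.pca, emg)
    return model.unmixing @ _whiten(model.pca, comps)


def amari_index(p: np.ndarray) -> float:
    """Permutation- and scale-invariant distance of ``p`` from a scaled
    permutation matrix; 0 iff each row and column has a single nonzero entry.

    index = (1/k) * [ sum_i (sum_j |p_ij| / max_j |p_ij| - 1)
                    + sum_j (sum_i |p_ij| / max_i |p_ij| - 1) ]
    """
    a = np.abs(np.asarray(p, dtype=float))
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("Amari index requires a square matrix")
    row_max = a.max(axis=1)
    col_max = a.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("matrix has an all-zero row or column")
    k = a.shape[0]
    row_term = float(np.sum(a.sum(axis=1) / row_max - 1.0))
    col_term = float(np.sum(a.sum(axis=0) / col_max - 1.0))
    return (row_term + col_term) / k
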