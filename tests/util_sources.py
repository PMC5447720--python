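"""Shared helpers for building amplitude-modulated super-Gaussian sources
with a known mixing matrix (ICA recovery oracles)."""

import numpy as np
from scipy import signal


def smooth_envelope(n: int, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative slowly varying envelope (low-pass filtered noise, rectified).

    The 3 Hz bandwidth matches the timescale of muscle-activation bursts
    during movements lasting a couple of seconds.
    """
    sos = signal.butter(2, 3.0, btype="lowpass", fs=rate_hz, output="sos")
    env = signal.sosfiltfilt(sos, rng.standard_normal(n))
    env = np.abs(env)
    return env / env.std()


def am_sources(
    n_sources: int, n: int, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent amplitude-modulated band-limited sources (super-Gaussian)."""
    sos = signal.butter(3, [10.0, 400.0], btype="bandpass", fs=rate_hz, output="sos")
    out = np.empty((n_sources, n))
    for i in range(n_sources):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        out[i] = smooth_envelope(n, rate_hz, rng) * carrier
    return out


def dominant_mixing(
    n_channels: int, n_sources: int, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative mixing where each source dominates its own channels."""
    a = 0.1 * rng.uniform(0.2, 1.0, size=(n_channels, n_sources))
    for j in range(n_sources):
        a[j % n_channels, j] += 1.0
        a[(j + n_sources) % n_channels, j] += 0.7
    return a
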