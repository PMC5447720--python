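"""Zero-phase Butterworth conditioning of EMG and motion signals.

EMG is band-pass filtered with an order-6 Butterworth (10-400 Hz); joint
angles are low-pass filtered with an order-2 Butterworth at 6 Hz.  Both are
applied forward-backward (``sosfiltfilt``): processing is offline, and zero
phase keeps EMG and motion aligned in time.  The forward-backward pass
squares the magnitude response, so effective stopband attenuation doubles
(in dB) relative to a single pass.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recordings import EmgRecording, MotionRecording

EMG_BAND_HZ = (10.0, 400.0)
EMG_FILTER_ORDER = 6  # overall band-pass order (3 poles per edge)
MOTION_CUTOFF_HZ = 6.0
MOTION_FILTER_ORDER = 2


def _check_band(low: float, high: float, rate_hz: float) -> None:
    nyq = rate_hz / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"cutoffs ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )


def bandpass_emg(emg: EmgRecording) -> EmgRecording:
    """Band-pass filter every EMG channel to 10-400 Hz, zero-phase.

    Output length equals input length; DC and low-frequency motion artifact
    fall in the stopband.
    """
    _check_band(*EMG_BAND_HZ, emg.rate_hz)
    sos = signal.butter(
        EMG_FILTER_ORDER // 2, EMG_BAND_HZ, btype="bandpass", fs=emg.rate_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, emg.samples, axis=1)
    return EmgRecording(filtered, emg.rate_hz, emg.channel_labels)


def lowpass_motion(motion: MotionRecording) -> MotionRecording:
    """Low-pass filter joint angles at 6 Hz (order 2, zero-phase).

    Voluntary arm kinematics live well below 6 Hz; this removes residual
    sample-level jitter while preserving the movement profile.
    """
    nyq = motion.rate_hz / 2.0
    if MOTION_CUTOFF_HZ >= nyq:
        raise ValueError(f"cutoff {MOTION_CUTOFF_HZ} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(
        MOTION_FILTER_ORDER, MOTION_CUTOFF_HZ, btype="lowpass", fs=motion.rate_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, motion.angles_deg, axis=1)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("filtering produced non-finite values")
    return MotionRecording(
        filtered, motion.rate_hz, motion.dof_labels, list(motion.repetition_intervals)
    )
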