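"""Per-frame time-weighted sound level metering.

The meter applies exponential ("fast", tau = 125 ms) time weighting to the
squared signal and reports 10*log10 of the frame-averaged mean square,
referenced to digital full scale, plus a user calibration offset.  The
calibration offset is how readings are tied to physical dB SPL: the user
matches the app's reading against an external meter once and stores the
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core_model import InvalidInputError


@dataclass
class SplState:
    """Running state of the exponential level detector."""

    time_weighting_tau_s: float = 0.125
    mean_square: float = 0.0
    floor_db: float = -120.0

    def __post_init__(self) -> None:
        if self.time_weighting_tau_s <= 0:
            raise InvalidInputError("time weighting tau must be positive")
        if self.mean_square < 0:
            raise InvalidInputError("running mean square must be non-negative")


def _smoothed_mean_square(samples: np.ndarray, state: SplState, fs: float) -> np.ndarray:
    """Per-sample exponentially time-weighted mean square, continuing state."""
    a = math.exp(-1.0 / (fs * state.time_weighting_tau_s))
    # y[n] = (1-a) x[n]^2 + a y[n-1]
    ms, _ = lfilter([1.0 - a], [1.0, -a], samples.astype(np.float64) ** 2,
                    zi=[a * state.mean_square])
    return ms


def spl_frame(samples: np.ndarray, state: SplState,
              calibration_offset_db: float = 0.0,
              fs: float = 48000.0) -> tuple[float, SplState]:
    """Meter one frame; returns (reading in dB, updated state).

    The reading is the frame average of the time-weighted mean square in
    dB re full scale, clamped at ``state.floor_db`` before the calibration
    offset is added.  State carries across frames, so consecutive frames
    form one continuous level trace.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise InvalidInputError("cannot meter an empty frame")
    if not np.all(np.isfinite(samples)):
        raise InvalidInputError("frame contains non-finite samples")
    ms = _smoothed_mean_square(samples, state, fs)
    mean_ms = float(np.mean(ms))
    floor_power = 10.0 ** (state.floor_db / 10.0)
    reading = 10.0 * math.log10(max(mean_ms, floor_power))
    new_state = SplState(time_weighting_tau_s=state.time_weighting_tau_s,
                         mean_square=float(ms[-1]),
                         floor_db=state.floor_db)
    return reading + calibration_offset_db, new_state


def level_trace(audio: np.ndarray, fs: float,
                tau_s: float = 0.125) -> np.ndarray:
    """Per-sample time-weighted mean-square trace of a whole signal.

    Convenience used by the synthetic generator's level calibration and by
    offline diagnostics; equivalent to feeding the signal through
    :func:`spl_frame` sample-run without frame averaging.
    """
    state = SplState(time_weighting_tau_s=tau_s)
    return _smoothed_mean_square(np.asarray(audio, dtype=np.float64), state, fs)
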