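"""Statistical likelihood-ratio voice activity detection.

A Gaussian-model likelihood-ratio detector: per frequency bin the
a-posteriori SNR gamma_k = |X_k|^2 / N_k is combined with a
decision-directed a-priori SNR estimate xi_k into the per-bin
log-likelihood ratio

    log L_k = gamma_k * xi_k / (1 + xi_k) - log(1 + xi_k),

and the frame statistic is the geometric mean (the average log L_k over
bins).  The speech-presence probability is a calibrated logistic map of
that statistic: the decision-directed estimate of xi has a small positive
bias under noise-only input, so the midpoint of the map sits at a small
positive log-likelihood margin rather than at zero, keeping the noise-only
false-positive rate low at the default 0.5 probability threshold.

The running noise power spectrum is estimated from the lead-in frames and
then adapted by exponential smoothing, frozen whenever the frame is judged
to contain speech so that speech energy never leaks into the noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import EngineConfig, InvalidInputError, StateError

#: Decision-directed a-priori SNR smoothing.
DD_ALPHA = 0.98
#: Exponential noise-PSD adaptation rate (weight of the old estimate).
NOISE_SMOOTHING = 0.95
#: Logistic calibration of the frame log-likelihood statistic: midpoint and
#: scale in nats.  The midpoint absorbs the noise-only bias of the
#: decision-directed statistic (~ +0.015 nats) with a wide margin.
LLR_MIDPOINT = 0.25
LLR_SCALE = 0.15

_TINY = 1e-12


@dataclass
class VadState:
    """Noise model plus decision-directed memory for the detector."""

    noise_psd: np.ndarray
    smoothing: float = NOISE_SMOOTHING
    frames_initialized: int = 0
    fft_len: int = 512
    frame_len: int = 256
    prev_snr_term: np.ndarray | None = None  # G^2 * gamma from previous frame

    def __post_init__(self) -> None:
        self.noise_psd = np.asarray(self.noise_psd, dtype=np.float64)
        if np.any(self.noise_psd < 0):
            raise InvalidInputError("noise PSD entries must be non-negative")
        if not (0.0 < self.smoothing < 1.0):
            raise InvalidInputError("noise smoothing factor must be in (0, 1)")
        if self.prev_snr_term is None:
            self.prev_snr_term = np.zeros_like(self.noise_psd)


def periodogram(frame: np.ndarray, fft_len: int) -> np.ndarray:
    """Zero-padded one-sided periodogram, normalized by the frame length."""
    frame = np.asarray(frame, dtype=np.float64)
    spec = np.fft.rfft(frame, n=fft_len)
    return (spec.real ** 2 + spec.imag ** 2) / frame.size


def init_noise_model(lead_in_frames, fft_len: int = 512) -> VadState:
    """Average the periodograms of the lead-in frames into a noise model."""
    frames = [np.asarray(f, dtype=np.float64) for f in lead_in_frames]
    if not frames:
        raise InvalidInputError("need at least one lead-in frame to initialize the noise model")
    psd = np.mean([periodogram(f, fft_len) for f in frames], axis=0)
    return VadState(noise_psd=psd, fft_len=fft_len, frame_len=frames[0].size,
                    frames_initialized=len(frames))


def vad_probability(frame: np.ndarray, state: VadState,
                    update_threshold: float = 0.5,
                    alpha: float = DD_ALPHA) -> tuple[float, VadState]:
    """Speech-presence probability of one frame; updates the noise model.

    The noise PSD adapts (exponential smoothing) only when the computed
    probability falls below ``update_threshold``.  An all-zero frame
    cannot contain speech and returns p = 0 without touching the model.
    """
    if state is None or state.noise_psd is None:
        raise StateError("VAD state not initialized; call init_noise_model first")
    frame = np.asarray(frame, dtype=np.float64)
    if not np.any(frame):
        state.frames_initialized += 1
        return 0.0, state

    power = periodogram(frame, state.fft_len)
    noise = np.maximum(state.noise_psd, _TINY)
    gamma = np.minimum(power / noise, 1e8)
    xi = alpha * state.prev_snr_term + (1.0 - alpha) * np.maximum(gamma - 1.0, 0.0)
    log_lr = gamma * xi / (1.0 + xi) - np.log1p(xi)
    stat = float(np.mean(log_lr))
    p = 1.0 / (1.0 + math.exp(-np.clip((stat - LLR_MIDPOINT) / LLR_SCALE, -500, 500)))

    gain = xi / (1.0 + xi)
    state.prev_snr_term = gain * gain * gamma
    if p < update_threshold:
        state.noise_psd = state.smoothing * state.noise_psd + (1.0 - state.smoothing) * power
    state.frames_initialized += 1
    return p, state


def is_speech(p: float, cfg: EngineConfig) -> bool:
    """Threshold rule; a probability exactly at threshold counts as speech."""
    return p >= cfg.vad_threshold
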