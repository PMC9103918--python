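"""Per-bin Wiener-filter noise reduction.

Each frame is transformed (zero-padded FFT matching the VAD analysis), and
every frequency bin is attenuated by the Wiener gain xi/(1+xi), where xi
is the decision-directed a-priori SNR built from the shared running noise
power spectrum.  A gain floor (default 0.1, i.e. -20 dB) limits the
maximum attenuation to avoid musical noise.  The noise model is the same
object the VAD maintains, so the detector and the suppressor agree on
what "noise" currently is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import InvalidInputError, StateError
from .vad import DD_ALPHA, NOISE_SMOOTHING, periodogram

_TINY = 1e-12


@dataclass
class NrState:
    """Wiener suppressor state (noise PSD may be shared with the VAD)."""

    noise_psd: np.ndarray
    prior_snr_smoothing: float = DD_ALPHA
    gain_floor: float = 0.1
    noise_smoothing: float = NOISE_SMOOTHING
    fft_len: int = 512
    prev_snr_term: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gain_floor <= 1.0):
            raise InvalidInputError("gain floor must be in (0, 1]")
        if not (0.0 < self.prior_snr_smoothing < 1.0):
            raise InvalidInputError("a-priori SNR smoothing must be in (0, 1)")
        if self.prev_snr_term is None:
            self.prev_snr_term = np.zeros(len(np.asarray(self.noise_psd)))


def wiener_gain(xi, gain_floor: float = 0.0):
    """Wiener attenuation xi/(1+xi), clamped at the gain floor."""
    xi = np.asarray(xi, dtype=np.float64)
    if np.any(xi < 0):
        raise InvalidInputError("a-priori SNR must be non-negative")
    g = np.maximum(xi / (1.0 + xi), gain_floor)
    if g.ndim == 0:
        return float(g)
    return g


def denoise_frame(frame: np.ndarray, state: NrState, vad_p: float,
                  speech_threshold: float = 0.5, enabled: bool = True,
                  update_noise: bool = True) -> tuple[np.ndarray, NrState]:
    """Apply per-bin Wiener gains to one frame.

    With ``enabled=False`` the frame is returned untouched (bypass path).
    ``update_noise=False`` leaves noise-PSD adaptation to the caller —
    used when the PSD object is shared with the VAD, which already adapts
    it once per frame.
    """
    if not enabled:
        return frame, state
    if state is None or state.noise_psd is None:
        raise StateError("noise PSD not initialized")
    frame = np.asarray(frame, dtype=np.float64)
    n = frame.size

    spec = np.fft.rfft(frame, n=state.fft_len)
    power = (spec.real ** 2 + spec.imag ** 2) / n
    noise = np.maximum(np.asarray(state.noise_psd, dtype=np.float64), _TINY)
    gamma = np.minimum(power / noise, 1e8)
    alpha = state.prior_snr_smoothing
    xi = alpha * state.prev_snr_term + (1.0 - alpha) * np.maximum(gamma - 1.0, 0.0)
    g = np.maximum(xi / (1.0 + xi), state.gain_floor)

    out = np.fft.irfft(spec * g, n=state.fft_len)[:n]
    state.prev_snr_term = g * g * gamma
    if update_noise and vad_p < speech_threshold:
        state.noise_psd = (state.noise_smoothing * state.noise_psd
                           + (1.0 - state.noise_smoothing) * power)
    return out, state
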