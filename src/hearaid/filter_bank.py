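"""The six-filter bank and the frame-wise selection logic.

Three linear-phase FIR filters realize the per-band WDRC gains at the
soft/moderate/loud operating points; each exists in an NR-off and an
NR-on variant (the NR variant routes the frame through the adaptive
Wiener stage before the FIR), giving the six selectable filters.  Every
frame produces a temporary selection from the current {WDRC, NR} flags;
selections accumulate in a decision buffer and a majority vote fixes the
active filter once per decision window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    BandPlan,
    CompressionParams,
    DesignError,
    EngineConfig,
    FlagState,
    SpeechLevel,
    StateError,
    classify_speech_level,
    filter_index_for,
    flags_for_filter,
)
from .wdrc import band_gains_db

#: Gains above this are treated as unrealizable requests.
MAX_BAND_GAIN_DB = 60.0


@dataclass(frozen=True)
class DesignedFilter:
    """One selectable filter: symmetric FIR taps plus routing metadata."""

    index: int
    fir_coefficients: np.ndarray
    nr_enabled: bool
    category: SpeechLevel

    @property
    def order(self) -> int:
        return len(self.fir_coefficients) - 1

    @property
    def group_delay_samples(self) -> int:
        return self.order // 2

    def magnitude_db(self, freqs_hz: np.ndarray, fs: float) -> np.ndarray:
        """Magnitude response in dB at the given frequencies."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=np.float64))
        n = np.arange(len(self.fir_coefficients))
        phase = np.exp(-2j * np.pi * np.outer(freqs_hz / fs, n))
        H = phase @ self.fir_coefficients
        return 20.0 * np.log10(np.maximum(np.abs(H), 1e-12))


def _desired_response_db(freqs_hz: np.ndarray, plan: BandPlan,
                         gains_db: np.ndarray) -> np.ndarray:
    """Smooth target magnitude: PCHIP through the band centers in log-f.

    Constant extension below the lowest and above the highest center keeps
    out-of-band behavior benign (no extrapolated boost).
    """
    from scipy.interpolate import PchipInterpolator

    centers = np.asarray(plan.center_hz, dtype=np.float64)
    interp = PchipInterpolator(np.log2(centers), np.asarray(gains_db, dtype=np.float64))
    x = np.log2(np.maximum(freqs_hz, 1.0))
    x = np.clip(x, np.log2(centers[0]), np.log2(centers[-1]))
    return interp(x)


def _ls_linear_phase_fir(freqs_hz: np.ndarray, desired_amp: np.ndarray,
                         numtaps: int, fs: float) -> np.ndarray:
    """Least-squares type-I linear-phase FIR fit to a desired amplitude."""
    M = (numtaps - 1) // 2
    k = np.arange(1, M + 1)
    A = np.empty((freqs_hz.size, M + 1))
    A[:, 0] = 1.0
    A[:, 1:] = 2.0 * np.cos(2.0 * np.pi * np.outer(freqs_hz / fs, k))
    coef, *_ = np.linalg.lstsq(A, desired_amp, rcond=None)
    h = np.empty(numtaps)
    h[M] = coef[0]
    h[M - k] = coef[1:]
    h[M + k] = coef[1:]
    return h


def design_filter(category: SpeechLevel, nr_enabled: bool,
                  params: CompressionParams, plan: BandPlan,
                  cfg: EngineConfig,
                  representative_level_dbfs: float | None = None) -> DesignedFilter:
    """Design one filter of the bank from the WDRC band gains.

    The FIR magnitude realizes the five static band gains of the category
    evaluated at its representative input level; ``nr_enabled`` is a
    routing flag (the Wiener stage runs adaptively in series when on).
    """
    if representative_level_dbfs is None:
        representative_level_dbfs = cfg.representative_level_dbfs(category)
    gains = band_gains_db(category, params, representative_level_dbfs)
    if np.any(gains > MAX_BAND_GAIN_DB):
        raise DesignError(
            f"requested band gain {gains.max():.1f} dB exceeds the "
            f"{MAX_BAND_GAIN_DB:.0f} dB design limit"
        )
    fs = cfg.sample_rate_hz
    nyq = fs / 2.0
    # Dense grid, log-spaced through the audio band so the low bands get
    # commensurate weight in the least-squares fit.
    grid = np.concatenate([
        np.linspace(0.0, 80.0, 24, endpoint=False),
        np.geomspace(80.0, nyq, 640),
    ])
    desired = 10.0 ** (_desired_response_db(grid, plan, gains) / 20.0)
    taps = _ls_linear_phase_fir(grid, desired, cfg.fir_order + 1, fs)
    return DesignedFilter(index=filter_index_for(FlagState(category, nr_enabled)),
                          fir_coefficients=taps, nr_enabled=nr_enabled,
                          category=category)


def build_filter_bank(params: CompressionParams, plan: BandPlan,
                      cfg: EngineConfig) -> dict[int, DesignedFilter]:
    """Design all six filters, keyed by their index (1-6)."""
    bank: dict[int, DesignedFilter] = {}
    for index in range(1, 7):
        flags = flags_for_filter(index)
        bank[index] = design_filter(flags.wdrc_flag, flags.nr_flag, params, plan, cfg)
    return bank


@dataclass
class DecisionBuffer:
    """Tumbling buffer of temporary per-frame filter selections."""

    capacity: int
    entries: list[int] = field(default_factory=list)

    def append(self, index: int) -> None:
        if len(self.entries) >= self.capacity:
            raise StateError("decision buffer full; vote before appending")
        self.entries.append(index)

    @property
    def full(self) -> bool:
        return len(self.entries) >= self.capacity

    def flush(self) -> None:
        self.entries.clear()


def majority_vote(buffer: DecisionBuffer) -> int:
    """Most frequent filter index in the buffer; ties go to the lowest index."""
    if not buffer.entries:
        raise StateError("cannot vote on an empty decision buffer")
    counts = np.bincount(buffer.entries, minlength=7)
    return int(np.argmax(counts[1:7])) + 1


def temporary_selection(vad_p: float, spl_db: float, flags: FlagState,
                        cfg: EngineConfig) -> tuple[int, FlagState]:
    """Per-frame flag update and temporary filter choice.

    Noise-only frames update the NR flag (on when the noise level reaches
    the NR threshold); speech frames update the WDRC category.  The flag
    not addressed by the current frame type persists.
    """
    if vad_p < cfg.vad_threshold:
        new_flags = FlagState(wdrc_flag=flags.wdrc_flag,
                              nr_flag=spl_db >= cfg.nr_spl_threshold_db)
    else:
        new_flags = FlagState(wdrc_flag=classify_speech_level(spl_db, cfg),
                              nr_flag=flags.nr_flag)
    return filter_index_for(new_flags), new_flags


def export_coefficients(bank: dict[int, DesignedFilter], directory) -> list[str]:
    """Write each filter's taps to a plain-text file; returns the paths."""
    import os

    paths = []
    os.makedirs(directory, exist_ok=True)
    for index, filt in sorted(bank.items()):
        path = os.path.join(directory, f"filter_{index}.txt")
        header = (f"filter {index}: category={filt.category.value} "
                  f"nr={'on' if filt.nr_enabled else 'off'} order={filt.order}")
        np.savetxt(path, filt.fir_coefficients, header=header)
        paths.append(path)
    return paths
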