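"""Wide-dynamic-range compression: static soft-knee gain law and level dynamics.

The static curve maps an input level L (dB re full scale) to an output
level through three regions around the compression threshold T with knee
width W:

    L < T - W/2          out = L                          (linear)
    |L - T| <= W/2       out = L + (1/R - 1)(L - T + W/2)^2 / (2W)
    L > T + W/2          out = T + (L - T)/R              (compressed)

and the applied gain is out - L + makeup.  With ratio R = 1 the gain is
the makeup gain at every level.  Attack/release dynamics smooth the
detected level with a one-pole recursion whose coefficient switches
between the attack and release time constants depending on whether the
level is rising or falling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import (
    CompressionParams,
    EngineConfig,
    InvalidInputError,
    SpeechLevel,
)


@dataclass(frozen=True)
class GainCurve:
    """One band/category static compression characteristic."""

    ratio: float
    makeup_db: float = 0.0
    threshold_dbfs: float = -45.0
    knee_db: float = 5.0

    def __post_init__(self) -> None:
        if self.ratio < 1.0:
            raise InvalidInputError("compression ratio must be >= 1")
        if self.knee_db < 0.0:
            raise InvalidInputError("knee width must be non-negative")


@dataclass
class Smoother:
    """One-pole attack/release level smoother."""

    attack_s: float = 0.01
    release_s: float = 1.0
    current_level_db: float = -120.0

    def __post_init__(self) -> None:
        if self.attack_s <= 0 or self.release_s <= 0:
            raise InvalidInputError("attack and release times must be positive")


def static_gain_db(input_level_db: float, curve: GainCurve) -> float:
    """Gain (dB) of the soft-knee static curve at one input level."""
    if not math.isfinite(input_level_db):
        raise InvalidInputError("input level must be finite")
    L, T, W, R = input_level_db, curve.threshold_dbfs, curve.knee_db, curve.ratio
    if W > 0.0 and abs(L - T) <= W / 2.0:
        out = L + (1.0 / R - 1.0) * (L - T + W / 2.0) ** 2 / (2.0 * W)
    elif L < T:  # below knee (hard-knee limit when W == 0)
        out = L
    else:
        out = T + (L - T) / R
    return out - L + curve.makeup_db


def smooth_level(detected_level_db: float, s: Smoother,
                 frame_hop_s: float) -> tuple[float, Smoother]:
    """Advance the level smoother by one hop toward the detected level."""
    if frame_hop_s <= 0:
        raise InvalidInputError("hop duration must be positive")
    tau = s.attack_s if detected_level_db > s.current_level_db else s.release_s
    a = math.exp(-frame_hop_s / tau)
    smoothed = a * s.current_level_db + (1.0 - a) * detected_level_db
    return smoothed, Smoother(attack_s=s.attack_s, release_s=s.release_s,
                              current_level_db=smoothed)


def band_gains_db(category: SpeechLevel, params: CompressionParams,
                  representative_level_dbfs: float) -> np.ndarray:
    """Static per-band gains (5,) for a category at one operating level."""
    row = params.row(category)
    return np.array([
        static_gain_db(representative_level_dbfs,
                       GainCurve(ratio=params.ratios[row][b],
                                 makeup_db=params.makeup_gains_db[row][b],
                                 threshold_dbfs=params.threshold_dbfs,
                                 knee_db=params.knee_db))
        for b in range(5)
    ])


def step_response_63_time(step_db: float, attack_s: float, release_s: float,
                          hop_s: float, rising: bool = True,
                          start_level_db: float = 0.0) -> float:
    """Elapsed time for the smoother to cover 1 - 1/e of a level step.

    Simulates the one-pole recursion at the given hop rate and linearly
    interpolates the crossing time between hops; the result recovers the
    attack (rising) or release (falling) time constant.
    """
    target_frac = 1.0 - math.exp(-1.0)
    detected = start_level_db + (step_db if rising else -step_db)
    threshold = start_level_db + target_frac * (detected - start_level_db)
    s = Smoother(attack_s=attack_s, release_s=release_s,
                 current_level_db=start_level_db)
    t_prev, v_prev = 0.0, start_level_db
    max_steps = int(10 * max(attack_s, release_s) / hop_s) + 2
    for n in range(1, max_steps):
        v, s = smooth_level(detected, s, hop_s)
        t = n * hop_s
        crossed = v >= threshold if rising else v <= threshold
        if crossed:
            return t_prev + hop_s * (threshold - v_prev) / (v - v_prev)
        t_prev, v_prev = t, v
    raise RuntimeError("smoother did not reach 63% of the step")
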