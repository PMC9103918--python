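"""Shared data types, configuration and the nine-to-five band mapping.

The processing chain classifies every speech frame into one of three
intensity categories (soft / moderate / loud) and every noise frame into
NR-on / NR-off, and the six combinations of those flags index the six
selectable filters of the filter bank.  This module owns those types, the
default clinical tables (audiogram, compression prescription) and the
engine configuration, so that every other module consumes one coherent
set of constants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONFIG_SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """A config document or domain object violates its invariants."""


class InvalidInputError(ValueError):
    """A runtime input (frame, level, audio buffer) is unusable."""


class StateError(RuntimeError):
    """An operation was called before its state was initialized."""


class DesignError(ValueError):
    """A requested filter response is not realizable."""


class FormatError(ValueError):
    """An audio file is not in a supported format."""


class SpeechLevel(enum.Enum):
    """The three speech-intensity categories driving the compressor choice."""

    SOFT = "soft"
    MODERATE = "moderate"
    LOUD = "loud"


# Category order used by every 3xN parameter table (rows).
SPEECH_LEVEL_ORDER = (SpeechLevel.SOFT, SpeechLevel.MODERATE, SpeechLevel.LOUD)


@dataclass(frozen=True)
class FlagState:
    """Current {WDRC category, NR on/off} decision state."""

    wdrc_flag: SpeechLevel = SpeechLevel.MODERATE
    nr_flag: bool = False


@dataclass(frozen=True)
class FrameLog:
    """Per-frame record mirroring the app-style debug text file."""

    frame_index: int
    vad_prob: float
    spl_db: float
    filter_index: int


@dataclass(frozen=True)
class Audiogram:
    """Nine-band hearing-threshold profile.

    ``band_edges_hz`` are contiguous, strictly increasing (lo, hi) pairs
    spanning 125-6000 Hz; ``thresholds_db_spl`` is the softest audible
    level per band.
    """

    band_edges_hz: tuple[tuple[float, float], ...]
    thresholds_db_spl: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.band_edges_hz) != 9 or len(self.thresholds_db_spl) != 9:
            raise ConfigurationError(
                f"audiogram must have 9 bands, got {len(self.band_edges_hz)} "
                f"edges / {len(self.thresholds_db_spl)} thresholds"
            )
        _check_contiguous(self.band_edges_hz, "audiogram")
        for t in self.thresholds_db_spl:
            if not math.isfinite(t) or t < 0:
                raise ConfigurationError(f"audiogram threshold {t} not a finite non-negative dB SPL")


@dataclass(frozen=True)
class BandPlan:
    """Five contiguous processing bands with geometric-mean centers."""

    edges_hz: tuple[tuple[float, float], ...]
    center_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges_hz) != 5 or len(self.center_hz) != 5:
            raise ConfigurationError("band plan must have exactly 5 bands")
        _check_contiguous(self.edges_hz, "band plan")


@dataclass(frozen=True)
class CompressionParams:
    """Per-band/per-category compression prescription plus global dynamics.

    ``ratios`` and ``makeup_gains_db`` are 3x5 (rows soft/moderate/loud);
    ``attack_s``/``release_s`` govern the level smoother; ``threshold_dbfs``
    and ``knee_db`` define the static soft-knee gain curve.
    """

    ratios: tuple[tuple[float, ...], ...]
    makeup_gains_db: tuple[tuple[float, ...], ...]
    attack_s: float = 0.01
    release_s: float = 1.0
    threshold_dbfs: float = -45.0
    knee_db: float = 5.0

    def __post_init__(self) -> None:
        for name, table in (("ratios", self.ratios), ("makeup_gains_db", self.makeup_gains_db)):
            if len(table) != 3 or any(len(row) != 5 for row in table):
                raise ConfigurationError(f"{name} must be a 3x5 table")
        if any(r < 1.0 for row in self.ratios for r in row):
            raise ConfigurationError("compression ratios must be >= 1")
        if self.attack_s <= 0 or self.release_s <= 0:
            raise ConfigurationError("attack/release times must be positive")
        if self.knee_db < 0:
            raise ConfigurationError("knee width must be non-negative")

    def row(self, level: SpeechLevel) -> int:
        return SPEECH_LEVEL_ORDER.index(level)


@dataclass(frozen=True)
class EngineConfig:
    """Global engine parameters (sampling, framing, decision logic)."""

    sample_rate_hz: int = 48000
    frame_len: int = 256
    overlap_fraction: float = 0.5
    decision_rate_frames: int = 200
    vad_threshold: float = 0.5
    soft_upper_db: float = 55.0
    loud_lower_db: float = 75.0
    nr_spl_threshold_db: float = 55.0
    calibration_offset_db: float = 0.0
    seed: int = 0
    # Secondary knobs with engineering defaults.
    noise_init_frames: int = 75
    nr_gain_floor: float = 0.1
    fir_order: int = 128
    crossfade_ms: float = 10.0
    representative_levels_dbfs: tuple[float, float, float] = (-50.0, -35.0, -20.0)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.frame_len <= 0:
            raise ConfigurationError("sample rate and frame length must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ConfigurationError("overlap fraction must be in [0, 1)")
        if self.decision_rate_frames < 1:
            raise ConfigurationError("decision rate must be >= 1 frame")
        if not (0.0 < self.vad_threshold < 1.0):
            raise ConfigurationError("VAD threshold must be in (0, 1)")
        if self.soft_upper_db > self.loud_lower_db:
            raise ConfigurationError("soft/loud category boundaries out of order")
        if self.fir_order % 2 != 0:
            raise ConfigurationError("FIR order must be even (type-I linear phase)")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.frame_len * (1.0 - self.overlap_fraction))))

    @property
    def hop_s(self) -> float:
        return self.hop / self.sample_rate_hz

    @property
    def fft_len(self) -> int:
        # Zero-padded spectral analysis at twice the frame length.
        return 2 * self.frame_len

    def representative_level_dbfs(self, level: SpeechLevel) -> float:
        return self.representative_levels_dbfs[SPEECH_LEVEL_ORDER.index(level)]


def _check_contiguous(edges: Sequence[tuple[float, float]], what: str) -> None:
    for lo, hi in edges:
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
            raise ConfigurationError(f"{what} band ({lo}, {hi}) is not a valid interval")
    for (_, hi), (lo2, _) in zip(edges, edges[1:]):
        if hi != lo2:
            raise ConfigurationError(f"{what} bands are not contiguous at {hi}/{lo2} Hz")


# ---------------------------------------------------------------------------
# Default clinical tables (sample audiogram and the prescription fitted to it)
# ---------------------------------------------------------------------------

DEFAULT_AUDIOGRAM = Audiogram(
    band_edges_hz=(
        (125.0, 250.0), (250.0, 500.0), (500.0, 750.0), (750.0, 1000.0),
        (1000.0, 1500.0), (1500.0, 2000.0), (2000.0, 3000.0),
        (3000.0, 4000.0), (4000.0, 6000.0),
    ),
    thresholds_db_spl=(20.0, 25.0, 30.0, 30.0, 35.0, 35.0, 40.0, 35.0, 35.0),
)

DEFAULT_COMPRESSION = CompressionParams(
    ratios=(
        (1.0, 1.0, 1.0, 1.0, 1.0),
        (1.6, 2.0, 1.6, 1.6, 5.0),
        (3.0, 2.8, 5.0, 20.0, 20.0),
    ),
    makeup_gains_db=(
        (10.0, 11.0, 14.0, 25.0, 21.0),
        (8.0, 9.0, 13.0, 23.0, 19.0),
        (6.0, 4.0, 8.0, 18.0, 15.0),
    ),
    attack_s=0.01,
    release_s=1.0,
    threshold_dbfs=-45.0,
    knee_db=5.0,
)

# Five processing bands the nine audiogram bands merge into.
FIVE_BAND_BOUNDARIES_HZ = (125.0, 500.0, 1000.0, 2000.0, 4000.0, 6000.0)


def map_bands(audiogram: Audiogram) -> tuple[BandPlan, tuple[float, ...]]:
    """Merge the nine audiogram bands into the five processing bands.

    Each five-band interval absorbs the audiogram bands nested inside it;
    the merged threshold is the arithmetic mean of its constituents.
    Returns the band plan (with geometric-mean centers) and the five
    merged thresholds in dB SPL.
    """
    bounds = FIVE_BAND_BOUNDARIES_HZ
    groups: list[list[float]] = [[] for _ in range(5)]
    for (lo, hi), thr in zip(audiogram.band_edges_hz, audiogram.thresholds_db_spl):
        placed = False
        for b in range(5):
            if bounds[b] <= lo and hi <= bounds[b + 1]:
                groups[b].append(thr)
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"audiogram band ({lo}, {hi}) Hz does not nest inside the five-band plan"
            )
    if any(not g for g in groups):
        raise ConfigurationError("an output band received no audiogram bands")
    edges = tuple((bounds[b], bounds[b + 1]) for b in range(5))
    centers = tuple(math.sqrt(lo * hi) for lo, hi in edges)
    thresholds = tuple(float(np.mean(g)) for g in groups)
    return BandPlan(edges_hz=edges, center_hz=centers), thresholds


_FILTER_TABLE = {
    (SpeechLevel.SOFT, False): 1,
    (SpeechLevel.SOFT, True): 2,
    (SpeechLevel.MODERATE, False): 3,
    (SpeechLevel.MODERATE, True): 4,
    (SpeechLevel.LOUD, False): 5,
    (SpeechLevel.LOUD, True): 6,
}


def filter_index_for(flags: FlagState) -> int:
    """Map the {WDRC, NR} flag pair to its filter index (1-6)."""
    return _FILTER_TABLE[(flags.wdrc_flag, flags.nr_flag)]


def flags_for_filter(index: int) -> FlagState:
    """Inverse of :func:`filter_index_for`."""
    for (level, nr), idx in _FILTER_TABLE.items():
        if idx == index:
            return FlagState(wdrc_flag=level, nr_flag=nr)
    raise ConfigurationError(f"filter index {index} outside 1..6")


def classify_speech_level(spl_db: float, cfg: EngineConfig) -> SpeechLevel:
    """Assign an SPL reading to soft / moderate / loud.

    Boundaries are closed into the moderate category: readings of exactly
    55 or 75 dB (at defaults) classify as moderate.
    """
    if math.isnan(spl_db):
        raise InvalidInputError("SPL reading is NaN")
    if spl_db < cfg.soft_upper_db:
        return SpeechLevel.SOFT
    if spl_db > cfg.loud_lower_db:
        return SpeechLevel.LOUD
    return SpeechLevel.MODERATE


# ---------------------------------------------------------------------------
# Config document (nested YAML-friendly dict) <-> domain objects
# ---------------------------------------------------------------------------

def config_to_dict(cfg: EngineConfig, params: CompressionParams,
                   audiogram: Audiogram) -> dict:
    """Serialize a full configuration to a plain dict (YAML-ready)."""
    return {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "engine": {
            "sample_rate_hz": cfg.sample_rate_hz,
            "frame_len": cfg.frame_len,
            "overlap_fraction": cfg.overlap_fraction,
            "decision_rate_frames": cfg.decision_rate_frames,
            "vad_threshold": cfg.vad_threshold,
            "soft_upper_db": cfg.soft_upper_db,
            "loud_lower_db": cfg.loud_lower_db,
            "nr_spl_threshold_db": cfg.nr_spl_threshold_db,
            "calibration_offset_db": cfg.calibration_offset_db,
            "seed": cfg.seed,
            "noise_init_frames": cfg.noise_init_frames,
            "nr_gain_floor": cfg.nr_gain_floor,
            "fir_order": cfg.fir_order,
            "crossfade_ms": cfg.crossfade_ms,
            "representative_levels_dbfs": list(cfg.representative_levels_dbfs),
        },
        "audiogram": {
            "band_edges_hz": [list(e) for e in audiogram.band_edges_hz],
            "thresholds_db_spl": list(audiogram.thresholds_db_spl),
        },
        "compression": {
            "ratios": [list(r) for r in params.ratios],
            "makeup_gains_db": [list(r) for r in params.makeup_gains_db],
            "attack_s": params.attack_s,
            "release_s": params.release_s,
            "threshold_dbfs": params.threshold_dbfs,
            "knee_db": params.knee_db,
        },
    }


def config_from_dict(doc: dict | None) -> tuple[EngineConfig, CompressionParams, Audiogram]:
    """Build configuration objects from a (possibly partial) config dict.

    Missing sections and keys fall back to the package defaults, so an
    empty document yields the default pipeline.
    """
    doc = doc or {}
    version = doc.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported config schema_version {version}")

    eng = dict(doc.get("engine", {}))
    if "representative_levels_dbfs" in eng:
        eng["representative_levels_dbfs"] = tuple(eng["representative_levels_dbfs"])
    try:
        cfg = EngineConfig(**eng)
    except TypeError as exc:
        raise ConfigurationError(f"unknown engine config key: {exc}") from exc

    comp = doc.get("compression")
    if comp is None:
        params = DEFAULT_COMPRESSION
    else:
        base = DEFAULT_COMPRESSION
        params = CompressionParams(
            ratios=tuple(tuple(float(x) for x in row)
                         for row in comp.get("ratios", base.ratios)),
            makeup_gains_db=tuple(tuple(float(x) for x in row)
                                  for row in comp.get("makeup_gains_db", base.makeup_gains_db)),
            attack_s=float(comp.get("attack_s", base.attack_s)),
            release_s=float(comp.get("release_s", base.release_s)),
            threshold_dbfs=float(comp.get("threshold_dbfs", base.threshold_dbfs)),
            knee_db=float(comp.get("knee_db", base.knee_db)),
        )

    aud = doc.get("audiogram")
    if aud is None:
        audiogram = DEFAULT_AUDIOGRAM
    else:
        audiogram = Audiogram(
            band_edges_hz=tuple(tuple(float(x) for x in e) for e in aud["band_edges_hz"]),
            thresholds_db_spl=tuple(float(t) for t in aud["thresholds_db_spl"]),
        )
    return cfg, params, audiogram


def with_overrides(cfg: EngineConfig, **kwargs) -> EngineConfig:
    """Return a copy of ``cfg`` with non-None keyword overrides applied."""
    updates = {k: v for k, v in kwargs.items() if v is not None}
    return replace(cfg, **updates) if updates else cfg
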