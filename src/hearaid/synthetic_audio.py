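"""Synthetic capture scenes: noise lead-in followed by speech at a set level.

The generator emulates the field-capture protocol the chain is built for:
the environment noise alone is present for a few seconds (so the noise
model can initialize), then a talker enters at a chosen SPL over the
continuing noise.  A harmonic "speech surrogate" stands in for recorded
speech: a drifting-f0 harmonic complex with formant-shaped partial
amplitudes and 4 Hz syllabic amplitude modulation.  It is synthetic by
construction and carries only the properties the VAD, the SPL categories
and the compressor respond to — periodicity, band-limited spectrum and
slow envelope modulation — not intelligible phonetic content.

SPL targets are defined against this package's own meter (flat weighting,
fast time constant), so a scene asking for "speech at 65 dB" produces a
signal the pipeline's meter reads as 65 dB under the scene's calibration
offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .core_model import InvalidInputError
from .spl_meter import level_trace

#: Default calibration offset tying digital full scale to a plausible
#: acoustic scale (a full-scale sine reads ~97 dB), so conversational
#: speech levels (50-80 dB) sit comfortably inside the digital range.
DEFAULT_CALIBRATION_DB = 100.0

NOISE_KINDS = ("white", "pink", "babble_like", "fan_like")


@dataclass(frozen=True)
class SpeechSurrogate:
    """Recipe for the synthetic talker."""

    f0_hz: float = 120.0
    n_harmonics: int = 32
    modulation_rate_hz: float = 4.0
    modulation_depth: float = 0.6
    duty_cycle: float = 0.7
    #: (center Hz, bandwidth Hz, linear boost) formant resonances.
    formants: tuple[tuple[float, float, float], ...] = (
        (500.0, 150.0, 2.0), (1500.0, 250.0, 1.5), (2500.0, 350.0, 1.0),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one capture scene."""

    noise_kind: str = "white"
    noise_spl_db: float = 55.0
    speech_spl_db: float = 65.0
    lead_in_s: float = 3.0
    speech_s: float = 5.0
    seed: int = 0
    calibration_offset_db: float = DEFAULT_CALIBRATION_DB
    surrogate: SpeechSurrogate = field(default_factory=SpeechSurrogate)

    def __post_init__(self) -> None:
        if self.noise_kind not in NOISE_KINDS:
            raise InvalidInputError(f"unknown noise kind {self.noise_kind!r}")
        if self.lead_in_s <= 0 or self.speech_s <= 0:
            raise InvalidInputError("segment durations must be positive")
        if not (math.isfinite(self.noise_spl_db) and math.isfinite(self.speech_spl_db)):
            raise InvalidInputError("scene SPLs must be finite")


def gen_noise(kind: str, duration_s: float, fs: int, seed: int) -> np.ndarray:
    """Seeded environmental-noise surrogate of the requested kind."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if kind == "white":
        return rng.standard_normal(n)
    if kind == "pink":
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.ones_like(f)
        shaping[1:] = 1.0 / np.sqrt(f[1:])  # -3 dB/octave power slope
        shaping[0] = 0.0
        x = np.fft.irfft(spec * shaping, n=n)
        return x / np.std(x)
    if kind == "fan_like":
        sos = butter(4, 400.0, btype="low", fs=fs, output="sos")
        rumble = sosfilt(sos, rng.standard_normal(n))
        t = np.arange(n) / fs
        hum = (0.4 * np.sin(2 * np.pi * 120.0 * t + rng.uniform(0, 2 * np.pi))
               + 0.15 * np.sin(2 * np.pi * 240.0 * t + rng.uniform(0, 2 * np.pi)))
        x = rumble / np.std(rumble) + hum
        return x / np.std(x)
    if kind == "babble_like":
        seeds = np.random.SeedSequence(seed).spawn(8)
        x = np.zeros(n)
        for ss in seeds:
            child = np.random.default_rng(ss)
            spec = SpeechSurrogate(f0_hz=float(child.uniform(90.0, 220.0)),
                                   modulation_depth=0.6,
                                   duty_cycle=1.0)
            x += gen_speech_surrogate(duration_s, fs, spec,
                                      seed=int(child.integers(0, 2**31 - 1)))
        return x / np.std(x)
    raise InvalidInputError(f"unknown noise kind {kind!r}")


def gen_speech_surrogate(duration_s: float, fs: int,
                         spec: SpeechSurrogate | None = None,
                         seed: int = 0) -> np.ndarray:
    """Harmonic speech stand-in with drifting f0 and syllabic modulation.

    Partial amplitudes fall as 1/k with formant boosts, keeping the
    spectral peak at the fundamental while concentrating energy below
    4 kHz.  The 4 Hz modulation gates amplitude between full scale and a
    soft "pause" floor of (1 - depth), with raised-cosine edges — pauses
    in running speech carry residual energy rather than dropping to zero.
    """
    spec = spec or SpeechSurrogate()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # Slow +-10% f0 drift (deterministic under the seed).
    drift = 0.1 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi))
    f0 = spec.f0_hz * (1.0 + drift)
    phase = 2.0 * np.pi * np.cumsum(f0) / fs

    n_harm = min(spec.n_harmonics, int(4000.0 / (spec.f0_hz * 1.1)))
    x = np.zeros(n)
    for k in range(1, n_harm + 1):
        fk = k * spec.f0_hz
        boost = 1.0 + sum(a * math.exp(-((fk - fc) / bw) ** 2)
                          for fc, bw, a in spec.formants)
        amp = boost / k
        x += amp * np.sin(k * phase + rng.uniform(0, 2 * np.pi))

    # Syllabic gating: duty-cycle square at the modulation rate, smoothed
    # with ~10 ms raised-cosine edges, scaled into [1-depth, 1].
    cycle = np.mod(spec.modulation_rate_hz * t, 1.0)
    gate = (cycle < spec.duty_cycle).astype(np.float64)
    edge = max(1, int(0.010 * fs))
    kernel = np.hanning(2 * edge + 1)
    kernel /= kernel.sum()
    gate = np.convolve(gate, kernel, mode="same")
    envelope = (1.0 - spec.modulation_depth) + spec.modulation_depth * gate
    x *= envelope
    return x / np.std(x)


def set_spl(audio: np.ndarray, target_db: float,
            calibration_offset_db: float = DEFAULT_CALIBRATION_DB,
            fs: int = 48000) -> np.ndarray:
    """Scale audio so the settled meter reading equals ``target_db``.

    The reading is taken as the time-average of the meter's weighted
    mean-square trace after a settling interval, under the given
    calibration offset.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0 or not np.any(audio):
        raise InvalidInputError("cannot set the SPL of silent audio")
    ms = level_trace(audio, fs)
    settle = min(int(0.5 * fs), audio.size // 4)
    reading = 10.0 * math.log10(float(np.mean(ms[settle:]))) + calibration_offset_db
    return audio * 10.0 ** ((target_db - reading) / 20.0)


def gen_scene(spec: SceneSpec, fs: int = 48000) -> tuple[np.ndarray, np.ndarray]:
    """Generate one scene: noise lead-in, then speech over continuing noise.

    Returns (audio, labels) where labels[i] is 0 during the noise-only
    lead-in and 1 from speech onset onward (exact by construction).
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    total_s = spec.lead_in_s + spec.speech_s
    noise = gen_noise(spec.noise_kind, total_s, fs,
                      seed=int(np.random.default_rng(seeds[0]).integers(0, 2**31 - 1)))
    noise = set_spl(noise, spec.noise_spl_db, spec.calibration_offset_db, fs)

    speech = gen_speech_surrogate(spec.speech_s, fs, spec.surrogate,
                                  seed=int(np.random.default_rng(seeds[1]).integers(0, 2**31 - 1)))
    speech = set_spl(speech, spec.speech_spl_db, spec.calibration_offset_db, fs)

    audio = noise.copy()
    lead_n = int(round(spec.lead_in_s * fs))
    audio[lead_n:lead_n + speech.size] += speech
    labels = np.zeros(audio.size, dtype=np.int8)
    labels[lead_n:] = 1
    return audio, labels


def expected_filter_windows(spec: SceneSpec, cfg, n_frames: int) -> list[int]:
    """Ground-truth filter index per decision window for a scene.

    Replays the selection rules with ideal measurements — perfect speech/
    noise labels and the nominal segment SPLs (speech frames read the
    speech+noise mix level) — so it predicts which filter a correctly
    behaving pipeline should hold active in each window.  Element w is the
    filter active during window w; window 0 is the neutral cold-start
    filter.
    """
    from .core_model import FlagState
    from .filter_bank import DecisionBuffer, majority_vote, temporary_selection

    lead_frames = int(round(spec.lead_in_s * cfg.sample_rate_hz)) // cfg.hop
    mix_db = 10.0 * math.log10(10.0 ** (spec.speech_spl_db / 10.0)
                               + 10.0 ** (spec.noise_spl_db / 10.0))
    flags = FlagState()
    expected = [3]
    buf = DecisionBuffer(capacity=cfg.decision_rate_frames)
    for f in range(n_frames):
        in_speech = f >= lead_frames
        p = 1.0 if in_speech else 0.0
        spl = mix_db if in_speech else spec.noise_spl_db
        idx, flags = temporary_selection(p, spl, flags, cfg)
        buf.append(idx)
        if buf.full:
            expected.append(majority_vote(buf))
            buf.flush()
    return expected


def write_labels(labels: np.ndarray, path) -> None:
    """Write ground-truth segments as tab-separated sample ranges."""
    changes = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [labels.size]])
    with open(path, "w") as fh:
        fh.write("start_sample\tend_sample\tlabel\n")
        for s, e in zip(starts, ends):
            name = "speech" if labels[s] else "noise"
            fh.write(f"{s}\t{e}\t{name}\n")
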