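import collections

import numpy as np
import pytest
from scipy.signal import welch

from hearaid import (
    InvalidInputError,
    SceneSpec,
    SpeechSurrogate,
    gen_noise,
    gen_scene,
    gen_speech_surrogate,
    process,
    set_spl,
)
from hearaid.spl_meter import level_trace

FS = 48000


class TestGenNoise:
    def test_seeded_generation_reproducible(self):
        for kind in ("white", "pink", "fan_like", "babble_like"):
            a = gen_noise(kind, 0.5, FS, seed=42)
            b = gen_noise(kind, 0.5, FS, seed=42)
            np.testing.assert_array_equal(a, b)
            c = gen_noise(kind, 0.5, FS, seed=43)
            assert not np.array_equal(a, c)

    def test_pink_noise_spectral_slope(self):
        x = gen_noise("pink", 4.0, FS, seed=1)
        f, psd = welch(x, FS, nperseg=8192)
        sel = (f >= 100) & (f <= 6000)
        slope = np.polyfit(np.log2(f[sel]), 10 * np.log10(psd[sel]), 1)[0]
        assert -3.5 < slope < -2.5

    def test_fan_noise_energy_concentrated_low(self):
        x = gen_noise("fan_like", 2.0, FS, seed=2)
        f, psd = welch(x, FS, nperseg=4096)
        frac = np.sum(psd[f < 1000]) / np.sum(psd)
        assert frac >= 0.7

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidInputError):
            gen_noise("brownian", 1.0, FS, seed=0)


@pytest.fixture(scope="module")
def surrogate():
    return gen_speech_surrogate(3.0, FS, SpeechSurrogate(), seed=5)


class TestSpeechSurrogate:
    def test_spectral_peak_at_fundamental(self, surrogate):
        spec = np.abs(np.fft.rfft(surrogate))
        freqs = np.fft.rfftfreq(surrogate.size, 1 / FS)
        peak = freqs[np.argmax(spec)]
        assert 120.0 * 0.9 <= peak <= 120.0 * 1.1

    def test_energy_concentrated_in_speech_band(self, surrogate):
        f, psd = welch(surrogate, FS, nperseg=4096)
        band = np.sum(psd[(f >= 100) & (f <= 4000)]) / np.sum(psd)
        assert band > 0.95

    def test_modulation_spectrum_peaks_near_4hz(self, surrogate):
        envelope = level_trace(surrogate, FS)
        envelope = envelope - envelope.mean()
        spec = np.abs(np.fft.rfft(envelope))
        freqs = np.fft.rfftfreq(envelope.size, 1 / FS)
        sel = (freqs > 0.5) & (freqs < 20)
        peak = freqs[sel][np.argmax(spec[sel])]
        assert 3.0 <= peak <= 5.0

    def test_two_seeds_share_long_term_spectrum(self):
        a = gen_speech_surrogate(3.0, FS, seed=5)
        b = gen_speech_surrogate(3.0, FS, seed=6)
        assert not np.array_equal(a, b)
        edges = [125, 250, 500, 1000, 2000, 4000]
        fa, pa = welch(a, FS, nperseg=8192)
        fb, pb = welch(b, FS, nperseg=8192)
        for lo, hi in zip(edges, edges[1:]):
            ea = np.sum(pa[(fa >= lo) & (fa < hi)])
            eb = np.sum(pb[(fb >= lo) & (fb < hi)])
            assert abs(10 * np.log10(ea / eb)) < 3.0


class TestSetSpl:
    def _settled_reading(self, x, cal=100.0):
        ms = level_trace(x, FS)
        return 10 * np.log10(np.mean(ms[FS // 2:])) + cal

    def test_target_reached_within_tenth_db(self, rng):
        x = rng.standard_normal(FS * 2)
        y = set_spl(x, 60.0, 100.0, FS)
        assert self._settled_reading(y) == pytest.approx(60.0, abs=0.1)

    def test_raising_target_raises_reading(self, rng):
        x = rng.standard_normal(FS * 2)
        r60 = self._settled_reading(set_spl(x, 60.0, 100.0, FS))
        r70 = self._settled_reading(set_spl(x, 70.0, 100.0, FS))
        assert r70 - r60 == pytest.approx(10.0, abs=0.1)

    def test_silent_input_rejected(self):
        with pytest.raises(InvalidInputError):
            set_spl(np.zeros(FS), 60.0, 100.0, FS)


class TestGenScene:
    def test_durations_and_labels_by_construction(self):
        spec = SceneSpec("white", 50.0, 65.0, lead_in_s=3.0, speech_s=5.0, seed=7)
        audio, labels = gen_scene(spec, FS)
        assert audio.size == 8 * FS
        assert np.all(labels[:3 * FS] == 0)
        assert np.all(labels[3 * FS:] == 1)

    def test_deterministic_under_seed(self):
        spec = SceneSpec("pink", 50.0, 65.0, lead_in_s=1.0, speech_s=1.0, seed=9)
        a, _ = gen_scene(spec, FS)
        b, _ = gen_scene(spec, FS)
        np.testing.assert_array_equal(a, b)

    def test_vad_accuracy_above_90_percent_at_snr_10(self, cal_cfg):
        spec = SceneSpec("white", 50.0, 60.0, lead_in_s=2.0, speech_s=3.0, seed=13)
        audio, labels = gen_scene(spec, FS)
        res = process(audio, cal_cfg)
        hop, flen = cal_cfg.hop, cal_cfg.frame_len
        correct = 0
        for rec in res.logs:
            seg = labels[rec.frame_index * hop:rec.frame_index * hop + flen]
            truth = seg.mean() > 0.5
            correct += (rec.vad_prob >= cal_cfg.vad_threshold) == truth
        assert correct / len(res.logs) > 0.90

    def test_soft_speech_scene_selects_soft_filters(self, cal_cfg):
        spec = SceneSpec("white", 40.0, 50.0, lead_in_s=2.0, speech_s=3.0, seed=21)
        audio, _ = gen_scene(spec, FS)
        res = process(audio, cal_cfg)
        lead_frames = int(2.0 * FS / cal_cfg.hop)
        speech = [l.filter_index for l in res.logs
                  if l.frame_index > lead_frames + cal_cfg.decision_rate_frames]
        modal = collections.Counter(speech).most_common(1)[0][0]
        assert modal in (1, 2)

    def test_quiet_noise_keeps_nr_off(self, cal_cfg):
        spec = SceneSpec("white", 40.0, 65.0, lead_in_s=2.0, speech_s=3.0, seed=22)
        audio, _ = gen_scene(spec, FS)
        res = process(audio, cal_cfg)
        modal = collections.Counter(l.filter_index for l in res.logs).most_common(1)[0][0]
        assert modal in (1, 3, 5)
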