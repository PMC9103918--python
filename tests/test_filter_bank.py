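import collections
from dataclasses import replace

import numpy as np
import pytest

from hearaid import (
    DesignError,
    EngineConfig,
    FlagState,
    SpeechLevel,
    StateError,
    design_filter,
    majority_vote,
    temporary_selection,
)
from hearaid.filter_bank import DecisionBuffer


class TestDesignFilter:
    def test_flat_prescription_gives_unity_response(self, params, band_plan, cfg):
        # Zero makeup and unity ratios ask for 0 dB everywhere: the filter
        # collapses to a pure delay.
        flat = replace(params, ratios=((1.0,) * 5,) * 3,
                       makeup_gains_db=((0.0,) * 5,) * 3)
        filt = design_filter(SpeechLevel.SOFT, False, flat, band_plan, cfg)
        freqs = np.linspace(125.0, 6000.0, 300)
        assert np.max(np.abs(filt.magnitude_db(freqs, cfg.sample_rate_hz))) < 0.1

    def test_soft_filter_matches_makeup_row_at_band_centers(self, filter_bank, band_plan, cfg):
        mags = filter_bank[1].magnitude_db(np.array(band_plan.center_hz),
                                           cfg.sample_rate_hz)
        np.testing.assert_allclose(mags, [10.0, 11.0, 14.0, 25.0, 21.0], atol=0.5)

    def test_all_filters_hit_their_band_gains(self, filter_bank, band_plan, params, cfg):
        from hearaid.wdrc import band_gains_db
        for index, filt in filter_bank.items():
            rep = cfg.representative_level_dbfs(filt.category)
            target = band_gains_db(filt.category, params, rep)
            mags = filt.magnitude_db(np.array(band_plan.center_hz), cfg.sample_rate_hz)
            np.testing.assert_allclose(mags, target, atol=0.5)

    def test_coefficients_symmetric_linear_phase(self, filter_bank):
        for filt in filter_bank.values():
            np.testing.assert_allclose(filt.fir_coefficients,
                                       filt.fir_coefficients[::-1], atol=1e-12)
            assert len(filt.fir_coefficients) % 2 == 1
            assert filt.group_delay_samples == filt.order // 2

    def test_passband_gain_ordering_soft_moderate_loud(self, filter_bank, cfg):
        freqs = np.linspace(125.0, 6000.0, 400)
        means = {i: np.mean(filter_bank[i].magnitude_db(freqs, cfg.sample_rate_hz))
                 for i in (1, 3, 5)}
        assert means[1] > means[3] > means[5]

    def test_excessive_gain_rejected(self, params, band_plan, cfg):
        greedy = replace(params, makeup_gains_db=((80.0,) * 5,) * 3)
        with pytest.raises(DesignError):
            design_filter(SpeechLevel.SOFT, False, greedy, band_plan, cfg)

    def test_nr_flag_recorded(self, filter_bank):
        assert [filter_bank[i].nr_enabled for i in range(1, 7)] == \
            [False, True, False, True, False, True]


class TestTemporarySelection:
    def test_soft_speech_frame_selects_filter_1(self, cfg):
        idx, flags = temporary_selection(0.9, 50.0, FlagState(), cfg)
        assert idx == 1 and flags.wdrc_flag == SpeechLevel.SOFT

    def test_loud_noise_frame_enables_nr(self, cfg):
        start = FlagState(wdrc_flag=SpeechLevel.LOUD, nr_flag=False)
        idx, flags = temporary_selection(0.1, 60.0, start, cfg)
        assert idx == 6 and flags.nr_flag is True

    def test_quiet_noise_frame_disables_nr(self, cfg):
        start = FlagState(wdrc_flag=SpeechLevel.MODERATE, nr_flag=True)
        idx, flags = temporary_selection(0.1, 40.0, start, cfg)
        assert idx == 3 and flags.nr_flag is False

    def test_speech_frame_preserves_nr_flag(self, cfg):
        start = FlagState(wdrc_flag=SpeechLevel.SOFT, nr_flag=True)
        idx, flags = temporary_selection(0.9, 70.0, start, cfg)
        assert idx == 4 and flags.nr_flag is True

    def test_noise_frame_preserves_wdrc_flag(self, cfg):
        start = FlagState(wdrc_flag=SpeechLevel.LOUD, nr_flag=False)
        _, flags = temporary_selection(0.1, 40.0, start, cfg)
        assert flags.wdrc_flag == SpeechLevel.LOUD


class TestMajorityVote:
    def test_plurality_wins(self):
        buf = DecisionBuffer(capacity=200, entries=[3] * 120 + [4] * 80)
        assert majority_vote(buf) == 3

    def test_tie_breaks_to_lowest_index(self):
        buf = DecisionBuffer(capacity=200, entries=[5] * 100 + [2] * 100)
        assert majority_vote(buf) == 2

    def test_unanimous(self):
        buf = DecisionBuffer(capacity=200, entries=[6] * 200)
        assert majority_vote(buf) == 6

    def test_empty_buffer_rejected(self):
        with pytest.raises(StateError):
            majority_vote(DecisionBuffer(capacity=200))

    def test_agrees_with_counting_oracle(self, rng):
        # Brute-force oracle: count occurrences, argmax, lowest index wins.
        for _ in range(2000):
            entries = list(rng.integers(1, 7, size=int(rng.integers(1, 201))))
            buf = DecisionBuffer(capacity=200, entries=entries)
            counts = collections.Counter(entries)
            best = max(counts.values())
            expected = min(i for i, c in counts.items() if c == best)
            assert majority_vote(buf) == expected

    def test_buffer_capacity_enforced(self):
        buf = DecisionBuffer(capacity=2)
        buf.append(1)
        buf.append(2)
        with pytest.raises(StateError):
            buf.append(3)
        buf.flush()
        assert buf.entries == []
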