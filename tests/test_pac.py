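"""Morlet transform and phase-amplitude coherence contracts."""

import numpy as np
import pytest

from emgpac.features.pac import (Comodulogram, MorletParams, WelchConfig,
                                 comodulogram, comodulogram_from_vector,
                                 default_amp_grid, default_phase_grid,
                                 morlet_transform, morlet_wavelet,
                                 pac_coherence, pac_feature_table,
                                 vectorize_comodulogram)
from emgpac.preprocess import segment
from emgpac.simulate import SimConfig, generate_subject

FS = 2048.0


def coupled_signal(f_p=10.0, f_a=150.0, seconds=4.0, rhythm=0.5):
    """Deterministic phase-amplitude coupled signal: AM carrier plus the
    slow rhythm that drives the modulation."""
    t = np.arange(int(seconds * FS)) / FS
    env = (1 + np.cos(2 * np.pi * f_p * t)) / 2
    return env * np.cos(2 * np.pi * f_a * t) + rhythm * np.cos(2 * np.pi * f_p * t)


class TestMorlet:
    def test_unit_energy_at_every_frequency(self):
        for f in (1.0, 5.0, 50.0, 150.0, 350.0):
            w = morlet_wavelet(f, FS)
            assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-6)

    def test_cycles_interpretation_sets_support(self):
        # sigma_t = 7/(2 pi f): support shrinks with frequency
        assert morlet_wavelet(5.0, FS).size > morlet_wavelet(50.0, FS).size

    def test_linearity(self, rng):
        x = rng.standard_normal(2048)
        _, w1 = morlet_transform(x, FS, [40.0])
        _, w2 = morlet_transform(2 * x, FS, [40.0])
        assert np.allclose(w2, 2 * w1)

    def test_sinusoid_envelope_and_phase(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        _, W = morlet_transform(x, FS, [50.0])
        interior = slice(int(0.5 * FS), -int(0.5 * FS))
        env = np.abs(W[0][interior])
        assert np.ptp(env) / env.mean() < 0.02
        phase = np.unwrap(np.angle(W[0][interior]))
        slope = np.polyfit(t[interior], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 50, rel=0.01)

    def test_unsupported_low_frequency_dropped_with_warning(self):
        x = np.zeros(1024)  # 0.5 s: a 2 Hz sigma=7-cycle wavelet cannot fit
        with pytest.warns(UserWarning, match="dropping"):
            kept, _ = morlet_transform(x, FS, [2.0, 100.0])
        assert list(kept) == [100.0]

    def test_all_frequencies_dropped_is_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                morlet_transform(np.zeros(256), FS, [2.0])

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet_wavelet(1500.0, FS)


class TestCoherence:
    def test_coupled_signal_scores_high_at_true_pair(self):
        assert pac_coherence(coupled_signal(), FS, 10.0, 150.0) >= 0.8

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(0)
        vals = [pac_coherence(rng.standard_normal(int(4 * FS)), FS, 10.0, 150.0)
                for _ in range(100)]
        assert np.median(vals) < 0.3

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(int(4 * FS))
        a = pac_coherence(x, FS, 10.0, 150.0)
        b = pac_coherence(5 * x, FS, 10.0, 150.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            v = pac_coherence(rng.standard_normal(int(2 * FS)), FS, 12.0, 100.0)
            assert 0.0 <= v <= 1.0

    def test_requires_amp_above_phase(self):
        with pytest.raises(ValueError):
            pac_coherence(np.zeros(8192), FS, 150.0, 10.0)

    def test_single_welch_segment_rejected(self):
        sig = coupled_signal(seconds=1.0)
        with pytest.raises(ValueError, match="segment"):
            pac_coherence(sig, FS, 20.0, 150.0,
                          welch=WelchConfig(nperseg=2048))


class TestComodulogram:
    def test_values_in_unit_interval_and_mask(self):
        c = comodulogram(coupled_signal(), FS)
        valid = c.values[~np.isnan(c.values)]
        assert ((valid >= 0) & (valid <= 1)).all()
        # masked cells are exactly those with amp <= phase
        for i, fp in enumerate(c.phase_freqs):
            for j, fa in enumerate(c.amp_freqs):
                assert np.isnan(c.values[i, j]) == (fa <= fp)

    def test_argmax_at_injected_pair_for_generated_case_channel(self):
        cfg = SimConfig(duration_s=8.0, muscles=("ECR",),
                        channels_per_muscle=1, coupled_muscles=("ECR",),
                        bad_channel_rate=0.0, seed=7)
        rec = generate_subject(cfg, 0, "case")
        c = comodulogram(rec.samples[0][:int(4 * FS)], FS)
        assert c.cells_away(rec.meta["true_f_phase"],
                            rec.meta["true_f_amp"]) <= 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            comodulogram(np.zeros(8192), FS, [], [])

    def test_fully_masked_grid_rejected(self):
        with pytest.raises(ValueError):
            comodulogram(np.zeros(8192), FS, [100.0], [50.0])

    def test_vectorize_count_and_names(self):
        phase = np.arange(2.0, 31.0, 2.0)          # 15
        amp = np.arange(40.0, 361.0, 10.0)         # 33, all above phase
        c = comodulogram(coupled_signal(seconds=6.0), FS, phase, amp)
        names, vals = vectorize_comodulogram(c)
        assert len(names) == 15 * 33 == 495
        assert names[0] == "PAC_2_40"
        assert np.isfinite(vals).all()

    def test_vectorize_excludes_masked_cells(self):
        c = comodulogram(coupled_signal(), FS, [20.0, 40.0], [30.0, 60.0])
        names, _ = vectorize_comodulogram(c)
        # (20,30),(20,60),(40,60) valid; (40,30) masked
        assert set(names) == {"PAC_20_30", "PAC_20_60", "PAC_40_60"}

    def test_vector_round_trip(self):
        c = comodulogram(coupled_signal(), FS, [10.0, 20.0], [100.0, 150.0])
        names, vals = vectorize_comodulogram(c)
        back = comodulogram_from_vector(names, vals, c.phase_freqs, c.amp_freqs)
        assert np.allclose(back.values, c.values, equal_nan=True)


class TestFeatureTable:
    def _rec(self, seconds, seed=0):
        cfg = SimConfig(duration_s=seconds, muscles=("ECR",),
                        channels_per_muscle=1, coupled_muscles=("ECR",),
                        bad_channel_rate=0.0, seed=seed)
        return generate_subject(cfg, 0, "case")

    def test_rows_align_with_segmentation(self):
        rec = self._rec(6.0)
        table = pac_feature_table(rec, phase_freqs=[10.0], amp_freqs=[150.0])
        assert len(table) == len(segment(rec))
        assert table.columns[-1] == "PAC_10_150"
        assert table["PAC_10_150"].between(0, 1).all()

    def test_epochs_in_one_window_share_their_vector(self):
        rec = self._rec(6.0)
        table = pac_feature_table(rec, phase_freqs=[10.0], amp_freqs=[150.0])
        first_window = table.iloc[:8]["PAC_10_150"]
        assert first_window.nunique() == 1

    def test_short_recording_uses_per_epoch_fallback(self):
        rec = self._rec(2.5)  # 5 epochs, no full 4 s window
        table = pac_feature_table(rec, phase_freqs=[10.0, 14.0],
                                  amp_freqs=[150.0])
        assert len(table) == 5
        assert np.isfinite(table[["PAC_10_150", "PAC_14_150"]].to_numpy()).all()


class TestParameterRecoveryProperties:
    def test_coupling_monotone_in_strength(self):
        """Mean coherence at the true cell is non-decreasing in m."""
        means = []
        for m in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = SimConfig(duration_s=4.0, muscles=("ECR",),
                            channels_per_muscle=1, coupled_muscles=("ECR",),
                            coupling_strength=m, subject_jitter=0.0,
                            bad_channel_rate=0.0, seed=77)
            vals = [pac_coherence(generate_subject(cfg, i, "case").samples[0],
                                  cfg.fs, 10.0, 150.0) for i in range(10)]
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))
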