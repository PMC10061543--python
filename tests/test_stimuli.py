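"""Stimulus generation: ripples, corpus balance, synthesis, noise, mixing."""
from collections import Counter

import numpy as np
import pytest
from scipy.signal import welch

from cisim import stimuli as st


class TestRippleNoise:
    def test_flat_when_zero_contrast(self):
        spec = st.RippleSpec(contrast_db=0.0)
        x = st.ripple_noise(spec, seed=0)
        n = len(x)
        mag = np.abs(np.fft.rfft(x))
        f = np.fft.rfftfreq(n, 1 / spec.fs_hz)
        inband = (f > 400) & (f < 5000)
        assert np.allclose(mag[inband], mag[inband][0], rtol=1e-6)
        assert np.all(mag[f > 5700] < 1e-9)
        assert np.all(mag[(f > 1) & (f < 330)] < 1e-9)

    def test_measured_contrast(self):
        spec = st.RippleSpec(contrast_db=10.0, theta0_rad=1.0)
        x = st.ripple_noise(spec, seed=3)
        f, p = welch(x, fs=spec.fs_hz, nperseg=2048)
        sel = (f > 450) & (f < 4500)
        ldb = 10 * np.log10(p[sel])
        xx = np.log2(f[sel] / 350.0)
        a = np.column_stack([np.sin(np.pi * xx + 1.0), np.cos(np.pi * xx + 1.0),
                             np.ones_like(xx)])
        c, *_ = np.linalg.lstsq(a, ldb, rcond=None)
        assert 2 * np.hypot(c[0], c[1]) == pytest.approx(10.0, abs=1.0)

    def test_ripple_periods_across_band(self):
        octaves = np.log2(5600 / 350)
        assert octaves == pytest.approx(4.0)
        assert octaves * 0.5 == pytest.approx(2.0)   # two full ripple periods

    def test_duration_and_rate(self):
        x = st.ripple_noise(st.RippleSpec(), seed=0)
        assert len(x) == int(0.4 * 17400)

    def test_negative_contrast_rejected(self):
        with pytest.raises(ValueError):
            st.RippleSpec(contrast_db=-1.0)


class TestLoudnessRoving:
    def test_zero_peak_is_exact_mean(self):
        x = np.sin(np.linspace(0, 100, 4000))
        y, level = st.loudness_roving(x, peak_db=0.0, seed=0)
        assert level == st.MEAN_LEVEL_DBFS
        assert st.dbfs(y) == pytest.approx(st.MEAN_LEVEL_DBFS, abs=0.01)

    def test_grid_of_21_levels(self):
        x = np.sin(np.linspace(0, 100, 4000))
        levels = {st.loudness_roving(x, seed=s)[1] for s in range(600)}
        grid = {st.MEAN_LEVEL_DBFS - 5 + 0.5 * k for k in range(21)}
        assert levels == grid

    def test_long_run_mean(self):
        x = np.sin(np.linspace(0, 100, 1000))
        drawn = [st.loudness_roving(x, seed=s)[1] for s in range(5000)]
        # SE of the mean ~ 0.04 dB at n = 5000
        assert np.mean(drawn) == pytest.approx(-49.0, abs=0.15)

    def test_rms_matches_drawn_level(self):
        x = np.random.default_rng(0).normal(size=5000)
        y, level = st.loudness_roving(x, seed=5)
        assert st.dbfs(y) == pytest.approx(level, abs=0.01)


class TestMatrixCorpus:
    def test_balanced_100(self):
        corpus = st.matrix_corpus(seed=11, n_sentences=100)
        counts = Counter(lab for s in corpus for lab in s.labels())
        assert len(counts) == 50
        assert set(counts.values()) == {10}
        assert sum(counts.values()) == 500

    def test_ten_sentence_variant_each_word_once(self):
        corpus = st.matrix_corpus(seed=2, n_sentences=10)
        counts = Counter(lab for s in corpus for lab in s.labels())
        assert set(counts.values()) == {1}

    def test_category_order(self):
        s = st.matrix_corpus(seed=0, n_sentences=10)[0]
        cats = [lab.rstrip("0123456789") for lab in s.labels()]
        assert cats == list(st.CATEGORIES)

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError):
            st.matrix_corpus(seed=0, n_sentences=15)


@pytest.fixture(scope="module")
def inv():
    return st.WordInventory()


class TestSynthSpeech:

    def test_deterministic(self, inv):
        s = st.MatrixSentence((1, 2, 3, 4, 5))
        a, _ = st.synth_speech(s, inv, seed=9)
        b, _ = st.synth_speech(s, inv, seed=9)
        assert np.array_equal(a, b)

    def test_duration_is_words_plus_gaps(self, inv):
        s = st.MatrixSentence((0, 0, 0, 0, 0))
        audio, spans = st.synth_speech(s, inv, seed=0)
        word_dur = sum(t1 - t0 for t0, t1 in spans)
        expected = word_dur + 4 * st.GAP_S + 2 * st.EDGE_SILENCE_S
        assert len(audio) / st.FS_HZ == pytest.approx(expected, abs=0.005)

    def test_words_are_distinct(self, inv):
        """Any two words' (time-normalized, linear-magnitude) spectrograms
        correlate below 0.9."""
        from scipy.signal import stft
        specs = {}
        for lab in inv.labels():
            tok = inv.render_word(lab, seed=0)
            _, _, z = stft(tok, fs=st.FS_HZ, nperseg=256)
            s = np.abs(z)
            idx = np.minimum(np.arange(30) * s.shape[1] // 30, s.shape[1] - 1)
            specs[lab] = s[:, idx].ravel()
        labs = list(specs)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                r = np.corrcoef(specs[labs[i]], specs[labs[j]])[0, 1]
                assert r < 0.9, (labs[i], labs[j], r)

    def test_unknown_word(self, inv):
        with pytest.raises(KeyError):
            inv.render_word("verb99")

    def test_no_clipping_with_roving(self, inv):
        s = st.MatrixSentence((3, 1, 4, 1, 5))
        audio, _ = st.synth_speech(s, inv, seed=1)
        roved, _ = st.loudness_roving(audio, seed=2)
        assert np.max(np.abs(roved)) < 1.0


class TestSpeechShapedNoise:
    def test_third_octave_spectrum_match(self):
        inv = st.WordInventory()
        noise = st.speech_shaped_noise(4.0, inv, seed=0)
        speech = np.concatenate([inv.render_word(lab, seed=0)
                                 for lab in inv.labels()])
        fn, pn = welch(noise, fs=st.FS_HZ, nperseg=1024)
        fs_, ps = welch(speech, fs=st.FS_HZ, nperseg=1024)
        edges = 350.0 * 2 ** (np.arange(0, 13) / 3)    # third octaves in band
        for lo, hi in zip(edges[:-1], edges[1:]):
            bn = pn[(fn >= lo) & (fn < hi)].mean()
            bs = ps[(fs_ >= lo) & (fs_ < hi)].mean()
            diff = 10 * abs(np.log10(bn / bs)
                            - np.log10(pn[(fn > 350) & (fn < 5600)].mean()
                                       / ps[(fs_ > 350) & (fs_ < 5600)].mean()))
            assert diff < 3.0, (lo, hi, diff)


class TestMixAtSnr:
    def setup_method(self):
        self.inv = st.WordInventory()
        self.speech, _ = st.synth_speech(st.MatrixSentence((0, 1, 2, 3, 4)),
                                         self.inv, seed=0)
        self.noise = st.speech_shaped_noise(5.0, self.inv, seed=1)

    def test_zero_snr_equal_rms(self):
        mix = st.mix_at_snr(self.speech, self.noise, 0.0, seed=2)
        sp = st.set_level(self.speech, -49.0)
        exc = mix - sp
        snr = 20 * np.log10(np.sqrt(np.mean(sp**2)) / np.sqrt(np.mean(exc**2)))
        assert snr == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("snr", [-9.0, 6.0, 18.0])
    def test_requested_snr_obtained(self, snr):
        mix = st.mix_at_snr(self.speech, self.noise, snr, seed=3)
        sp = st.set_level(self.speech, -49.0)
        exc = mix - sp
        got = 20 * np.log10(np.sqrt(np.mean(sp**2)) / np.sqrt(np.mean(exc**2)))
        assert got == pytest.approx(snr, abs=0.01)

    def test_clean_condition(self):
        mix = st.mix_at_snr(self.speech, self.noise, None)
        assert st.dbfs(mix) == pytest.approx(-49.0, abs=0.01)

    def test_noise_too_short(self):
        with pytest.raises(ValueError):
            st.mix_at_snr(self.speech, self.noise[:100], 0.0)
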