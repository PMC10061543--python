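"""Synthetic experimental audio: spectral ripple noise, a matrix-sentence
corpus, speech-shaped noise, SNR mixing and loudness roving.

All stimuli are generated, none recorded.  Levels follow the convention
``dBFS = 20*log10(RMS * sqrt(2))`` (full-scale sine = 0 dBFS); experiments
present stimuli around -49 dBFS, the calibration point of the coder.

Spectral ripple noise has a sinusoidal (in log frequency) spectral envelope:

    |F(f)| = 10^(C_t/2 * sin(2 pi log2(f/350) f_RPO + theta_0) / 20)

inside 350--5600 Hz and zero outside, so the in-band peak-to-valley contrast
is exactly ``C_t`` dB.  Component-bin phases are randomized per stimulus (the
standard construction for a noise carrier) in addition to the ripple phase
``theta_0``.

The matrix corpus mirrors a 5 x 10 closed matrix test: five word categories
(name, verb, number, adjective, noun) of ten words each; sentences take one
word per category in fixed order.  Licensed recordings are replaced by a
fully synthetic inventory: each word is a reproducible formant-like token
(glottal pulse train through per-word resonators with fixed duration), so
the corpus structure -- word balance, categories, SNR schedule -- is
preserved while the audio is self-contained.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt, stft

FS_HZ = 17_400.0
BAND_HZ = (350.0, 5600.0)
RIPPLE_DURATION_S = 0.4
MEAN_LEVEL_DBFS = -49.0
CATEGORIES = ("name", "verb", "number", "adjective", "noun")
WORDS_PER_CATEGORY = 10
GAP_S = 0.050          #: silence between words in a sentence
EDGE_SILENCE_S = 0.1   #: lead/tail silence around a sentence

__all__ = ["RippleSpec", "MatrixSentence", "WordInventory", "ripple_noise",
           "loudness_roving", "matrix_corpus", "synth_speech",
           "speech_shaped_noise", "mix_at_snr", "dbfs", "set_level"]


def dbfs(audio: np.ndarray) -> float:
    """Level re full-scale sine: ``20 log10(RMS * sqrt(2))``."""
    rms = float(np.sqrt(np.mean(np.square(audio))))
    return 20.0 * np.log10(max(rms, 1e-30) * np.sqrt(2.0))


def set_level(audio: np.ndarray, level_dbfs: float) -> np.ndarray:
    """Scale to the requested level (exact for non-silent input)."""
    rms = float(np.sqrt(np.mean(np.square(audio))))
    if rms <= 0:
        return audio.copy()
    target = 10.0 ** (level_dbfs / 20.0) / np.sqrt(2.0)
    return audio * (target / rms)


@dataclass(frozen=True)
class RippleSpec:
    """Parameters of one spectral-ripple stimulus."""

    contrast_db: float = 10.0
    ripples_per_octave: float = 0.5
    theta0_rad: float = 0.0
    band_hz: tuple[float, float] = BAND_HZ
    fs_hz: float = FS_HZ
    duration_s: float = RIPPLE_DURATION_S

    def __post_init__(self):
        if self.contrast_db < 0:
            raise ValueError("spectral contrast must be non-negative")


def ripple_noise(spec: RippleSpec, seed: int | None = None,
                 randomize_theta0: bool = False) -> np.ndarray:
    """Random-phase noise with a sinusoidal-in-log-frequency envelope."""
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0, 2 * np.pi) if randomize_theta0 else spec.theta0_rad
    n = int(round(spec.duration_s * spec.fs_hz))
    f = np.fft.rfftfreq(n, 1.0 / spec.fs_hz)
    lo, hi = spec.band_hz
    mag = np.zeros_like(f)
    inband = (f > lo) & (f < hi)
    ripple = np.sin(2 * np.pi * np.log2(f[inband] / lo) * spec.ripples_per_octave
                    + theta0)
    mag[inband] = 10.0 ** (spec.contrast_db / 2.0 * ripple / 20.0)
    phase = rng.uniform(0, 2 * np.pi, len(f))
    spectrum = mag * np.exp(1j * phase)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = np.abs(spectrum[-1])
    return np.fft.irfft(spectrum, n)


def loudness_roving(audio: np.ndarray, mean_dbfs: float = MEAN_LEVEL_DBFS,
                    peak_db: float = 5.0, resolution_db: float = 0.5,
                    seed: int | None = None) -> tuple[np.ndarray, float]:
    """Present the stimulus at a random level on a discrete grid.

    The level is uniform over ``mean +/- peak`` with ``resolution`` spacing
    (21 points for the defaults); returns the scaled audio and the drawn
    level.  Roving removes overall loudness as a discrimination cue.
    """
    steps = int(round(2 * peak_db / resolution_db))
    if abs(steps * resolution_db - 2 * peak_db) > 1e-9:
        raise ValueError("resolution must divide 2*peak")
    rng = np.random.default_rng(seed)
    level = mean_dbfs - peak_db + resolution_db * rng.integers(0, steps + 1)
    return set_level(audio, level), float(level)


@dataclass(frozen=True)
class MatrixSentence:
    """Five word indices (0..9), one per category in fixed order."""

    words: tuple[int, int, int, int, int]

    def __post_init__(self):
        if len(self.words) != len(CATEGORIES):
            raise ValueError("a matrix sentence has exactly 5 words")

    def labels(self) -> list[str]:
        return [f"{cat}{w}" for cat, w in zip(CATEGORIES, self.words)]


def matrix_corpus(seed: int | None = 0, n_sentences: int = 100,
                  ) -> list[MatrixSentence]:
    """Balanced sentence list: every word appears exactly ``n/10`` times.

    Built by stacking independent random permutations of each category's ten
    words; ``n_sentences`` must be a multiple of 10.
    """
    if n_sentences % WORDS_PER_CATEGORY:
        raise ValueError("n_sentences must be a multiple of 10")
    rng = np.random.default_rng(seed)
    layers = n_sentences // WORDS_PER_CATEGORY
    cols = []
    for _ in CATEGORIES:
        col = np.concatenate([rng.permutation(WORDS_PER_CATEGORY)
                              for _ in range(layers)])
        cols.append(col)
    return [MatrixSentence(tuple(int(c[i]) for c in cols))
            for i in range(n_sentences)]


@dataclass(frozen=True)
class WordSpec:
    """Deterministic synthesis recipe for one inventory word."""

    f0_hz: float
    formants_hz: tuple[float, float, float]
    formant_glide: float      #: relative F2 glide over the word
    duration_s: float


class WordInventory:
    """The 50-word synthetic matrix inventory.

    Word recipes are fixed functions of (category, index): fundamental
    frequency, three formant resonances and duration are spread over
    plausible speech ranges so that any two words are spectro-temporally
    distinct.  The same word id always renders the same token up to seeded
    micro-variation of the pitch contour.
    """

    def __init__(self, fs_hz: float = FS_HZ):
        self.fs_hz = fs_hz
        self.specs: dict[str, WordSpec] = {}
        for ci, cat in enumerate(CATEGORIES):
            for w in range(WORDS_PER_CATEGORY):
                k = ci * WORDS_PER_CATEGORY + w
                # mixed-radix recipe: (F1, F2) is unique per word and any two
                # words differ by >= one formant step
                f1 = 300.0 + 130.0 * (k % 5)
                f2 = 950.0 + 165.0 * (k // 5)
                f3 = 2600.0 + 300.0 * (k % 3)
                f0 = 92.0 + 6.0 * (k % 11)
                glide = (-1) ** k * (0.15 + 0.10 * (k % 4) / 3.0)
                dur = 0.250 + 0.250 * ((k * 13) % 10) / 9.0
                self.specs[f"{cat}{w}"] = WordSpec(f0, (f1, f2, f3), glide, dur)

    def labels(self) -> list[str]:
        return list(self.specs)

    def render_word(self, label: str, seed: int | None = None) -> np.ndarray:
        """Glottal-pulse-train-through-resonators token for one word."""
        if label not in self.specs:
            raise KeyError(f"unknown word id {label!r}")
        spec = self.specs[label]
        fs = self.fs_hz
        n = int(round(spec.duration_s * fs))
        rng = np.random.default_rng(seed)
        k = list(self.specs).index(label)
        # pitch contour with +-1% seeded micro-variation
        f0 = spec.f0_hz * (1.0 + 0.01 * rng.standard_normal()) \
            * (1.0 + 0.05 * np.linspace(0, -1, n))
        phase = 2 * np.pi * np.cumsum(f0) / fs
        duty = 0.15 + 0.25 * (k % 5) / 4.0       # source spectral tilt varies
        source = (np.mod(phase, 2 * np.pi) < duty * 2 * np.pi).astype(float)
        source -= source.mean()
        if k % 3 == 0:
            # fricative-like onset burst around the third formant
            burst = int(0.07 * fs)
            noise = rng.standard_normal(burst)
            t_b = np.arange(burst) / fs
            source[:burst] = 0.5 * noise * np.cos(
                2 * np.pi * spec.formants_hz[2] * t_b)
        # two-half formant track: F2 glides by the word's glide fraction
        halves = np.array_split(np.arange(n), 2)
        out = np.zeros(n)
        for hi, idx in enumerate(halves):
            x = source[idx]
            f1, f2, f3 = spec.formants_hz
            f2 = f2 * (1.0 + spec.formant_glide * (hi - 0.5))
            for fc, bw in ((f1, 70.0), (f2, 90.0), (f3, 130.0)):
                r = np.exp(-np.pi * bw / fs)
                th = 2 * np.pi * fc / fs
                b, a = [1.0 - r], [1.0, -2 * r * np.cos(th), r * r]
                x = lfilter(b, a, x)
            out[idx] = x
        # radiation characteristic (+6 dB/oct) balances formant energies
        out = np.diff(out, prepend=out[0])
        # confine to the transmitted band and shape the envelope
        nyq = fs / 2
        sos = butter(4, [BAND_HZ[0] / nyq, BAND_HZ[1] / nyq], btype="band",
                     output="sos")
        out = sosfiltfilt(sos, out)
        ramp = int(0.025 * fs)
        env = np.ones(n)
        env[:ramp] = np.sin(np.linspace(0, np.pi / 2, ramp)) ** 2
        env[-ramp:] = env[:ramp][::-1]
        if k % 2:
            # two-syllable words: a brief energy dip mid-word
            mid = n // 2
            dip = int(0.03 * fs)
            env[mid - dip:mid + dip] *= 0.15
        out *= env
        return set_level(out, MEAN_LEVEL_DBFS)


def synth_speech(sentence: MatrixSentence, inventory: WordInventory | None = None,
                 seed: int | None = 0, gap_s: float = GAP_S,
                 edge_s: float = EDGE_SILENCE_S) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render a sentence: word tokens separated by 50 ms gaps.

    Returns the audio and the (start_s, end_s) span of each word; the spans
    are exact because the generator controls concatenation.
    """
    inventory = inventory or WordInventory()
    fs = inventory.fs_hz
    gap = np.zeros(int(round(gap_s * fs)))
    edge = np.zeros(int(round(edge_s * fs)))
    pieces = [edge]
    spans = []
    t = len(edge) / fs
    for i, label in enumerate(sentence.labels()):
        tok = inventory.render_word(label, seed=None if seed is None
                                    else seed * 53 + i)
        pieces.append(tok)
        spans.append((t, t + len(tok) / fs))
        t += len(tok) / fs
        if i < len(CATEGORIES) - 1:
            pieces.append(gap)
            t += len(gap) / fs
    pieces.append(edge)
    audio = np.concatenate(pieces)
    return set_level(audio, MEAN_LEVEL_DBFS), spans


def corpus_average_spectrum(inventory: WordInventory, n_fft: int = 1024) -> np.ndarray:
    """Mean power spectrum over the 50-word inventory (for the noise shape)."""
    acc = None
    for label in inventory.labels():
        tok = inventory.render_word(label, seed=0)
        _, _, z = stft(tok, fs=inventory.fs_hz, nperseg=n_fft)
        p = np.mean(np.abs(z) ** 2, axis=1)
        acc = p if acc is None else acc + p
    return acc / len(inventory.labels())


def speech_shaped_noise(duration_s: float, inventory: WordInventory | None = None,
                        seed: int | None = 0, fs_hz: float = FS_HZ,
                        _spectrum_cache: dict = {}) -> np.ndarray:
    """Stationary noise with the long-term spectrum of the matrix corpus."""
    inventory = inventory or WordInventory()
    key = id(type(inventory))
    if "spec" not in _spectrum_cache:
        _spectrum_cache["spec"] = corpus_average_spectrum(inventory)
    p = _spectrum_cache["spec"]
    n = int(round(duration_s * fs_hz))
    f = np.fft.rfftfreq(n, 1.0 / fs_hz)
    f_ref = np.linspace(0, fs_hz / 2, len(p))
    mag = np.interp(f, f_ref, np.sqrt(p))
    rng = np.random.default_rng(seed)
    spectrum = mag * np.exp(1j * rng.uniform(0, 2 * np.pi, len(f)))
    spectrum[0] = 0.0
    noise = np.fft.irfft(spectrum, n)
    return set_level(noise, MEAN_LEVEL_DBFS)


def mix_at_snr(speech: np.ndarray, noise: np.ndarray, snr_db: float | None,
               speech_level_dbfs: float = MEAN_LEVEL_DBFS,
               seed: int | None = None) -> np.ndarray:
    """Mix speech at a fixed level with a random noise excerpt at ``snr_db``.

    ``snr_db=None`` is the no-noise (clean) condition.  The noise must be at
    least as long as the speech; a uniformly random excerpt is used.
    """
    speech = set_level(speech, speech_level_dbfs)
    if snr_db is None:
        return speech
    if len(noise) < len(speech):
        raise ValueError("noise must be at least as long as the speech")
    rng = np.random.default_rng(seed)
    off = int(rng.integers(0, len(noise) - len(speech) + 1))
    exc = noise[off:off + len(speech)].copy()
    rms_s = np.sqrt(np.mean(speech**2))
    rms_n = np.sqrt(np.mean(exc**2))
    exc *= rms_s / (rms_n * 10.0 ** (snr_db / 20.0))
    return speech + exc
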