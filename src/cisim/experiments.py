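"""End-to-end SMT and SRT experiments over coding variants and neural health.

An experiment cell is one (coding variant, neural-health condition) pair.
For each cell the chain is: build the electrode-nerve interface, apply
degeneration, fit T/MCL per virtual channel through the spike-count loop,
generate the stimulus corpus, push every stimulus through coder ->
excitation -> fiber population -> internal representation, train the HMM
back-end on the training features, score the test features per condition,
and fit the psychometric function.

* SMT: ripple-vs-flat classification; scores vs spectral contrast (dB),
  chance 50%, threshold at 79.4% correct.
* SRT: matrix-sentence word recognition; scores vs SNR (dB), chance 10%,
  threshold at 50% words correct.

Three built-in profiles scale the compute: ``full`` (9001 fibers, full
corpora -- cluster scale), ``desk`` (901 fibers, 1/10 corpora) and ``smoke``
(201 fibers, reduced corpora and condition grids, for fast checks).  All
randomness derives from one master seed; identical configuration and seed
reproduce identical results.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sound_coding as sc
from . import stimuli as st
from .anf import NeuronParams
from .cochlea import CochleaConfig, HEALTH_PRESETS, apply_degeneration, build_geometry
from .excitation import ExcitationModel, MC_DEFAULT
from .fitting import fit_map
from .internal_representation import IRConfig, InternalRepresentationExtractor
from .pipeline import schedule_from_table, simulate_population
from .psychometrics import (PsychometricResult, ThresholdUndefinedError,
                            fit_psychometric, threshold)
from .recognizer import SentenceDecoder, log_likelihood, train_hmm

SMT_CRITERION = 79.4
SRT_CRITERION = 50.0
SMT_CHANCE = 50.0
SRT_CHANCE = 10.0
VARIANTS = ("S", "P", "T")
HEALTH_CONDITIONS = ("healthy", "moderate", "severe")

__all__ = ["ExperimentProfile", "PROFILES", "Pipeline", "SmtResult",
           "SrtResult", "run_smt", "run_srt", "run_matrix"]


@dataclass(frozen=True)
class ExperimentProfile:
    """Corpus sizes, condition grids and model scale of one compute profile."""

    name: str
    n_fibers: int
    smt_train_per_class: int
    smt_test_per_condition: int      #: per class (ripple and reference)
    smt_contrasts: tuple = (2, 3, 4, 5, 7, 9, 11, 14, 17, 20)
    smt_train_contrast_range: tuple = (2, 20)
    srt_n_sentences: int = 100
    srt_train_snrs: tuple = (0, 3, 6, 9, 12, 15, 18, None)   #: None = clean
    srt_test_snrs: tuple = (-9, -6, -3, 0, 3, 6, 9, 12, 15, 18)
    fitting_seeds: tuple = (0, 1, 2)
    degeneration_sd: float = 3.0


PROFILES = {
    "full": ExperimentProfile("full", 9001, 1000, 50),
    "desk": ExperimentProfile("desk", 901, 100, 5, srt_n_sentences=10),
    "smoke": ExperimentProfile(
        "smoke", 201, 30, 3, smt_contrasts=(2, 4, 7, 11, 14, 20),
        srt_n_sentences=10, srt_train_snrs=(0, 6, 12, 18, None),
        srt_test_snrs=(-9, -6, -3, 0, 3, 6, 9, 15)),
}


def _child_seed(master: int, *key) -> int:
    """Deterministic sub-seed below 2**31 for a named stage."""
    import zlib
    tags = [zlib.crc32(repr(k).encode()) for k in key]
    ss = np.random.SeedSequence([int(master)] + tags)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class Pipeline:
    """Front end of one experiment cell: audio in, IR feature matrix out."""

    def __init__(self, variant: str, health: str | float,
                 profile: ExperimentProfile | str = "desk", master_seed: int = 0,
                 cochlea_config: CochleaConfig | None = None,
                 neuron_params: NeuronParams | None = None,
                 coder_config: sc.CoderConfig | None = None,
                 ir_config: IRConfig | None = None, m_c: float = MC_DEFAULT):
        if isinstance(profile, str):
            profile = PROFILES[profile]
        self.profile = profile
        self.variant = variant
        self.health = health
        self.master_seed = master_seed
        self.m_c = m_c
        mean = HEALTH_PRESETS[health] if isinstance(health, str) else float(health)
        cfg = cochlea_config or CochleaConfig(n_fibers=profile.n_fibers)
        base = build_geometry(cfg)
        self.interface = apply_degeneration(
            base, mean, profile.degeneration_sd,
            seed=_child_seed(master_seed, "degeneration", mean))
        self.excitation = ExcitationModel(self.interface)
        self.neuron_params = neuron_params or NeuronParams()
        self.coder_config = coder_config or sc.CoderConfig()
        self.table = sc.build_pulse_table(variant)
        self.schedule = schedule_from_table(self.table)
        self.fitting_map, self.fitting_diagnostics = fit_map(
            self.excitation, self.neuron_params, m_c,
            seeds=tuple(_child_seed(master_seed, "fit", s)
                        for s in profile.fitting_seeds))
        self.extractor = InternalRepresentationExtractor(
            self.interface, self.excitation, ir_config)

    def with_variant(self, variant: str) -> "Pipeline":
        """Same cell with a different coding variant.

        Geometry, degeneration, fitting and the filter bank do not depend on
        the pulse-table variant, so they are shared; only the stimulation
        schedule changes.
        """
        clone = object.__new__(Pipeline)
        clone.__dict__.update(self.__dict__)
        clone.variant = variant
        clone.table = sc.build_pulse_table(variant)
        clone.schedule = schedule_from_table(clone.table)
        return clone

    def features(self, audio: np.ndarray, fs: float, seed: int) -> np.ndarray:
        """IR feature matrix (frames x groups) for one stimulus."""
        amp_cu, steer, duration_us = sc.analyze_cycles(
            audio, fs, self.fitting_map, self.coder_config)
        spikes = simulate_population(
            self.excitation, self.schedule, amp_cu, steer, self.neuron_params,
            self.m_c, seed=seed)
        return self.extractor(spikes, duration_s=duration_us * 1e-6).T


@dataclass
class SmtResult:
    threshold_db: float | None
    psychometric: PsychometricResult
    scores: pd.DataFrame
    profile: str
    variant: str
    health: str | float
    master_seed: int


@dataclass
class SrtResult:
    threshold_db: float | None
    psychometric: PsychometricResult
    scores: pd.DataFrame
    profile: str
    variant: str
    health: str | float
    master_seed: int


def run_smt(pipeline: Pipeline, master_seed: int | None = None) -> SmtResult:
    """Spectral-modulation-threshold experiment for one cell.

    Training: ripples at random integer contrasts within the training range
    plus flat references, all loudness-roved.  Testing: the fixed contrast
    grid, equal ripple/reference counts; binary classification by model
    log-likelihood; threshold at 79.4% correct.
    """
    prof = pipeline.profile
    seed = pipeline.master_seed if master_seed is None else master_seed
    rng = np.random.default_rng(_child_seed(seed, "smt-corpus"))
    lo, hi = prof.smt_train_contrast_range

    def make_stim(contrast, idx, stage):
        spec = st.RippleSpec(contrast_db=contrast)
        s = _child_seed(seed, "smt", stage, idx)
        audio = st.ripple_noise(spec, seed=s, randomize_theta0=True)
        audio, _ = st.loudness_roving(audio, seed=s + 1)
        return pipeline.features(audio, spec.fs_hz, seed=s + 2)

    train = {"target": [], "reference": []}
    for i in range(prof.smt_train_per_class):
        train["target"].append(make_stim(int(rng.integers(lo, hi + 1)), i, "tr-t"))
        train["reference"].append(make_stim(0.0, i, "tr-r"))
    models = {lab: train_hmm(feats, lab) for lab, feats in train.items()}

    rows = []
    for c in prof.smt_contrasts:
        correct = 0
        total = 0
        for i in range(prof.smt_test_per_condition):
            for truth, contrast in (("target", float(c)), ("reference", 0.0)):
                f = make_stim(contrast, i, f"te-{truth}-{c}")
                lls = {lab: log_likelihood(m, f) for lab, m in models.items()}
                pred = max(lls, key=lls.get)
                correct += int(pred == truth)
                total += 1
        rows.append({"contrast_db": float(c), "n": total,
                     "percent_correct": 100.0 * correct / total})
    scores = pd.DataFrame(rows)
    psy = fit_psychometric(scores["percent_correct"], scores["contrast_db"],
                           p_chance=SMT_CHANCE)
    try:
        thr = threshold(psy, SMT_CRITERION)
    except ThresholdUndefinedError:
        thr = None
    return SmtResult(thr, psy, scores, prof.name, pipeline.variant,
                     pipeline.health, seed)


def _word_frames(features: np.ndarray, spans, fps: float = 100.0):
    """Slice the feature matrix into per-word and gap frame ranges."""
    T = len(features)
    word_feats = []
    occupied = np.zeros(T, dtype=bool)
    for t0, t1 in spans:
        i0, i1 = int(np.floor(t0 * fps)), min(int(np.ceil(t1 * fps)), T)
        word_feats.append(features[i0:i1])
        occupied[i0:i1] = True
    sil = features[~occupied]
    return word_feats, sil


def run_srt(pipeline: Pipeline, master_seed: int | None = None) -> SrtResult:
    """Speech-reception-threshold experiment for one cell.

    A balanced matrix corpus is mixed with speech-shaped noise at the
    training SNRs (plus clean); word models are trained on the word segments
    pooled over all training conditions, then every sentence is decoded at
    each test SNR through the five-slot grammar.  Threshold at 50% words
    correct.
    """
    prof = pipeline.profile
    seed = pipeline.master_seed if master_seed is None else master_seed
    inv = st.WordInventory()
    corpus = st.matrix_corpus(_child_seed(seed, "srt-corpus"),
                              n_sentences=prof.srt_n_sentences)
    noise = st.speech_shaped_noise(6.0, inv, seed=_child_seed(seed, "srt-noise"))

    word_train: dict[str, list] = {lab: [] for lab in inv.labels()}
    sil_train = []
    for si, sent in enumerate(corpus):
        audio, spans = st.synth_speech(sent, inv, seed=_child_seed(seed, "syn", si))
        for ci, snr in enumerate(prof.srt_train_snrs):
            s = _child_seed(seed, "srt-train", si, ci)
            mixed = st.mix_at_snr(audio, noise, snr, seed=s)
            feats = pipeline.features(mixed, st.FS_HZ, seed=s + 1)
            wf, sil = _word_frames(feats, spans)
            for lab, f in zip(sent.labels(), wf):
                word_train[lab].append(f)
            if len(sil):
                sil_train.append(sil)
    word_models = [[train_hmm(word_train[f"{cat}{w}"], f"{cat}{w}")
                    for w in range(st.WORDS_PER_CATEGORY)]
                   for cat in st.CATEGORIES]
    silence = train_hmm(sil_train, "sil", n_states=1)
    decoder = SentenceDecoder(word_models, silence)

    rows = []
    for snr in prof.srt_test_snrs:
        correct = 0
        total = 0
        for si, sent in enumerate(corpus):
            audio, spans = st.synth_speech(sent, inv, seed=_child_seed(seed, "syn", si))
            s = _child_seed(seed, "srt-test", si, int(snr * 10))
            mixed = st.mix_at_snr(audio, noise, float(snr), seed=s)
            feats = pipeline.features(mixed, st.FS_HZ, seed=s + 1)
            decoded, _ = decoder.decode(feats)
            correct += sum(int(d == w) for d, w in zip(decoded, sent.words))
            total += len(sent.words)
        rows.append({"snr_db": float(snr), "n": total,
                     "percent_correct": 100.0 * correct / total})
    scores = pd.DataFrame(rows)
    psy = fit_psychometric(scores["percent_correct"], scores["snr_db"],
                           p_chance=SRT_CHANCE)
    try:
        thr = threshold(psy, SRT_CRITERION)
    except ThresholdUndefinedError:
        thr = None
    return SrtResult(thr, psy, scores, prof.name, pipeline.variant,
                     pipeline.health, seed)


def _cell_cache_key(profile: ExperimentProfile, master_seed: int, exp: str,
                    variant: str, health) -> str:
    import hashlib
    cfg = repr(dataclasses.astuple(profile)) + repr((master_seed, exp, variant,
                                                     health))
    return hashlib.sha1(cfg.encode()).hexdigest()[:16]


def run_matrix(profile: ExperimentProfile | str = "desk", master_seed: int = 0,
               experiments: tuple = ("smt", "srt"), variants: tuple = VARIANTS,
               healths: tuple = HEALTH_CONDITIONS, cache_dir=None,
               progress=None) -> pd.DataFrame:
    """All (variant x health) cells for the requested experiment types.

    Returns one row per cell and experiment with the fitted threshold, the
    psychometric parameters and goodness of fit.  Cells share nothing but
    the master seed; a failed cell is reported with NaNs and the run
    continues.  With ``cache_dir`` set, finished cells are stored as JSON
    keyed by a hash of (profile, seed, cell) and re-runs resume from them.
    """
    import json
    from pathlib import Path
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for health in healths:
        base = None
        fit_error = None
        for variant in variants:
            for exp in experiments:
                cache_file = None
                if cache_dir is not None:
                    key = _cell_cache_key(profile, master_seed, exp, variant,
                                          health)
                    cache_file = cache_dir / f"cell_{key}.json"
                    if cache_file.exists():
                        rows.append(json.loads(cache_file.read_text()))
                        continue
                if base is None and fit_error is None:
                    try:
                        base = Pipeline(variant, health, profile, master_seed)
                    except Exception as err:   # fitting failure etc.
                        fit_error = str(err)
                if fit_error is not None:
                    rows.append({"experiment": exp, "variant": variant,
                                 "health": health, "threshold_db": np.nan,
                                 "error": fit_error})
                    continue
                pipe = base.with_variant(variant)
                if progress:
                    progress(f"{exp} {variant} {health}")
                try:
                    res = run_smt(pipe) if exp == "smt" else run_srt(pipe)
                    row = {
                        "experiment": exp, "variant": variant, "health": health,
                        "threshold_db": np.nan if res.threshold_db is None
                        else res.threshold_db,
                        "p_max": res.psychometric.p_max,
                        "slope": res.psychometric.s,
                        "x_o": res.psychometric.x_o,
                        "r_squared": res.psychometric.r_squared,
                        "error": "",
                    }
                except Exception as err:
                    row = {"experiment": exp, "variant": variant,
                           "health": health, "threshold_db": np.nan,
                           "error": str(err)}
                rows.append(row)
                if cache_file is not None and not row["error"]:
                    cache_file.write_text(json.dumps(
                        {k: (None if isinstance(v, float) and np.isnan(v) else v)
                         for k, v in row.items()}, default=float))
    return pd.DataFrame(rows)
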