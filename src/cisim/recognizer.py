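"""Whole-stimulus HMM back-end for the simulated discrimination experiments.

Each stimulus class (a word, or the ripple/flat reference classes) is an
8-state left-to-right hidden Markov model with self-loops and one diagonal-
covariance Gaussian per state over the internal-representation features.
Training is segmental k-means: uniform segmentation seeds the states, then
Viterbi alignment and exact per-state maximum-likelihood updates alternate
until the alignments stop changing; the Viterbi data log-likelihood is
non-decreasing along the way.  Training is deterministic (no random
initialization).

Recognition is Viterbi decoding against a grammar: a two-class comparison
for the spectral task, or a five-slot word chain (one word per category,
separated by a shared silence model) for the matrix-sentence task.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_STATES = 8
VAR_FLOOR_FRAC = 1e-4
LOG0 = -1e30

__all__ = ["StimulusHMM", "train_hmm", "viterbi", "log_likelihood",
           "SentenceDecoder", "TrainingError"]


class TrainingError(RuntimeError):
    pass


@dataclass
class StimulusHMM:
    """Left-to-right Gaussian HMM for one stimulus class."""

    label: str
    means: np.ndarray        #: (n_states, dim)
    variances: np.ndarray    #: (n_states, dim), floored
    log_self: np.ndarray     #: (n_states,) log self-transition
    log_adv: np.ndarray      #: (n_states,) log advance (last state: exit)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    def frame_logprob(self, x: np.ndarray) -> np.ndarray:
        """(T, n_states) per-frame emission log-likelihoods."""
        x = np.atleast_2d(x)
        diff = x[:, None, :] - self.means[None]
        return -0.5 * np.sum(diff * diff / self.variances[None]
                             + np.log(2 * np.pi * self.variances)[None], axis=2)

    def to_json(self) -> dict:
        return {"label": self.label, "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "log_self": self.log_self.tolist(),
                "log_adv": self.log_adv.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "StimulusHMM":
        return cls(obj["label"], np.asarray(obj["means"]),
                   np.asarray(obj["variances"]), np.asarray(obj["log_self"]),
                   np.asarray(obj["log_adv"]))


def _lr_viterbi(logb: np.ndarray, log_self: np.ndarray, log_adv: np.ndarray):
    """Viterbi path through one left-to-right model (entry at state 0,
    exit from the last state); returns (path, log-likelihood incl. exit)."""
    T, S = logb.shape
    delta = np.full((T, S), LOG0)
    psi = np.zeros((T, S), dtype=np.int32)
    delta[0, 0] = logb[0, 0]
    for t in range(1, T):
        stay = delta[t - 1] + log_self
        adv = np.concatenate([[LOG0], delta[t - 1, :-1] + log_adv[:-1]])
        take_adv = adv > stay
        delta[t] = np.where(take_adv, adv, stay) + logb[t]
        psi[t] = np.where(take_adv, np.arange(S) - 1, np.arange(S))
    ll = delta[-1, -1] + log_adv[-1]
    path = np.empty(T, dtype=np.int32)
    path[-1] = S - 1
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, float(ll)


def log_likelihood(model: StimulusHMM, features: np.ndarray) -> float:
    """Viterbi log-likelihood of a whole stimulus under one model."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    if features.shape[0] < model.n_states:
        # too short to traverse all states: compress by merging frames
        features = _stretch(features, model.n_states)
    return _lr_viterbi(model.frame_logprob(features), model.log_self,
                       model.log_adv)[1]


def viterbi(model: StimulusHMM, features: np.ndarray):
    """State path and log-likelihood for one stimulus."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return _lr_viterbi(model.frame_logprob(features), model.log_self,
                       model.log_adv)


def _stretch(x: np.ndarray, n: int) -> np.ndarray:
    idx = np.minimum((np.arange(n) * len(x) // n), len(x) - 1)
    return x[idx]


def _estimate(sequences, assignments, n_states, dim, var_floor):
    sums = np.zeros((n_states, dim))
    sqs = np.zeros((n_states, dim))
    cnt = np.zeros(n_states)
    stay = np.zeros(n_states)
    leave = np.zeros(n_states)
    for x, a in zip(sequences, assignments):
        for s in range(n_states):
            m = a == s
            cnt[s] += m.sum()
            sums[s] += x[m].sum(axis=0)
            sqs[s] += (x[m] ** 2).sum(axis=0)
        trans_stay = (a[1:] == a[:-1])
        for s in range(n_states):
            stay[s] += np.sum(trans_stay & (a[:-1] == s))
            leave[s] += np.sum(~trans_stay & (a[:-1] == s))
        leave[a[-1]] += 1.0  # exit counts as an advance
    cnt = np.maximum(cnt, 1.0)
    means = sums / cnt[:, None]
    var = np.maximum(sqs / cnt[:, None] - means**2, var_floor)
    tot = np.maximum(stay + leave, 1.0)
    p_stay = np.clip(stay / tot, 1e-6, 1.0 - 1e-6)
    return means, var, np.log(p_stay), np.log(1.0 - p_stay)


def train_hmm(sequences: list, label: str = "", n_states: int = N_STATES,
              max_iter: int = 20, var_floor_frac: float = VAR_FLOOR_FRAC,
              ) -> StimulusHMM:
    """Segmental k-means training of one stimulus model.

    Requires at least two example sequences.  Sequences shorter than the
    state count are frame-replicated to length ``n_states``.  Deterministic:
    uniform initial segmentation, exact ML updates, Viterbi realignment,
    stop on unchanged alignment or ``max_iter``.
    """
    if len(sequences) < 2:
        raise TrainingError(f"label {label!r}: need >= 2 training examples")
    seqs = []
    for x in sequences:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if len(x) < n_states:
            x = _stretch(x, n_states)
        seqs.append(x)
    dim = seqs[0].shape[1]
    global_var = np.var(np.concatenate(seqs), axis=0)
    var_floor = np.maximum(var_floor_frac * global_var, 1e-12)

    assignments = [np.minimum(np.arange(len(x)) * n_states // len(x),
                              n_states - 1) for x in seqs]
    model = None
    for _ in range(max_iter):
        means, var, lself, ladv = _estimate(seqs, assignments, n_states, dim,
                                            var_floor)
        model = StimulusHMM(label, means, var, lself, ladv)
        new_assign = [_lr_viterbi(model.frame_logprob(x), lself, ladv)[0]
                      for x in seqs]
        if all(np.array_equal(a, b) for a, b in zip(assignments, new_assign)):
            break
        assignments = new_assign
    return model


class SentenceDecoder:
    """Viterbi decoding of a five-slot matrix sentence.

    The grammar is ``sil w1 sil w2 sil w3 sil w4 sil w5 sil`` where slot
    ``k`` chooses among the ten word models of category ``k``; the silence
    model is a single-state HMM trained on gap frames.  Decoding maximizes
    the joint path likelihood over all 10^5 word sequences without
    enumerating them.
    """

    def __init__(self, word_models: list[list[StimulusHMM]],
                 silence: StimulusHMM):
        self.word_models = word_models
        self.silence = silence
        if silence.n_states != 1:
            raise ValueError("silence model must have a single state")

    def decode(self, features: np.ndarray) -> tuple[list[int], float]:
        """Most likely word index per slot and the path log-likelihood."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        T = len(x)
        n_slots = len(self.word_models)
        n_words = len(self.word_models[0])
        S = self.word_models[0][0].n_states
        dim = self.word_models[0][0].means.shape[1]
        if x.shape[1] != dim:
            raise ValueError("feature dimension does not match the models")

        # stack all word models for one vectorized emission computation
        means = np.stack([m.means for slot in self.word_models for m in slot])
        var = np.stack([m.variances for slot in self.word_models for m in slot])
        lself = np.stack([m.log_self for slot in self.word_models for m in slot])
        ladv = np.stack([m.log_adv for slot in self.word_models for m in slot])
        diff = x[:, None, None, :] - means[None]
        logb = -0.5 * np.sum(diff**2 / var[None] + np.log(2 * np.pi * var)[None],
                             axis=3)                     # (T, slots*words, S)
        logb = logb.reshape(T, n_slots, n_words, S)
        lself = lself.reshape(n_slots, n_words, S)
        ladv = ladv.reshape(n_slots, n_words, S)
        logb_sil = self.silence.frame_logprob(x)[:, 0]   # (T,)
        sil_self = float(self.silence.log_self[0])
        sil_adv = float(self.silence.log_adv[0])

        d_word = np.full((n_slots, n_words, S), LOG0)
        d_sil = np.full(n_slots + 1, LOG0)
        bp_word = np.full((T, n_slots, n_words, S), -1, dtype=np.int8)
        bp_sil_word = np.full((T, n_slots + 1), -1, dtype=np.int16)

        d_sil = d_sil.copy()
        d_sil[0] = logb_sil[0]
        ll_end = LOG0
        best_end_t_word = None
        word_of_slot_tb = np.full((T, n_slots), -1, dtype=np.int16)

        for t in range(1, T):
            # word-state updates
            stay = d_word + lself
            adv = np.full_like(d_word, LOG0)
            adv[:, :, 1:] = d_word[:, :, :-1] + ladv[:, :, :-1]
            new_d = np.maximum(stay, adv)
            bp = np.where(adv > stay, 1, 0)             # 1 = advanced
            # entry into state 0 from the preceding silence
            enter0 = d_sil[:n_slots, None] + sil_adv    # (slots, 1)
            better = enter0 > new_d[:, :, 0]
            new_d[:, :, 0] = np.where(better, enter0, new_d[:, :, 0])
            bp0 = np.where(better, 2, bp[:, :, 0])      # 2 = entered from sil
            bp[:, :, 0] = bp0
            new_d += logb[t]
            # silence updates: stay, or exit of any word of previous slot
            exit_word = d_word[:, :, -1] + ladv[:, :, -1]   # (slots, words)
            best_w = np.argmax(exit_word, axis=1)
            best_v = exit_word[np.arange(n_slots), best_w]
            sil_stay = d_sil + sil_self
            new_sil = sil_stay.copy()
            from_word = np.concatenate([[LOG0], best_v])
            take = from_word > sil_stay
            new_sil = np.where(take, from_word, sil_stay) + logb_sil[t]
            bp_sil_word[t] = np.where(take, np.concatenate([[-1], best_w]), -1)
            d_word = new_d
            d_sil = new_sil
            bp_word[t] = bp

        ll = d_sil[-1] + sil_adv

        # traceback: walk backwards through silence/word segments
        slots_out = [-1] * n_slots
        t = T - 1
        pos = n_slots          # index into silence chain (end)
        state = ("sil", pos)
        cur_word = -1
        cur_state = -1
        while t > 0:
            if state[0] == "sil":
                w = bp_sil_word[t, state[1]]
                if w >= 0:
                    slot = state[1] - 1
                    slots_out[slot] = int(w)
                    cur_word = int(w)
                    cur_state = S - 1
                    state = ("word", slot)
                t -= 1
            else:
                slot = state[1]
                move = bp_word[t, slot, cur_word, cur_state]
                if move == 1:
                    cur_state -= 1
                elif move == 2:
                    state = ("sil", slot)
                t -= 1
        return slots_out, float(ll)
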