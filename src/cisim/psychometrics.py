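"""Psychometric-function fitting and threshold extraction.

Per-condition percent-correct scores are regressed onto the logistic

    Ps(x) = p_chance + p_range / (1 + exp(-s (x - x_o)))

with the chance level fixed by the task design (50% for the two-alternative
spectral task, 10% for the ten-alternative word task), ``p_range`` bounded by
``100 - p_chance`` and the growth rate ``s`` positive.  The threshold at a
criterion level is the closed-form inversion

    x = x_o - ln(p_range / (criterion - p_chance) - 1) / s.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PsychometricResult", "ThresholdUndefinedError", "FitFailureError",
           "psychometric", "fit_psychometric", "threshold"]


class ThresholdUndefinedError(RuntimeError):
    """The criterion lies at or above the fitted upper asymptote."""


class FitFailureError(RuntimeError):
    """The non-linear regression did not converge from any start point."""


def psychometric(x, p_chance, p_range, s, x_o):
    """Evaluate ``Ps(x)`` (percent correct)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-s * (x - x_o), -500.0, 500.0)   # avoid overflow far from x_o
    return p_chance + p_range / (1.0 + np.exp(z))


@dataclass
class PsychometricResult:
    """Fitted psychometric parameters with goodness of fit."""

    p_chance: float
    p_range: float
    s: float
    x_o: float
    r_squared: float
    conditions: np.ndarray
    scores: np.ndarray

    @property
    def p_max(self) -> float:
        return self.p_chance + self.p_range

    def __call__(self, x):
        return psychometric(x, self.p_chance, self.p_range, self.s, self.x_o)


def fit_psychometric(scores, conditions, p_chance: float) -> PsychometricResult:
    """Least-squares fit with ``p_chance`` fixed and multi-start initialization.

    Start points place ``x_o`` at the empirical mid-range crossing and try a
    small grid of slopes; the best converged fit (lowest residual) wins.
    """
    scores = np.asarray(scores, dtype=float)
    conditions = np.asarray(conditions, dtype=float)
    if len(scores) != len(conditions) or len(scores) < 4:
        raise ValueError("need >= 4 matched (condition, score) pairs")
    if np.any((scores < 0) | (scores > 100)):
        raise ValueError("scores must be percentages in [0, 100]")
    max_range = 100.0 - p_chance

    def resid(p):
        p_range, s, x_o = p
        return psychometric(conditions, p_chance, p_range, s, x_o) - scores

    # empirical mid-range crossing for x_o initialization
    rng0 = max(np.max(scores) - p_chance, 1.0)
    mid = p_chance + rng0 / 2.0
    above = conditions[scores >= mid]
    x0_init = float(above.min()) if len(above) else float(np.median(conditions))

    best = None
    x_starts = {x0_init, float(conditions.min()), float(np.median(conditions)),
                float(conditions.max())}
    for s0 in (0.1, 0.3, 1.0, 3.0):
        for x0 in x_starts:
            try:
                sol = least_squares(
                    resid, x0=[min(rng0, max_range), s0, x0],
                    bounds=([0.0, 1e-6, conditions.min() - 60.0],
                            [max_range, 50.0, conditions.max() + 60.0]))
            except Exception:
                continue
            if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitFailureError("psychometric regression failed from all starts")
    p_range, s, x_o = best.x
    # parsimony: scores flat at chance fit equally well with no range at all
    flat_cost = 0.5 * float(np.sum((scores - p_chance) ** 2))
    if flat_cost <= best.cost + 1e-9:
        p_range = 0.0
    ss_res = float(np.sum(best.fun ** 2))
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return PsychometricResult(p_chance=p_chance, p_range=float(p_range),
                              s=float(s), x_o=float(x_o), r_squared=r2,
                              conditions=conditions, scores=scores)


def threshold(result: PsychometricResult, criterion: float) -> float:
    """Stimulus value where the fitted function crosses ``criterion`` percent."""
    if not (result.p_chance < criterion):
        raise ValueError("criterion must exceed the chance level")
    if criterion >= result.p_max:
        raise ThresholdUndefinedError(
            f"criterion {criterion}% is not reached (p_max = {result.p_max:.1f}%)")
    return float(result.x_o
                 - np.log(result.p_range / (criterion - result.p_chance) - 1.0)
                 / result.s)
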