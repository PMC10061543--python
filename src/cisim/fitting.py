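"""Virtual fitting (T/MCL per virtual channel) and model calibration.

The clinical fitting loop -- audiologist adjusts the level, the listener
reports loudness -- is closed virtually through the spike count of the fiber
population: for each virtual channel a 200 ms, ~1852 pps biphasic pulse train
(10 ms silence margins) is presented at increasing clinical units, and the
most comfortable level (MCL) is declared where the mean per-pulse firing
probability of the channel's fitting group (the 858 fibers with the highest
absolute activation, scaled proportionally for smaller populations) crosses
75%.  The threshold level T is 10% of MCL, giving a 20 dB electric dynamic
range.

The 75% criterion is interpreted as the mean per-pulse, per-fiber firing
probability across the group; an any-fiber-fires reading saturates
immediately with hundreds of fibers and is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sound_coding as sc
from .anf import NeuronParams
from .cochlea import ElectrodeNerveInterface
from .excitation import ExcitationModel, MC_DEFAULT
from .pipeline import simulate_population, single_channel_schedule

REFERENCE_GROUP_SIZE = 858     #: fitting-group size in the full 9001-fiber model
REFERENCE_POPULATION = 9001
FITTING_TRAIN_MS = 200.0
FITTING_MARGIN_MS = 10.0
FITTING_PROBABILITY = 0.75
SWEEP_CU = tuple(range(1, 452, 30)) + (471,)
DEFAULT_STEER = 4              #: fitting stimulates the pair at c = 4/8

__all__ = ["FittingError", "make_fitting_pulse_train", "select_fitting_group",
           "pulse_response_probability", "estimate_mcl", "fit_map", "calibrate_mc"]


class FittingError(RuntimeError):
    """A channel could not be fitted (probability never reached criterion)."""


def make_fitting_pulse_train(channel: int, cu: float,
                             steering: float = DEFAULT_STEER / sc.N_STEER,
                             phase_us: float = sc.PHASE_US) -> sc.Electrodogram:
    """Fitting stimulus: 200 ms of 540 us-periodic biphasic pulses on one
    virtual channel with 10 ms leading/trailing silence."""
    if not (1 <= cu <= sc.CU_MAX):
        raise ValueError(f"cu must be in [1, {sc.CU_MAX}]")
    if not (1 <= channel <= sc.N_CHANNELS):
        raise ValueError("channel must be in 1..15")
    n_pulses = int(FITTING_TRAIN_MS * 1000 // sc.CHANNEL_PERIOD_US)
    onsets = FITTING_MARGIN_MS * 1000 + np.arange(n_pulses) * sc.CHANNEL_PERIOD_US
    ev = np.zeros(n_pulses, dtype=sc.EVENT_DTYPE)
    ev["onset_us"] = onsets
    ev["channel"] = channel
    ev["electrode_apical"] = channel
    ev["electrode_basal"] = channel + 1
    ev["steering"] = steering
    ev["amplitude_cu"] = cu
    ev["phase_us"] = phase_us
    duration = 2 * FITTING_MARGIN_MS * 1000 + FITTING_TRAIN_MS * 1000
    return sc.Electrodogram(ev, duration)


def scaled_group_size(n_fibers: int) -> int:
    """Fitting-group size rescaled to the modeled population."""
    return max(1, round(REFERENCE_GROUP_SIZE * n_fibers / REFERENCE_POPULATION))


def select_fitting_group(channel: int, model: ExcitationModel,
                         steer_idx: int = DEFAULT_STEER) -> np.ndarray:
    """Fibers with the highest absolute activation for this channel.

    Ranked by max-over-nodes |A| of the channel's steering pattern; the group
    is not required to be spatially contiguous.
    """
    pat = model.channel_patterns[channel - 1, steer_idx]
    strength = np.max(np.abs(pat), axis=1)
    k = scaled_group_size(len(strength))
    order = np.argsort(strength)[::-1]
    return np.sort(order[:k])


def pulse_response_probability(channel: int, cu: float, model: ExcitationModel,
                               group: np.ndarray, params: NeuronParams,
                               m_c: float, seeds: tuple[int, ...]) -> float:
    """Mean per-pulse, per-fiber firing probability over the active span."""
    sched = single_channel_schedule(channel)
    n_pulses = int(FITTING_TRAIN_MS * 1000 // sc.CHANNEL_PERIOD_US)
    amp = np.full((n_pulses, sc.N_CHANNELS), 0.0)
    amp[:, channel - 1] = cu
    steer = np.full((n_pulses, sc.N_CHANNELS), DEFAULT_STEER, dtype=np.int64)
    t0 = FITTING_MARGIN_MS * 1e-3
    t1 = t0 + FITTING_TRAIN_MS * 1e-3
    probs = []
    for s in seeds:
        spk = simulate_population(model, sched, amp, steer, params, m_c,
                                  seed=s, fiber_subset=group,
                                  lead_us=FITTING_MARGIN_MS * 1000,
                                  tail_us=FITTING_MARGIN_MS * 1000)
        n_active = sum(int(np.count_nonzero((spk.fiber(f) >= t0) & (spk.fiber(f) < t1)))
                       for f in range(spk.n_fibers))
        probs.append(n_active / (n_pulses * len(group)))
    return float(np.mean(probs))


def estimate_mcl(channel: int, model: ExcitationModel,
                 params: NeuronParams | None = None, m_c: float = MC_DEFAULT,
                 seeds: tuple[int, ...] = (0, 1, 2),
                 sweep: tuple[int, ...] = SWEEP_CU,
                 criterion: float = FITTING_PROBABILITY) -> int:
    """MCL in clinical units for one virtual channel.

    Sweeps the 30-CU grid, then linearly interpolates the crossing of the
    criterion probability and rounds to integer CU.  Raises
    :class:`FittingError` if the criterion is never reached at 471 CU.
    """
    params = params or NeuronParams()
    group = select_fitting_group(channel, model)
    prev_cu, prev_p = None, None
    for cu in sweep:
        p = pulse_response_probability(channel, cu, model, group, params, m_c, seeds)
        if p >= criterion:
            if prev_cu is None:
                return int(cu)
            frac = (criterion - prev_p) / (p - prev_p)
            return int(round(prev_cu + frac * (cu - prev_cu)))
        prev_cu, prev_p = cu, p
    raise FittingError(
        f"channel {channel}: firing probability {prev_p:.3f} at {prev_cu} CU "
        f"never reached {criterion:.0%}")


def fit_map(model: ExcitationModel, params: NeuronParams | None = None,
            m_c: float = MC_DEFAULT, seeds: tuple[int, ...] = (0, 1, 2),
            ) -> tuple[sc.FittingMap, dict]:
    """Fit all 15 virtual channels; failed channels are disabled (MCL = NaN
    reported in diagnostics, amplitude forced to 0 by a 0-CU map entry)."""
    mcl = np.zeros(sc.N_CHANNELS)
    failed = []
    for ch in range(1, sc.N_CHANNELS + 1):
        try:
            mcl[ch - 1] = estimate_mcl(ch, model, params, m_c, seeds)
        except FittingError as err:
            failed.append((ch, str(err)))
            mcl[ch - 1] = np.nan
    diagnostics = {"failed_channels": failed, "m_c": m_c, "seeds": list(seeds)}
    if failed:
        # disabled channels stimulate at 0; map stays usable for the others
        mcl = np.where(np.isnan(mcl), 0.0, mcl)
    return sc.FittingMap(mcl_cu=mcl), diagnostics


def calibrate_mc(model: ExcitationModel, params: NeuronParams | None = None,
                 reference: tuple[float, float] | None = None,
                 mcl_limit_cu: float = 250.0, probe_channel: int = 8,
                 seeds: tuple[int, ...] = (0, 1, 2)) -> float:
    """Calibrate the modeling factor ``M_C``.

    Without a reference target the search is skipped and the default
    89.525e6 is returned (idempotent).  With ``reference = (cu, spike_count)``
    a bisection on ``M_C`` matches the fitting-group spike count of the probe
    channel's 200 ms train at the given level, then the result is checked
    against the compliance limit: the probe channel must fit below
    ``mcl_limit_cu``.
    """
    params = params or NeuronParams()
    if reference is None:
        return MC_DEFAULT
    cu_ref, count_ref = reference
    group = select_fitting_group(probe_channel, model)
    n_pulses = int(FITTING_TRAIN_MS * 1000 // sc.CHANNEL_PERIOD_US)
    target_p = count_ref / (n_pulses * len(group))

    def prob(m_c):
        return pulse_response_probability(probe_channel, cu_ref, model, group,
                                          params, m_c, seeds)

    lo, hi = MC_DEFAULT / 64.0, MC_DEFAULT * 64.0
    if not (prob(lo) <= target_p <= prob(hi)):
        raise FittingError("no M_C in the search range matches the reference "
                           "rate-level target")
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if prob(mid) < target_p:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.001:
            break
    m_c = float(np.sqrt(lo * hi))
    mcl = estimate_mcl(probe_channel, model, params, m_c, seeds)
    if mcl > mcl_limit_cu:
        raise FittingError(
            f"calibrated M_C = {m_c:.4g} puts the probe-channel MCL at {mcl} CU, "
            f"beyond the compliance limit {mcl_limit_cu}")
    return m_c
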