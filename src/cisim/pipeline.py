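"""Glue between the coder, the excitation model and the fiber population.

The stimulation waveform produced by the coder is piecewise constant, so the
population simulation never renders the dense 1 MHz electrodogram: the
per-cycle channel amplitudes and steering positions drive a per-slot
activation computation (node of maximum absolute combined activation, then
``M_C`` scaling) feeding the point-neuron integrator fiber by fiber.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sound_coding as sc
from ._kernels import run_population, slot_values
from .anf import NeuronParams, SpikeActivity, fiber_seeds, noise_streams
from .excitation import ExcitationModel, MC_DEFAULT


@dataclass(frozen=True)
class CycleSchedule:
    """One stimulation cycle flattened for the population kernel."""

    group_of_slot: np.ndarray   #: (n_slots, 3) 0-based channel ids, -1 padded
    seg_slot: np.ndarray        #: (n_seg,) slot index or -1 for gaps
    seg_phase: np.ndarray       #: (n_seg,) -1 cathodic / +1 anodic / 0 gap
    seg_dur_us: np.ndarray      #: (n_seg,)

    @property
    def cycle_us(self) -> float:
        return float(self.seg_dur_us.sum())


def schedule_from_table(table: sc.PulseTable) -> CycleSchedule:
    """Flatten a pulse table into kernel segment arrays."""
    n_slots = len(table.groups)
    width = max(len(g) for g in table.groups)
    group_of_slot = np.full((n_slots, max(width, 3)), -1, dtype=np.int64)
    for s, g in enumerate(table.groups):
        for m, ch in enumerate(g):
            group_of_slot[s, m] = ch - 1
    seg_slot, seg_phase, seg_dur = [], [], []
    for s in range(n_slots):
        seg_slot += [s, s]
        seg_phase += [-1, +1]
        seg_dur += [table.phase_us, table.phase_us]
        if table.gap_us > 0:
            seg_slot.append(-1)
            seg_phase.append(0)
            seg_dur.append(table.gap_us)
    return CycleSchedule(group_of_slot,
                         np.asarray(seg_slot, dtype=np.int64),
                         np.asarray(seg_phase, dtype=np.int64),
                         np.asarray(seg_dur, dtype=np.float64))


def single_channel_schedule(channel: int, phase_us: float = sc.PHASE_US,
                            period_us: float = sc.CHANNEL_PERIOD_US) -> CycleSchedule:
    """Cycle with one biphasic pulse on ``channel`` then silence (fitting)."""
    group_of_slot = np.full((1, 3), -1, dtype=np.int64)
    group_of_slot[0, 0] = channel - 1
    return CycleSchedule(
        group_of_slot,
        np.array([0, 0, -1], dtype=np.int64),
        np.array([-1, +1, 0], dtype=np.int64),
        np.array([phase_us, phase_us, period_us - 2 * phase_us]),
    )


def simulate_population(model: ExcitationModel, schedule: CycleSchedule,
                        amp_cu: np.ndarray, steer_idx: np.ndarray,
                        params: NeuronParams | None = None,
                        m_c: float = MC_DEFAULT, seed: int = 0,
                        fiber_subset: np.ndarray | None = None,
                        lead_us: float = 0.0, tail_us: float = 0.0,
                        phase_us: float = sc.PHASE_US) -> SpikeActivity:
    """Run excitation + spiking for per-cycle amplitudes on a fiber subset.

    ``amp_cu``/``steer_idx`` are (n_cycles, 15); amplitudes are converted to
    microamps with the clinical-unit law before excitation.  ``fiber_subset``
    restricts the simulation while keeping each fiber's RNG stream tied to
    its global index.
    """
    params = params or NeuronParams()
    patterns_t = model.channel_patterns_t
    single_vals = model.single_channel_values
    if fiber_subset is not None:
        fiber_subset = np.asarray(fiber_subset)
        patterns_t = np.ascontiguousarray(patterns_t[:, :, :, fiber_subset])
        single_vals = np.ascontiguousarray(single_vals[:, :, fiber_subset])
        fiber_ids = fiber_subset
    else:
        fiber_ids = np.arange(patterns_t.shape[3])
    amps_ua = sc.cu_to_microamps(np.asarray(amp_cu, dtype=float), phase_us)
    amps_ua = np.ascontiguousarray(amps_ua, dtype=np.float64)
    steer = np.ascontiguousarray(steer_idx, dtype=np.int64)
    F = patterns_t.shape[3]
    n_cycles = amps_ua.shape[0]
    duration_us = lead_us + n_cycles * schedule.cycle_us + tail_us
    max_spikes = int(duration_us / params.arp_us) + 2
    spikes = np.zeros((F, max_spikes))
    counts = np.zeros(F, dtype=np.int64)
    seeds = fiber_seeds(seed, fiber_ids)
    noise_c, noise_a = noise_streams(params, duration_us, seeds)
    vals = slot_values(patterns_t, single_vals, amps_ua, steer,
                       schedule.group_of_slot)
    run_population(vals, float(m_c), schedule.seg_slot, schedule.seg_phase,
                   schedule.seg_dur_us, float(lead_us), float(tail_us),
                   params.pack(), noise_c, noise_a, spikes, counts)
    return SpikeActivity(times=spikes, counts=counts,
                         duration_s=duration_us * 1e-6, seed=seed)
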