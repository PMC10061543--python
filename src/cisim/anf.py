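"""Phenomenological auditory-nerve-fiber population model.

Each fiber is a pair of adaptive leaky integrate-and-fire circuits coupled by
a logical OR: a *cathodic-excitatory* circuit (peripheral axon, membrane
capacitance 856.96 nF) and an *anodic-excitatory* circuit (central axon,
1772.4 nF).  Both see the same induced current ``I`` but with the opposite
phase acting inhibitorily, compressed by ``beta`` = 0.75:

    cathodic circuit drive: -(I^- + beta * I^+)
    anodic   circuit drive:   I^+ + beta * I^-

Each circuit integrates ``C dV/dt = h(V) - I_sub - I_supra + I_noise +
I_stim``.  A threshold crossing in either circuit emits one spike, resets
both and silences the fiber for an absolute refractory period of 500 us.

The internal dynamics are first-order processes with configurable defaults
(the cited point-neuron family leaves room here): ``h(V) = -V / R`` with ``R
= tau_m / C``; a subthreshold adaptation current relaxing toward
``a_sub * V``; a suprathreshold adaptation current incremented by ``b_supra``
at each spike; and an Ornstein-Uhlenbeck noise current.  Threshold and reset
values are model choices calibrated together with ``M_C`` so that fitted
most-comfortable levels stay inside the clinical-unit compliance range (see
the methods note).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import simulate_piecewise
from .excitation import InducedCurrentTrace

ARP_US = 500.0

__all__ = ["NeuronParams", "SpikeActivity", "split_phases", "simulate_spikes",
           "ARP_US"]


@dataclass(frozen=True)
class NeuronParams:
    """Tunable constants of the dual-circuit point neuron."""

    c_cathodic_f: float = 856.96e-9    #: membrane capacitance, cathodic circuit (F)
    c_anodic_f: float = 1772.4e-9      #: membrane capacitance, anodic circuit (F)
    tau_m_us: float = 200.0            #: membrane time constant
    v_threshold: float = 0.040         #: spike threshold (V)
    beta: float = 0.75                 #: inhibitory compression of the opposite phase
    arp_us: float = ARP_US             #: absolute refractory period
    a_sub: float = 5e-3                #: subthreshold adaptation conductance (S)
    tau_sub_us: float = 50e3           #: subthreshold adaptation time constant
    b_supra_a: float = 6e-7            #: per-spike adaptation increment (A)
    tau_supra_us: float = 100e3        #: suprathreshold adaptation time constant
    noise_sd_a: float = 8.0e-5         #: stationary s.d. of the noise current (A)
    tau_noise_us: float = 100.0        #: noise correlation time
    noise_update_us: float = 90.0      #: noise refresh interval (<= tau_noise)

    def __post_init__(self):
        if self.c_cathodic_f <= 0 or self.c_anodic_f <= 0:
            raise ValueError("capacitances must be positive")
        if self.arp_us <= 0:
            raise ValueError("refractory period must be positive")
        if self.noise_sd_a < 0:
            raise ValueError("noise amplitude must be non-negative")

    def pack(self) -> np.ndarray:
        """Flatten into the kernel parameter vector."""
        return np.array([
            self.c_cathodic_f, self.c_anodic_f, self.tau_m_us, self.v_threshold,
            self.beta, self.arp_us, self.a_sub, self.tau_sub_us, self.b_supra_a,
            self.tau_supra_us, self.noise_sd_a, self.tau_noise_us,
            self.noise_update_us,
        ])


def split_phases(i: np.ndarray, beta: float = 0.75):
    """Circuit-specific drives from the induced current.

    Returns ``(cathodic_drive, anodic_drive)`` with ``I+ = max(I, 0)`` and
    ``I- = min(I, 0)``: the cathodic-excitatory circuit receives
    ``-(I- + beta I+)`` and the anodic-excitatory circuit ``I+ + beta I-``.
    """
    i = np.asarray(i, dtype=float)
    if not np.all(np.isfinite(i)):
        raise ValueError("induced current must be finite")
    i_pos = np.maximum(i, 0.0)
    i_neg = np.minimum(i, 0.0)
    return -(i_neg + beta * i_pos), i_pos + beta * i_neg


@dataclass
class SpikeActivity:
    """Spike times per fiber (seconds), sorted within each fiber."""

    times: np.ndarray      #: (F, max_spikes) padded buffer
    counts: np.ndarray     #: (F,) valid entries per fiber
    duration_s: float
    seed: int | None = None

    @property
    def n_fibers(self) -> int:
        return len(self.counts)

    def fiber(self, f: int) -> np.ndarray:
        return self.times[f, : self.counts[f]]

    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def to_events(self) -> np.ndarray:
        """(n_spikes, 2) array of (fiber_id, time_s) rows."""
        rows = [np.column_stack([np.full(c, f, dtype=float), self.times[f, :c]])
                for f, c in enumerate(self.counts) if c]
        if not rows:
            return np.zeros((0, 2))
        return np.concatenate(rows)

    def to_frame(self):
        """Sparse event table with ``fiber_id`` and ``time_s`` columns."""
        import pandas as pd
        ev = self.to_events()
        return pd.DataFrame({"fiber_id": ev[:, 0].astype(int),
                             "time_s": ev[:, 1]})


def fiber_seeds(master_seed: int, fiber_ids: np.ndarray) -> np.ndarray:
    """Independent per-fiber RNG seeds tied to the global fiber identity.

    A fiber's stream depends only on the master seed and its own id, so
    adding or removing other fibers never perturbs its spike train.
    """
    fiber_ids = np.asarray(fiber_ids, dtype=np.int64)
    mix = (np.int64(master_seed) * np.int64(1000003) + fiber_ids * np.int64(7919) + 12345)
    return np.abs(mix) % np.int64(2**31 - 1)


def noise_streams(params: NeuronParams, duration_us: float, seeds: np.ndarray):
    """Pre-generated standard-normal noise draws per fiber and circuit.

    Returns ``(noise_c, noise_a)`` of shape (F, n_draws); empty when the
    noise amplitude is zero.
    """
    F = len(seeds)
    if params.noise_sd_a <= 0:
        z = np.zeros((F, 0), dtype=np.float32)
        return z, z
    n_draws = int(duration_us / params.noise_update_us) + 2
    noise_c = np.empty((F, n_draws), dtype=np.float32)
    noise_a = np.empty((F, n_draws), dtype=np.float32)
    for f, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        noise_c[f] = rng.standard_normal(n_draws, dtype=np.float32)
        noise_a[f] = rng.standard_normal(n_draws, dtype=np.float32)
    return noise_c, noise_a


def simulate_spikes(trace: InducedCurrentTrace, params: NeuronParams | None = None,
                    seed: int = 0, fiber_ids: np.ndarray | None = None,
                    ) -> SpikeActivity:
    """Simulate spike trains from a piecewise-constant induced-current trace."""
    params = params or NeuronParams()
    if not np.all(np.isfinite(trace.currents_a)):
        bad = np.argwhere(~np.isfinite(trace.currents_a))
        raise FloatingPointError(
            f"non-finite induced current at fiber {bad[0][0]}, segment {bad[0][1]}")
    F = trace.n_fibers
    seg_dur = np.diff(trace.bounds_us).astype(float)
    if fiber_ids is None:
        fiber_ids = np.arange(F)
    seeds = fiber_seeds(seed, fiber_ids)
    pv = params.pack()
    max_spikes = int(trace.bounds_us[-1] / params.arp_us) + 2
    times = np.zeros((F, max_spikes))
    counts = np.zeros(F, dtype=np.int64)
    noise_c, noise_a = noise_streams(params, float(trace.bounds_us[-1]), seeds)
    for f in range(F):
        counts[f] = simulate_piecewise(trace.currents_a[f].astype(float), seg_dur,
                                       pv, noise_c[f], noise_a[f], times[f])
    return SpikeActivity(times=times, counts=counts,
                         duration_s=trace.duration_s, seed=seed)
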