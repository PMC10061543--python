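"""Voltage spread, activation function and induced current.

Electrodes are point sources in a homogeneous medium of resistivity
``rho_ext`` = 3.0 Ohm*m, so the extracellular potential at a node is

    U = rho_ext * I / (4 * pi * d)

with ``d`` the electrode-node distance.  The activation function -- the
discrete second spatial difference of U along the fiber divided by the axon
internal resistance ``R_i = 4 * L_i * r / (pi * D^2)`` -- approximates the
stimulation current a node receives.  With the defaults (internodal length
200 um, diameter 2 um, axial resistivity 1 Ohm*m) ``R_i`` is about 63.66
MOhm.  Note the activation carries units of amperes here: the membrane
capacitance is applied later inside the point-neuron model.

Degenerated peripheral nodes -- and with them the chain ends -- are discarded
from the activation function: activation is defined only at interior nodes
with both neighbors present.  Treating the new terminal with a one-sided
difference instead can *raise* the activation as degeneration worsens, which
is both unphysical here and breaks the monotone loss of excitability the
degeneration model is meant to express.

The induced current driving a fiber's point-neuron model is

    I = M_C * sum_n A_nf(a_max)

where the sum runs over active electrodes, ``a_max`` is the node maximizing
the absolute *combined* activation at that instant, and ``M_C`` (default
89.525e6) is the calibration factor that bridges the geometric model and the
phenomenological neuron.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cochlea import ElectrodeNerveInterface
from . import sound_coding as sc

RHO_EXT_OHM_M = 3.0
AXON_DIAMETER_M = 2.0e-6
AXIAL_RESISTIVITY_OHM_M = 1.0
INTERNODAL_M = 200e-6
MC_DEFAULT = 89.525e6

__all__ = ["ExcitationModel", "InducedCurrentTrace", "axon_internal_resistance",
           "voltage_at_nodes", "activation_function", "induced_current", "MC_DEFAULT"]


def axon_internal_resistance(internodal_m: float = INTERNODAL_M,
                             diameter_m: float = AXON_DIAMETER_M,
                             axial_resistivity: float = AXIAL_RESISTIVITY_OHM_M) -> float:
    """``R_i = 4 L_i r / (pi D^2)`` in Ohm."""
    return 4.0 * internodal_m * axial_resistivity / (np.pi * diameter_m**2)


def activation_function(u: np.ndarray, r_i: float) -> np.ndarray:
    """Activation (A) from node voltages of one fiber.

    Interior nodes get the full second difference
    ``(U[a-1] - U[a])/R_i + (U[a+1] - U[a])/R_i``; terminal nodes (including
    the new most-peripheral node after degeneration) are excluded from the
    activation function and reported as 0.  A one-sided end treatment is
    deliberately not used: it can raise the activation as peripheral segments
    are removed, inverting the intended loss of excitability.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or len(u) < 3:
        raise ValueError("need at least 3 effective nodes")
    a = np.zeros_like(u)
    a[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / r_i
    return a


def voltage_at_nodes(electrode_currents_ua: np.ndarray,
                     interface: ElectrodeNerveInterface,
                     rho_ext: float = RHO_EXT_OHM_M) -> np.ndarray:
    """Superposed node voltages (V) for one instant of electrode currents (uA)."""
    cur = np.asarray(electrode_currents_ua, dtype=float) * 1e-6
    d_m = interface.distances_mm() * 1e-3
    return (rho_ext / (4.0 * np.pi)) * (1.0 / d_m) @ cur


@dataclass
class InducedCurrentTrace:
    """Piecewise-constant per-fiber induced current.

    ``currents_a[f, s]`` holds the current (A) of fiber ``f`` inside segment
    ``s``; ``bounds_us`` has the S+1 segment edges.  ``a_max[f, s]`` records
    which node dominated the combined activation.
    """

    bounds_us: np.ndarray
    currents_a: np.ndarray
    m_c: float
    a_max: np.ndarray | None = None

    @property
    def n_fibers(self) -> int:
        return self.currents_a.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.bounds_us[-1]) * 1e-6


class ExcitationModel:
    """Precomputed unit-current excitation fields for one interface.

    ``unit_activation[f, a, n]`` is the activation (A) at node ``a`` of fiber
    ``f`` for +1 A on electrode ``n``; entries outside the effective
    (non-degenerated) node range are zero.  ``channel_patterns[ch, c]`` adds
    the two electrodes of virtual channel ``ch`` weighted ``(1-c, c)`` for
    each of the 8 steering positions.
    """

    def __init__(self, interface: ElectrodeNerveInterface,
                 rho_ext: float = RHO_EXT_OHM_M,
                 diameter_m: float = AXON_DIAMETER_M,
                 axial_resistivity: float = AXIAL_RESISTIVITY_OHM_M):
        self.interface = interface
        self.rho_ext = rho_ext
        self.r_i = axon_internal_resistance(interface.config.internodal_mm * 1e-3,
                                            diameter_m, axial_resistivity)
        d_m = interface.distances_mm() * 1e-3
        self.unit_voltage = rho_ext / (4.0 * np.pi * d_m)  # V per A, (F, nodes, 16)
        self.unit_activation = self._build_unit_activation()
        self._patterns = None
        self._patterns_t = None
        self._single_vals = None

    def _build_unit_activation(self) -> np.ndarray:
        u = self.unit_voltage
        F, N, E = u.shape
        a = np.zeros_like(u)
        alpha = self.interface.alpha
        # group fibers by degeneration index; slice off the degenerated start
        for al in np.unique(alpha):
            idx = np.where(alpha == al)[0]
            ue = u[idx, al:, :]
            ae = np.zeros_like(ue)
            ae[:, 1:-1] = (ue[:, :-2] - 2.0 * ue[:, 1:-1] + ue[:, 2:]) / self.r_i
            a[idx, al:, :] = ae
        return a

    @property
    def channel_patterns(self) -> np.ndarray:
        """(15, 8, F, nodes) float32 activation per +1 A of channel current."""
        if self._patterns is None:
            ua = self.unit_activation
            F, N, _ = ua.shape
            p = np.empty((sc.N_CHANNELS, sc.N_STEER, F, N), dtype=np.float32)
            c = np.arange(sc.N_STEER) / sc.N_STEER
            for ch in range(sc.N_CHANNELS):
                ap = ua[:, :, ch]       # electrode ch (1-based ch) is apical
                ba = ua[:, :, ch + 1]
                for j, cj in enumerate(c):
                    p[ch, j] = ((1.0 - cj) * ap + cj * ba).astype(np.float32)
            self._patterns = p
        return self._patterns

    @property
    def channel_patterns_t(self) -> np.ndarray:
        """Fiber-contiguous transpose (15, 8, nodes, F) of the patterns."""
        if self._patterns_t is None:
            self._patterns_t = np.ascontiguousarray(
                self.channel_patterns.transpose(0, 1, 3, 2))
        return self._patterns_t

    @property
    def single_channel_values(self) -> np.ndarray:
        """(15, 8, F) signed activation at each channel pattern's own argmax
        node -- the induced-current coefficient when a slot stimulates a
        single channel (the argmax is then amplitude-independent)."""
        if self._single_vals is None:
            p = self.channel_patterns
            idx = np.argmax(np.abs(p), axis=3)
            self._single_vals = np.take_along_axis(p, idx[..., None], axis=3)[..., 0]
        return self._single_vals

    def fiber_electrode_strength(self) -> np.ndarray:
        """max-over-nodes |unit activation| per (fiber, electrode)."""
        return np.max(np.abs(self.unit_activation), axis=1)


def induced_current(electrodogram: sc.Electrodogram, model: ExcitationModel,
                    m_c: float = MC_DEFAULT, chunk: int = 2048,
                    keep_a_max: bool = False) -> InducedCurrentTrace:
    """Induced current per fiber for an arbitrary electrodogram.

    For every piecewise-constant segment of electrode currents the combined
    per-node activation is formed by superposition; ``a_max`` is the node with
    the largest absolute combined activation and the fiber's induced current
    is ``M_C`` times the (signed) activation there.  ``a_max`` may differ
    between segments.
    """
    bounds, cur_ua = electrodogram.segments()
    ua = model.unit_activation
    F, N, E = ua.shape
    S = cur_ua.shape[1]
    flat = ua.reshape(F * N, E)
    out = np.zeros((F, S))
    amax = np.zeros((F, S), dtype=np.int16) if keep_a_max else None
    cur_a = cur_ua * 1e-6
    for s0 in range(0, S, chunk):
        s1 = min(s0 + chunk, S)
        comb = (flat @ cur_a[:, s0:s1]).reshape(F, N, s1 - s0)
        idx = np.argmax(np.abs(comb), axis=1)  # (F, chunk)
        val = np.take_along_axis(comb, idx[:, None, :], axis=1)[:, 0, :]
        out[:, s0:s1] = m_c * val
        if keep_a_max:
            amax[:, s0:s1] = idx.astype(np.int16)
    return InducedCurrentTrace(bounds_us=bounds, currents_a=out, m_c=m_c, a_max=amax)
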