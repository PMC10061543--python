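"""Internal representation: from population spikes to recognizer features.

The spike activity of the fiber population is integrated spatially and
temporally into a low-rate feature matrix standing in for more central
auditory processing:

1.  fibers are grouped into *auditory filters* by their most likely
    stimulating electrode (argmax of the absolute unit activation), with
    filter extents constrained to 1.1--2.6 mm of basilar membrane (16 to 39
    filters for a 16-electrode array on a 42 mm cochlea);
2.  spike trains are binned at 10 kHz and summed within each filter (spike
    group activity ``S_g``);
3.  ``S_g`` is low-pass filtered by convolution with a Gaussian-shaped
    kernel with a 1 ms time constant (``F_g``);
4.  a forward-masking stage tracks a masker envelope ``Z_g`` that rises
    exponentially on onsets and decays exponentially on offsets; the
    internal representation is ``max(Z_g, F_g)``;
5.  the result is reduced to 100 Hz with a 10 ms moving-average (block
    mean), the frame rate expected by the HMM back-end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anf import SpikeActivity
from .cochlea import ElectrodeNerveInterface
from .excitation import ExcitationModel

FS_SPIKES_HZ = 10_000.0
FS_FRAMES_HZ = 100.0
TAU_LP_S = 1e-3
MIN_EXTENT_MM = 1.1
MAX_EXTENT_MM = 2.6
MIN_GROUPS = 16
MAX_GROUPS = 39

__all__ = ["AuditoryFilterBank", "IRConfig", "group_fibers",
           "spike_group_activity", "temporal_filter", "forward_masking",
           "downsample_ir", "InternalRepresentationExtractor"]


@dataclass
class IRConfig:
    """Temporal-integration parameters.

    The Gaussian kernel width multiplies ``f_s * tau_LP`` (10 samples at
    10 kHz and 1 ms); attack is much faster than release in the masker.
    """

    kernel_width: float = 1.0
    tau_attack_s: float = 5e-3
    tau_release_s: float = 50e-3
    smooth_window: int = 5     #: majority filter on electrode labels


@dataclass
class AuditoryFilterBank:
    """Ordered partition of fibers into auditory filters (base to apex)."""

    groups: list[np.ndarray]
    extents_mm: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def member_count(self) -> int:
        return int(sum(len(g) for g in self.groups))


def _majority_smooth(labels: np.ndarray, window: int) -> np.ndarray:
    """Majority vote over a centered window; stabilizes isolated argmax flips."""
    if window <= 1:
        return labels
    half = window // 2
    out = labels.copy()
    n = len(labels)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals, cnt = np.unique(labels[lo:hi], return_counts=True)
        out[i] = vals[np.argmax(cnt)]
    return out


def _extent(idx: np.ndarray, pos: np.ndarray, ds: float) -> float:
    return float(pos[idx[-1]] - pos[idx[0]] + ds)


def group_fibers(interface: ElectrodeNerveInterface, model: ExcitationModel,
                 config: IRConfig | None = None) -> AuditoryFilterBank:
    """Partition fibers into auditory filters along the basilar membrane.

    Contiguous runs of the (majority-smoothed) argmax-electrode label seed
    the filters; runs narrower than 1.1 mm merge into their apical neighbor
    and runs wider than 2.6 mm shed maximal filters basal-first.
    """
    config = config or IRConfig()
    strength = model.fiber_electrode_strength()     # (F, 16)
    labels = _majority_smooth(np.argmax(strength, axis=1), config.smooth_window)
    pos = interface.bm_position_mm
    ds = float(np.median(np.diff(pos))) if len(pos) > 1 else 0.0

    # contiguous runs, base -> apex
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append(np.arange(start, i))
            start = i

    # merge sub-minimum runs into the adjacent filter toward the apex
    merged: list[np.ndarray] = []
    i = 0
    while i < len(runs):
        run = runs[i]
        while _extent(run, pos, ds) < MIN_EXTENT_MM and i + 1 < len(runs):
            i += 1
            run = np.concatenate([run, runs[i]])
        if _extent(run, pos, ds) < MIN_EXTENT_MM and merged:
            # apical-most remainder: nothing further apical, fold it backward
            merged[-1] = np.concatenate([merged[-1], run])
        else:
            merged.append(run)
        i += 1

    # split super-maximum runs: basal-most fibers form maximal filters; if the
    # apical remainder would fall below the minimum, the cut shrinks so the
    # remainder stays a valid filter
    final: list[np.ndarray] = []
    for run in merged:
        while _extent(run, pos, ds) > MAX_EXTENT_MM:
            remaining = _extent(run, pos, ds)
            size = MAX_EXTENT_MM
            if remaining - MAX_EXTENT_MM < MIN_EXTENT_MM:
                size = remaining - MIN_EXTENT_MM
            cut = np.searchsorted(pos[run], pos[run[0]] + size - ds, side="right")
            cut = min(max(cut, 1), len(run) - 1)
            final.append(run[:cut])
            run = run[cut:]
        if len(run):
            final.append(run)

    extents = np.array([_extent(r, pos, ds) for r in final])
    return AuditoryFilterBank(groups=final, extents_mm=extents)


def spike_group_activity(spikes: SpikeActivity, bank: AuditoryFilterBank,
                         duration_s: float | None = None,
                         fs: float = FS_SPIKES_HZ) -> np.ndarray:
    """Bin spikes at ``fs`` and sum within each auditory filter.

    Total spike count is conserved (spikes outside the duration are clipped
    into the last bin edge region by construction of the simulation).
    """
    duration_s = duration_s or spikes.duration_s
    n_bins = int(np.ceil(duration_s * fs))
    edges = np.arange(n_bins + 1) / fs
    out = np.zeros((bank.n_groups, n_bins))
    for g, members in enumerate(bank.groups):
        for f in members:
            t = spikes.fiber(int(f))
            if len(t):
                out[g] += np.histogram(t, bins=edges)[0]
    return out


def gaussian_kernel(fs: float = FS_SPIKES_HZ, tau_lp_s: float = TAU_LP_S,
                    width: float = 1.0) -> np.ndarray:
    """Area-normalized Gaussian-shaped kernel ``exp(-(k/(w fs tau))^2)``,
    truncated at four standard deviations."""
    scale = width * fs * tau_lp_s          # samples; sigma = scale/sqrt(2)
    half = int(np.ceil(4 * scale / np.sqrt(2)))
    k = np.arange(-half, half + 1)
    w = np.exp(-((k / scale) ** 2))
    return w / w.sum()


def temporal_filter(s_g: np.ndarray, fs: float = FS_SPIKES_HZ,
                    tau_lp_s: float = TAU_LP_S, width: float = 1.0) -> np.ndarray:
    """Low-pass the spike group activity with the Gaussian-shaped kernel."""
    kern = gaussian_kernel(fs, tau_lp_s, width)
    return np.apply_along_axis(lambda m: np.convolve(m, kern, mode="same"), -1,
                               np.asarray(s_g, dtype=float))


def forward_masking(f_g: np.ndarray, fs: float = FS_SPIKES_HZ,
                    tau_attack_s: float = 5e-3, tau_release_s: float = 50e-3,
                    ) -> np.ndarray:
    """Forward-masked representation ``max(Z_g, F_g)``.

    The masker ``Z_g`` relaxes toward ``F_g`` with the attack constant while
    rising and with the (much slower) release constant while falling, so
    activity shadows forward in time after offsets.
    """
    f_g = np.asarray(f_g, dtype=float)
    a_att = 1.0 - np.exp(-1.0 / (fs * tau_attack_s))
    a_rel = 1.0 - np.exp(-1.0 / (fs * tau_release_s))
    z = np.zeros(f_g.shape[:-1])
    out = np.empty_like(f_g)
    for k in range(f_g.shape[-1]):
        x = f_g[..., k]
        coef = np.where(x >= z, a_att, a_rel)
        z = z + coef * (x - z)
        out[..., k] = np.maximum(z, x)
    return out


def downsample_ir(ir: np.ndarray, fs_in: float = FS_SPIKES_HZ,
                  fs_out: float = FS_FRAMES_HZ) -> np.ndarray:
    """Moving-average anti-alias then decimate (block mean over 10 ms)."""
    ir = np.asarray(ir, dtype=float)
    step = int(round(fs_in / fs_out))
    n = ir.shape[-1]
    n_frames = int(np.ceil(n / step))
    pad = n_frames * step - n
    if pad:
        ir = np.concatenate([ir, np.zeros(ir.shape[:-1] + (pad,))], axis=-1)
    return ir.reshape(ir.shape[:-1] + (n_frames, step)).mean(axis=-1)


class InternalRepresentationExtractor:
    """Bundle of a filter bank and temporal-integration parameters.

    Calling it on a :class:`SpikeActivity` yields the (groups x frames)
    feature matrix at 100 Hz.
    """

    def __init__(self, interface: ElectrodeNerveInterface, model: ExcitationModel,
                 config: IRConfig | None = None):
        self.config = config or IRConfig()
        self.bank = group_fibers(interface, model, self.config)

    def __call__(self, spikes: SpikeActivity, duration_s: float | None = None,
                 ) -> np.ndarray:
        s_g = spike_group_activity(spikes, self.bank, duration_s)
        f_g = temporal_filter(s_g, width=self.config.kernel_width)
        ir = forward_masking(f_g, tau_attack_s=self.config.tau_attack_s,
                             tau_release_s=self.config.tau_release_s)
        return downsample_ir(ir)
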