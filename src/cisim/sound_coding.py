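"""Current-steering sound coding for a 16-electrode cochlear implant.

Implements the three stimulation variants of an F120-style strategy:

* sequential (``S``) -- one virtual channel at a time,
* paired (``P``)     -- two virtual channels simultaneously,
* triplet (``T``)    -- three virtual channels simultaneously.

Fifteen virtual channels are formed by adjacent electrode pairs (channel ``i``
uses electrodes ``i`` and ``i+1``, numbered apex to base).  Current steering
splits the channel current between the two electrodes at one of eight discrete
ratios.  All variants keep the per-channel pulse rate constant: every virtual
channel is stimulated exactly once per 540 us cycle (~1852 pps), which for the
simultaneous variants requires zero-current gaps between stimulation groups.

The output of :func:`encode` is a sparse :class:`Electrodogram` -- a list of
biphasic, cathodic-leading pulse events -- that can be rendered densely at
1 MHz or reduced to piecewise-constant per-electrode current segments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

# Device constants (Advanced-Bionics-style clinical-unit scale).
I_MAX_UA = 2040.0       #: maximum output current in microamps
T_MAX_US = 229.0        #: maximum pulse phase duration in microseconds
CU_MAX = 471            #: largest clinical unit value
N_ELECTRODES = 16
N_CHANNELS = 15
N_STEER = 8             #: discrete steering positions per electrode pair
PHASE_US = 18.0         #: pulse phase duration used throughout
CHANNEL_PERIOD_US = 540.0   #: per-channel inter-pulse interval (~1852 pps)

__all__ = [
    "PulseTable",
    "Electrodogram",
    "FittingMap",
    "CoderConfig",
    "cu_to_microamps",
    "build_pulse_table",
    "analyze_cycles",
    "encode",
]


def cu_to_microamps(cu: float | np.ndarray, phase_us: float = PHASE_US):
    """Convert clinical units to output current in microamps.

    ``I = cu/6000 * I_max * T_max / phase_us`` -- linear in ``cu`` and
    inversely proportional to the phase duration (charge-based scale).
    """
    if phase_us <= 0:
        raise ValueError(f"phase_us must be positive, got {phase_us}")
    cu = np.asarray(cu, dtype=float)
    if np.any(cu < 0):
        raise ValueError("clinical units must be non-negative")
    out = cu / 6000.0 * I_MAX_UA * T_MAX_US / phase_us
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PulseTable:
    """One cycle of the stimulation schedule for a coding variant.

    ``groups`` lists the simultaneously stimulated virtual channels (1-based)
    in firing order.  Every channel appears in exactly one group per cycle and
    the per-channel period is 540 us for all variants; the zero-current gap
    after each group absorbs the remaining cycle time.
    """

    variant: str
    groups: tuple[tuple[int, ...], ...]
    gap_slots: int
    phase_us: float = PHASE_US
    channel_period_us: float = CHANNEL_PERIOD_US

    @property
    def slot_duration_us(self) -> float:
        """Duration of one biphasic pulse (both phases)."""
        return 2.0 * self.phase_us

    @property
    def gap_us(self) -> float:
        """Zero-current time after each group, from the 540 us period."""
        active = len(self.groups) * self.slot_duration_us
        return (self.channel_period_us - active) / len(self.groups)

    @property
    def group_onsets_us(self) -> np.ndarray:
        """Onset of each group within the cycle."""
        step = self.slot_duration_us + self.gap_us
        return np.arange(len(self.groups)) * step

    def validate(self) -> None:
        seen = sorted(ch for g in self.groups for ch in g)
        if seen != list(range(1, N_CHANNELS + 1)):
            raise ValueError("each virtual channel 1..15 must appear exactly once")
        if self.gap_us < -1e-9:
            raise ValueError("groups do not fit into the channel period")


def build_pulse_table(variant: str) -> PulseTable:
    """Build the pulse table for variant ``S``, ``P`` or ``T``.

    ``S`` fires 15 singleton groups back to back (15 x 36 us = 540 us, no
    gap).  ``P`` pairs channels ``{i, i+8}`` (channel 8 remains alone) and
    ``T`` forms triplets ``{i, i+5, i+10}``; the gaps after each group are
    sized so the per-channel period stays exactly 540 us.
    """
    variant = variant.upper()
    if variant == "S":
        groups = tuple((i,) for i in range(1, N_CHANNELS + 1))
        gap_slots = 0
    elif variant == "P":
        groups = tuple((i, i + 8) for i in range(1, 8)) + ((8,),)
        gap_slots = 1
    elif variant == "T":
        groups = tuple((i, i + 5, i + 10) for i in range(1, 6))
        gap_slots = 2
    else:
        raise ValueError(f"unknown coding variant {variant!r}; expected S, P or T")
    table = PulseTable(variant=variant, groups=groups, gap_slots=gap_slots)
    table.validate()
    return table


@dataclass
class FittingMap:
    """Per-virtual-channel stimulation levels in clinical units.

    ``t_cu`` (threshold) and ``mcl_cu`` (most comfortable loudness) bound the
    electrical dynamic range of each channel.  With the device default
    ``T = round(0.1 * MCL)`` the range is 20 dB.
    """

    mcl_cu: np.ndarray
    t_cu: np.ndarray | None = None

    def __post_init__(self):
        self.mcl_cu = np.asarray(self.mcl_cu, dtype=float)
        if self.mcl_cu.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} MCL values")
        if self.t_cu is None:
            self.t_cu = np.round(0.1 * self.mcl_cu)
        self.t_cu = np.asarray(self.t_cu, dtype=float)

    @property
    def fitted(self) -> bool:
        """Usable for encoding: finite levels with at least one live channel.

        Channels with MCL = 0 are *disabled* (they stimulate at zero
        amplitude), which is how unfittable channels are reported.
        """
        return bool(np.all(np.isfinite(self.mcl_cu)) and np.any(self.mcl_cu > 0))

    def to_json(self) -> dict:
        return {"mcl_cu": self.mcl_cu.tolist(), "t_cu": self.t_cu.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "FittingMap":
        return cls(np.asarray(obj["mcl_cu"]), np.asarray(obj["t_cu"]))


# Sparse pulse-event record layout of an electrodogram.
EVENT_DTYPE = np.dtype(
    [
        ("onset_us", np.float64),
        ("channel", np.int16),            # virtual channel 1..15
        ("electrode_apical", np.int16),   # 1-based electrode index
        ("electrode_basal", np.int16),
        ("steering", np.float64),         # c in {0/8 .. 7/8}
        ("amplitude_cu", np.float64),     # total channel amplitude
        ("phase_us", np.float64),
    ]
)


@dataclass
class Electrodogram:
    """Sparse pulse-event representation of the stimulation pattern.

    Each event is one cathodic-leading biphasic pulse on a virtual channel:
    the apical electrode of the pair carries ``(1-c)`` of the channel current
    and the basal electrode ``c``.  The dense 1 MHz per-electrode current
    matrix is rendered on demand.
    """

    events: np.ndarray
    duration_us: float
    n_electrodes: int = N_ELECTRODES

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=EVENT_DTYPE)
        order = np.argsort(self.events["onset_us"], kind="stable")
        self.events = self.events[order]

    def __len__(self) -> int:
        return len(self.events)

    def electrode_phase_intervals(self):
        """Flatten events into constant-current intervals per electrode.

        Returns ``(start_us, dur_us, electrode0, current_uA)`` arrays with one
        row per (event, electrode, phase); cathodic current is negative.
        """
        ev = self.events
        if len(ev) == 0:
            z = np.zeros(0)
            return z, z, np.zeros(0, dtype=int), z
        total_ua = cu_to_microamps(ev["amplitude_cu"], PHASE_US)
        # phase duration can vary per event
        total_ua = ev["amplitude_cu"] / 6000.0 * I_MAX_UA * T_MAX_US / ev["phase_us"]
        starts, durs, els, cur = [], [], [], []
        for el_field, w in (("electrode_apical", 1.0 - ev["steering"]),
                            ("electrode_basal", ev["steering"])):
            amp = total_ua * w
            for sign, off in ((-1.0, 0.0), (+1.0, ev["phase_us"])):
                starts.append(ev["onset_us"] + off)
                durs.append(ev["phase_us"])
                els.append(ev[el_field] - 1)
                cur.append(sign * amp)
        start = np.concatenate(starts)
        dur = np.concatenate(durs)
        el = np.concatenate(els).astype(int)
        amp = np.concatenate(cur)
        keep = np.abs(amp) > 0
        return start[keep], dur[keep], el[keep], amp[keep]

    def segments(self):
        """Piecewise-constant form: ``(bounds_us, currents_uA)``.

        ``bounds_us`` has ``S+1`` edges; ``currents_uA`` is ``(n_electrodes,
        S)`` with the signed current inside each segment.
        """
        start, dur, el, amp = self.electrode_phase_intervals()
        if len(start) == 0:
            return np.array([0.0, self.duration_us]), np.zeros((self.n_electrodes, 1))
        edges = np.unique(np.concatenate([start, start + dur, [0.0, self.duration_us]]))
        S = len(edges) - 1
        cur = np.zeros((self.n_electrodes, S))
        idx0 = np.searchsorted(edges, start)
        idx1 = np.searchsorted(edges, start + dur)
        for s, i0, i1, e, a in zip(start, idx0, idx1, el, amp):
            cur[e, i0:i1] += a
        return edges, cur

    def to_dense(self, fs: float = 1e6) -> np.ndarray:
        """Render per-electrode signed current (uA) at sample rate ``fs``."""
        n = int(round(self.duration_us * 1e-6 * fs))
        out = np.zeros((self.n_electrodes, n))
        start, dur, el, amp = self.electrode_phase_intervals()
        for s, d, e, a in zip(start, dur, el, amp):
            i0 = int(round(s * 1e-6 * fs))
            i1 = int(round((s + d) * 1e-6 * fs))
            out[e, i0:min(i1, n)] += a
        return out

    def charge_imbalance(self) -> float:
        """Largest absolute per-electrode charge integral (uA*us)."""
        start, dur, el, amp = self.electrode_phase_intervals()
        if len(start) == 0:
            return 0.0
        q = np.zeros(self.n_electrodes)
        np.add.at(q, el, amp * dur)
        return float(np.max(np.abs(q)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, duration_us: float) -> "Electrodogram":
        ev = np.zeros(len(frame), dtype=EVENT_DTYPE)
        for name in EVENT_DTYPE.names:
            ev[name] = frame[name].to_numpy()
        return cls(ev, duration_us)


@dataclass
class CoderConfig:
    """Tunable parameters of the analysis front half of the coder.

    The filterbank design, envelope detector, steering rule and compression
    mapping are not standardized; these defaults follow published F120
    descriptions (log-spaced analysis bands over 350-5600 Hz, Hilbert
    envelopes, within-band spectral-balance steering, and a logarithmic map
    of the envelope onto the T..MCL range over ``idr_db`` of input range).
    """

    band_lo_hz: float = 350.0
    band_hi_hz: float = 5600.0
    idr_db: float = 60.0
    ceiling_dbfs: float = -44.0   #: envelope level mapped to MCL
    filter_order: int = 3
    env_smooth_hz: float = 200.0  #: envelope low-pass cutoff

    def band_edges(self) -> np.ndarray:
        return np.geomspace(self.band_lo_hz, self.band_hi_hz, N_CHANNELS + 1)


def _band_envelopes(audio: np.ndarray, fs: float, cfg: CoderConfig):
    """Hilbert envelopes of the 15 analysis bands and their steering ratio.

    Returns ``(env, c_raw)`` at the audio rate; ``env`` approximates the tone
    amplitude within the band, ``c_raw`` in [0, 1] is the fraction of band
    energy in the upper half-band (basal direction).
    """
    edges = cfg.band_edges()
    nyq = fs / 2.0
    env = np.zeros((N_CHANNELS, len(audio)))
    c_raw = np.full((N_CHANNELS, len(audio)), 0.5)
    sm = None
    if cfg.env_smooth_hz and cfg.env_smooth_hz < nyq:
        sm = butter(2, cfg.env_smooth_hz / nyq, output="sos")
    for b in range(N_CHANNELS):
        lo, hi = edges[b], min(edges[b + 1], 0.99 * nyq)
        mid = np.sqrt(lo * hi)
        sub = []
        for f0, f1 in ((lo, mid), (mid, hi)):
            sos = butter(cfg.filter_order, [f0 / nyq, f1 / nyq], btype="band", output="sos")
            x = sosfiltfilt(sos, audio)
            sub.append(np.abs(hilbert(x)))
        e_lo, e_hi = sub
        tot = np.hypot(e_lo, e_hi)
        if sm is not None:
            tot = np.maximum(sosfiltfilt(sm, tot), 0.0)
        env[b] = tot
        p = e_lo**2 + e_hi**2
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(p > 0, e_hi**2 / np.maximum(p, 1e-30), 0.5)
        c_raw[b] = frac
    return env, c_raw


def analyze_cycles(audio: np.ndarray, fs: float, fitting: FittingMap,
                   config: CoderConfig | None = None):
    """Front-half analysis: per-cycle channel amplitudes and steering.

    Returns ``(amp_cu, steer_idx, duration_us)`` with one row per 540 us
    stimulation cycle.  Band envelopes are compressed logarithmically from T
    to MCL over the input dynamic range; the steering position is the
    quantized upper-half energy fraction of the band.
    """
    config = config or CoderConfig()
    if not fitting.fitted:
        raise RuntimeError("fitting map is not fitted (invalid MCLs)")
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    duration_us = len(audio) / fs * 1e6
    n_cycles = int(duration_us // CHANNEL_PERIOD_US)
    if len(audio) == 0 or n_cycles == 0:
        return (np.zeros((0, N_CHANNELS)), np.zeros((0, N_CHANNELS), dtype=np.int8),
                duration_us)

    env, c_raw = _band_envelopes(audio, fs, config)
    t_audio = np.arange(len(audio)) / fs
    t_cycle = (np.arange(n_cycles) + 0.5) * CHANNEL_PERIOD_US * 1e-6
    # sample per cycle
    env_c = np.empty((N_CHANNELS, n_cycles))
    steer_c = np.empty((N_CHANNELS, n_cycles), dtype=np.int8)
    for b in range(N_CHANNELS):
        env_c[b] = np.interp(t_cycle, t_audio, env[b])
        steer_c[b] = np.clip((np.interp(t_cycle, t_audio, c_raw[b]) * N_STEER).astype(int),
                             0, N_STEER - 1)
    with np.errstate(divide="ignore"):
        e_db = 20.0 * np.log10(np.maximum(env_c, 1e-30))
    floor_db = config.ceiling_dbfs - config.idr_db
    frac = np.clip((e_db - floor_db) / config.idr_db, 0.0, 1.0)
    t = fitting.t_cu[:, None]
    mcl = fitting.mcl_cu[:, None]
    amp_cu = t + (mcl - t) * frac
    return amp_cu.T.copy(), steer_c.T.copy(), duration_us


def encode(audio: np.ndarray, fs: float, fitting: FittingMap, variant: str,
           config: CoderConfig | None = None) -> Electrodogram:
    """Encode a calibrated mono waveform into an electrodogram.

    The waveform convention is ``dBFS = 20*log10(RMS * sqrt(2))`` so that a
    full-scale sine sits at 0 dBFS; stimuli are normally presented around
    -49 dBFS (~65 dB SPL at the processor microphone).  Band envelopes are
    sampled once per 540 us stimulation cycle, steered to one of eight
    positions within the band's electrode pair, and compressed
    logarithmically from T to MCL over the input dynamic range; pulses are
    scheduled by the variant's pulse table.
    """
    amp_cu, steer_c, duration_us = analyze_cycles(audio, fs, fitting, config)
    table = build_pulse_table(variant)
    n_cycles = amp_cu.shape[0]
    if n_cycles == 0:
        return Electrodogram(np.zeros(0, dtype=EVENT_DTYPE), duration_us)
    events = []
    onsets = table.group_onsets_us
    for k in range(n_cycles):
        base = k * CHANNEL_PERIOD_US
        for g, group in enumerate(table.groups):
            for ch in group:
                b = ch - 1
                events.append((base + onsets[g], ch, ch, ch + 1,
                               steer_c[k, b] / N_STEER, amp_cu[k, b], PHASE_US))
    ev = np.array(events, dtype=EVENT_DTYPE)
    return Electrodogram(ev, duration_us)
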