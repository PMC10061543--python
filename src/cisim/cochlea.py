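"""Parametric 3D electrode-nerve interface with controllable degeneration.

The cochlea is represented as a logarithmic spiral: the basilar membrane (BM)
runs 42 mm over 900 degrees of insertion angle (2.5 turns).  9001 auditory
nerve fibers (ANFs) are planted every 0.1 degree, indexed base (high
frequencies) to apex (low frequencies).  Each fiber is a chain of nodes with
a constant 200 um internodal length running from its peripheral terminal on
the BM radially toward the modiolar axis and then down the nerve trunk.

The electrode array descends from a 22-contact template spanning almost one
turn of the scala tympani; template contacts 11, 13, 15, 17, 19 and 21 are
removed to obtain the 16 contacts of the modeled device.

Neural degeneration removes the ``alpha_f`` most peripheral segments of each
fiber (``alpha_f`` in 0..20), drawn per fiber from a rounded normal with a
configurable mean ("healthy" 5, "moderate" 10, "severe" 15) and a standard
deviation of three nodes.

The true mesh geometry of an implanted cochlea is patient specific; this
module is a deterministic parametric stand-in whose radii, pitch and offsets
are all exposed in :class:`CochleaConfig` so other geometries can be dropped
in.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

HEALTH_PRESETS = {"ideal": 0.0, "healthy": 5.0, "moderate": 10.0, "severe": 15.0,
                  "total": 20.0}
ALPHA_MAX = 20
TEMPLATE_REMOVED = (11, 13, 15, 17, 19, 21)  # 1-based template contacts dropped

__all__ = ["CochleaConfig", "ElectrodeNerveInterface", "build_geometry",
           "apply_degeneration", "HEALTH_PRESETS"]


@dataclass(frozen=True)
class CochleaConfig:
    """Geometric parameters of the spiral stand-in (all lengths in mm)."""

    n_fibers: int = 9001
    span_deg: float = 900.0            #: angular span of the ANF population
    bm_length_mm: float = 42.0         #: basilar-membrane arc length
    radius_ratio: float = 0.35         #: apical/basal BM radius
    z_rise_mm: float = 4.0             #: axial rise base->apex
    nodes_per_fiber: int = 30
    internodal_mm: float = 0.2
    trunk_radius_mm: float = 1.8       #: radius of the descending nerve trunk
    bend_drop_mm: float = 1.5          #: axial drop over the BM-to-trunk bend
    n_template_electrodes: int = 22
    insertion_deg: tuple[float, float] = (20.0, 380.0)  #: basal..apical contact angle
    electrode_radial_offset_mm: float = 0.9   #: contact sits inside the BM radius
    electrode_axial_offset_mm: float = 1.2    #: contact sits below the BM

    def validate(self) -> None:
        if self.bm_length_mm <= 0 or self.span_deg <= 0:
            raise ValueError("BM length and angular span must be positive")
        if not (0 < self.radius_ratio < 1):
            raise ValueError("radius_ratio must be in (0, 1)")
        if self.n_fibers < 2 or self.nodes_per_fiber < ALPHA_MAX + 3:
            raise ValueError("need >= 2 fibers and >= 23 nodes per fiber")


@dataclass
class ElectrodeNerveInterface:
    """Fiber node coordinates, electrode positions and degeneration state.

    ``node_xyz_mm[f, a]`` is node ``a`` of fiber ``f`` counted from the
    peripheral terminal; after degeneration the effective node list of fiber
    ``f`` starts at index ``alpha[f]``.
    """

    config: CochleaConfig
    node_xyz_mm: np.ndarray          #: (F, nodes, 3)
    electrode_xyz_mm: np.ndarray     #: (16, 3)
    insertion_angle_deg: np.ndarray  #: (F,)
    bm_position_mm: np.ndarray       #: (F,) arc position along BM from base
    alpha: np.ndarray = None         #: (F,) degeneration index

    def __post_init__(self):
        if self.alpha is None:
            self.alpha = np.zeros(self.n_fibers, dtype=np.int64)

    @property
    def n_fibers(self) -> int:
        return self.node_xyz_mm.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.node_xyz_mm.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.electrode_xyz_mm.shape[0]

    def effective_node_slice(self, f: int) -> slice:
        return slice(int(self.alpha[f]), self.n_nodes)

    def distances_mm(self) -> np.ndarray:
        """Electrode-to-node Euclidean distances, shape (F, nodes, 16)."""
        d = np.linalg.norm(
            self.node_xyz_mm[:, :, None, :] - self.electrode_xyz_mm[None, None, :, :],
            axis=-1,
        )
        if np.any(d <= 0):
            raise ValueError("electrode coincides with a fiber node (zero distance)")
        return d

    def to_json(self) -> dict:
        return {
            "config": asdict(self.config),
            "alpha": self.alpha.tolist(),
            "electrode_xyz_mm": self.electrode_xyz_mm.tolist(),
        }

    def save(self, path: str) -> None:
        np.savez_compressed(
            path,
            node_xyz_mm=self.node_xyz_mm,
            electrode_xyz_mm=self.electrode_xyz_mm,
            insertion_angle_deg=self.insertion_angle_deg,
            bm_position_mm=self.bm_position_mm,
            alpha=self.alpha,
            config=json.dumps(asdict(self.config)),
        )

    @classmethod
    def load(cls, path: str) -> "ElectrodeNerveInterface":
        z = np.load(path, allow_pickle=False)
        cfg_d = json.loads(str(z["config"]))
        cfg_d["insertion_deg"] = tuple(cfg_d["insertion_deg"])
        return cls(CochleaConfig(**cfg_d), z["node_xyz_mm"], z["electrode_xyz_mm"],
                   z["insertion_angle_deg"], z["bm_position_mm"], z["alpha"])


def _spiral(theta: np.ndarray, cfg: CochleaConfig):
    """BM spiral point(s) at angle ``theta`` (radians from base)."""
    theta_max = np.deg2rad(cfg.span_deg)
    b = np.log(cfg.radius_ratio) / theta_max
    # basal radius chosen so the spiral arc length equals bm_length_mm
    r0 = cfg.bm_length_mm * abs(b) / (np.sqrt(1 + b * b) * (1 - cfg.radius_ratio))
    r = r0 * np.exp(b * theta)
    z = cfg.z_rise_mm * theta / theta_max
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    # arc length from base: s = sqrt(1+b^2)/|b| * (r0 - r)
    s = np.sqrt(1 + b * b) / abs(b) * (r0 - r)
    return np.stack([x, y, z], axis=-1), r, s


def build_geometry(config: CochleaConfig | None = None) -> ElectrodeNerveInterface:
    """Construct the deterministic electrode-nerve interface.

    Each fiber leaves its peripheral terminal on the BM spiral, sweeps along a
    smooth quarter-ellipse (in the radial/axial plane at its insertion angle)
    down to the nerve-trunk radius, and then descends parallel to the
    modiolar axis.  The smooth bend avoids artificial curvature hotspots in
    the activation function at trajectory corners.
    """
    cfg = config or CochleaConfig()
    cfg.validate()
    theta_f = np.deg2rad(np.linspace(0.0, cfg.span_deg, cfg.n_fibers))
    bm_xyz, r_bm, s_bm = _spiral(theta_f, cfg)

    nodes = np.empty((cfg.n_fibers, cfg.nodes_per_fiber, 3))
    cos_t, sin_t = np.cos(theta_f), np.sin(theta_f)
    t_dense = np.linspace(0.0, np.pi / 2, 800)
    targets = np.arange(cfg.nodes_per_fiber) * cfg.internodal_mm
    for f in range(cfg.n_fibers):
        r0, z0 = r_bm[f], bm_xyz[f, 2]
        rt = min(cfg.trunk_radius_mm, 0.8 * r0)
        # cubic Bezier in the (radius, z) plane: leaves the BM heading down
        # and inward, joins the descending trunk tangentially (no corners)
        u = t_dense / (np.pi / 2)
        p0 = np.array([r0, z0])
        p1 = np.array([r0 - 0.35 * (r0 - rt), z0 - 0.5 * cfg.bend_drop_mm])
        p2 = np.array([rt, z0 - 0.5 * cfg.bend_drop_mm])
        p3 = np.array([rt, z0 - cfg.bend_drop_mm])
        bez = ((1 - u)[:, None] ** 3 * p0 + 3 * ((1 - u) ** 2 * u)[:, None] * p1
               + 3 * ((1 - u) * u ** 2)[:, None] * p2 + (u ** 3)[:, None] * p3)
        r, z = bez[:, 0], bez[:, 1]
        # straight descent after the bend, long enough for the full chain
        z_tail = np.linspace(z[-1], z[-1] - 8.0, 200)[1:]
        r_full = np.concatenate([r, np.full(len(z_tail), rt)])
        z_full = np.concatenate([z, z_tail])
        pts = np.column_stack([r_full * cos_t[f], r_full * sin_t[f], z_full])
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        for i in range(3):
            nodes[f, :, i] = np.interp(targets, cum, pts[:, i])

    # electrode template: contact 1 = most apical (deepest)
    a_basal, a_apical = cfg.insertion_deg
    tmpl_angles = np.linspace(a_apical, a_basal, cfg.n_template_electrodes)
    keep = [i for i in range(1, cfg.n_template_electrodes + 1) if i not in TEMPLATE_REMOVED]
    angles = np.deg2rad(tmpl_angles[[i - 1 for i in keep]])
    e_xyz, r_e, _ = _spiral(angles, cfg)
    radial = np.maximum(r_e - cfg.electrode_radial_offset_mm, 0.1) / r_e
    e_xyz[:, 0] *= radial
    e_xyz[:, 1] *= radial
    e_xyz[:, 2] -= cfg.electrode_axial_offset_mm

    return ElectrodeNerveInterface(
        config=cfg,
        node_xyz_mm=nodes,
        electrode_xyz_mm=e_xyz,
        insertion_angle_deg=np.rad2deg(theta_f),
        bm_position_mm=s_bm,
    )


def apply_degeneration(interface: ElectrodeNerveInterface, mean_nodes: float,
                       sd_nodes: float = 3.0, seed: int | None = 0,
                       ) -> ElectrodeNerveInterface:
    """Assign per-fiber degeneration indices ``alpha_f``.

    ``alpha_f ~ round(Normal(mean_nodes, sd_nodes))`` clipped to [0, 20];
    segments are always removed from the most peripheral end.  Returns a new
    interface sharing the coordinate arrays.
    """
    if not np.isfinite(mean_nodes) or mean_nodes < 0 or mean_nodes > 2 * ALPHA_MAX:
        raise ValueError(f"mean_nodes must be in [0, {2 * ALPHA_MAX}]")
    rng = np.random.default_rng(seed)
    if sd_nodes == 0:
        alpha = np.full(interface.n_fibers, round(mean_nodes))
    else:
        alpha = np.round(rng.normal(mean_nodes, sd_nodes, interface.n_fibers))
    alpha = np.clip(alpha, 0, ALPHA_MAX).astype(np.int64)
    return ElectrodeNerveInterface(
        config=interface.config,
        node_xyz_mm=interface.node_xyz_mm,
        electrode_xyz_mm=interface.electrode_xyz_mm,
        insertion_angle_deg=interface.insertion_angle_deg,
        bm_position_mm=interface.bm_position_mm,
        alpha=alpha,
    )
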