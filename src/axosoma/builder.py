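"""Assemble complete cable models: efferent geometry, membrane distribution.

The full model of one motoneuron is the imported (or synthetic)
somato-dendritic tree plus a standardised efferent pathway: a frustum-shaped
axon hillock (25 um, 7 compartments) whose diameter interpolates linearly
from the soma to the AIS value, a cylindrical unmyelinated axon initial
segment (9 x 50 um compartments, default diameter 3 um), and a double-cable
myelinated axon of repeating internodes (node of Ranvier, paranodal myelin
attachment segment MYSA, juxtaparanodal segment FLUT, internodal segment
STIN) with a finite-impedance myelin sheath and a resistive periaxonal
space.  With the default 20 internodes at 1.150 mm node-to-node separation
the axon is 23 mm long and node[15] lies 17.25 mm from the soma under the
node-count convention.

Channel densities follow region rules: the soma carries the full somatic
set; along the proximal dendrites (out to 10% of the cell's mean terminal
path distance) each density falls linearly to its distal value; dendritic
compartments between 30% and 60% of that distance additionally carry a
low-threshold Ca2+ conductance and extra Ca2+-activated K+; the hillock
cross-fades linearly from the somatic to the AIS density set; the AIS is
uniform; nodes carry the nodal set and the paranodal/internodal axolemma is
passive under the myelin.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelSpec, load_channel_set
from .morphology import Morphology, Section, morphometrics

__all__ = [
    "EfferentSpec", "RegionMembraneSpec", "PlacedChannel", "CableModel",
    "BuildError", "build_efferent", "attach_efferent", "assign_conductances",
    "build_cell", "lamella_scale", "periaxonal_resistance",
]

RHO_AXIAL = 70.0  # Ohm cm, intracellular
RHO_PERIAXONAL = 70.0  # Ohm cm, periaxonal space (external resistivity)


class BuildError(RuntimeError):
    """Inconsistent geometry or membrane specification."""


@dataclass(frozen=True)
class EfferentSpec:
    """Geometry of the hillock + AIS + myelinated axon (lengths/diameters um)."""

    hillock_length: float = 25.0
    hillock_n: int = 7
    ais_length: float = 450.0
    ais_n: int = 9
    ais_diameter: float = 3.0
    n_internodes: int = 20
    node_node_sep: float = 1150.0
    node_length: float = 1.0
    node_diameter: float = 3.3
    mysa_length: float = 3.0
    mysa_diameter: float = 3.6
    mysa_periax_width: float = 0.002
    flut_length: float = 46.0
    flut_diameter: float = 6.9
    flut_periax_width: float = 0.004
    stin_diameter: float = 6.9
    stin_periax_width: float = 0.004
    stin_n_sub: int = 6
    stin_sub_length_nominal: float = 175.2
    n_lamellae: int = 120

    @property
    def stin_sub_length(self) -> float:
        """STIN sub-compartment length tiling the internode exactly.

        One internode is [node, MYSA, FLUT, STIN x n, FLUT, MYSA]; the STIN
        pieces absorb the rounding so the lengths sum to the node-to-node
        separation.
        """
        rest = (self.node_node_sep - self.node_length
                - 2 * self.mysa_length - 2 * self.flut_length)
        if rest <= 0:
            raise BuildError("internode segments longer than node separation")
        sub = rest / self.stin_n_sub
        if abs(sub - self.stin_sub_length_nominal) > 1.0:
            raise BuildError(
                f"internode tiling inconsistent: STIN sub-length {sub:.2f} um "
                f"vs nominal {self.stin_sub_length_nominal} um")
        return sub

    @property
    def axon_length(self) -> float:
        """Total myelinated axon length (um), node-separation convention."""
        return self.n_internodes * self.node_node_sep

    def node_distance(self, k: int) -> float:
        """Distance (um) from soma to node[k]: k node-to-node separations."""
        return k * self.node_node_sep

    def node_path_distance(self, k: int) -> float:
        """True path distance including hillock + AIS (um)."""
        return self.hillock_length + self.ais_length + self.node_distance(k)


def lamella_scale(spec: EfferentSpec, c_my: float = 0.1, g_my: float = 1.0):
    """Effective myelin sheath capacitance and conductance per unit area.

    Each of the N lamellae contributes two membranes in series, so the
    effective values are ``c_my / (2N)`` uF/cm^2 and ``g_my / (2N)`` mS/cm^2.
    """
    if spec.n_lamellae < 1:
        raise BuildError("need at least one myelin lamella")
    return c_my / (2 * spec.n_lamellae), g_my / (2 * spec.n_lamellae)


def periaxonal_resistance(d: float, w: float, rho: float, L: float) -> float:
    """Axial resistance (MOhm) of the periaxonal annulus.

    ``d`` axolemma diameter (um), ``w`` periaxonal width (um), ``rho``
    resistivity (Ohm cm), ``L`` length (um).
    """
    if d <= 0 or w <= 0 or L <= 0:
        raise ValueError("d, w, L must be positive")
    area_um2 = math.pi * ((d / 2 + w) ** 2 - (d / 2) ** 2)
    # rho * L / A: Ohm cm * um / um^2 -> Ohm: factor 1e4; -> MOhm: 1e-6
    return rho * L * 1e4 / area_um2 * 1e-6


def build_efferent(spec: EfferentSpec, soma_diameter: float) -> list[Section]:
    """Build hillock + AIS + axon sections (parents relative, -1 = attach).

    The hillock tapers linearly from the soma diameter to the AIS diameter;
    the axon repeats [MYSA, FLUT, STIN.., FLUT, MYSA, node] per internode,
    with the first MYSA attached directly to the distal end of the AIS (no
    intervening node).  Nodes are numbered 1..n_internodes proximal->distal.
    """
    if soma_diameter <= spec.ais_diameter:
        raise BuildError("soma diameter must exceed AIS diameter")
    secs: list[Section] = []
    y = 0.0  # grow along -y; coordinates only encode arc lengths

    def cyl(length: float, d0: float, d1: float | None = None,
            parent: int = -1, region: str = "dendrite", nseg: int = 1) -> int:
        nonlocal y
        d1 = d0 if d1 is None else d1
        # sample every compartment boundary so taper is piecewise linear
        npts = max(2, nseg + 1)
        ys = np.linspace(y, y - length, npts)
        ds = np.linspace(d0, d1, npts)
        pts = np.column_stack([np.zeros(npts), ys, np.zeros(npts), ds])
        y -= length
        secs.append(Section(points=pts, parent=parent, parent_pos=1.0,
                            region=region, nseg=nseg))
        return len(secs) - 1

    hil = cyl(spec.hillock_length, soma_diameter, spec.ais_diameter,
              parent=-1, region="hillock", nseg=spec.hillock_n)
    ais = cyl(spec.ais_length, spec.ais_diameter, spec.ais_diameter,
              parent=hil, region="AIS", nseg=spec.ais_n)
    sub = spec.stin_sub_length
    prev = ais
    for _ in range(spec.n_internodes):
        prev = cyl(spec.mysa_length, spec.mysa_diameter, parent=prev, region="MYSA")
        prev = cyl(spec.flut_length, spec.flut_diameter, parent=prev, region="FLUT")
        for _ in range(spec.stin_n_sub):
            prev = cyl(sub, spec.stin_diameter, parent=prev, region="STIN")
        prev = cyl(spec.flut_length, spec.flut_diameter, parent=prev, region="FLUT")
        prev = cyl(spec.mysa_length, spec.mysa_diameter, parent=prev, region="MYSA")
        prev = cyl(spec.node_length, spec.node_diameter, parent=prev, region="node")
    return secs


def attach_efferent(m: Morphology, spec: EfferentSpec) -> Morphology:
    """Return a copy of ``m`` with the efferent sections appended.

    The hillock attaches to the proximal end (arc position 0) of the soma.
    """
    mm = morphometrics(m)
    eff = build_efferent(spec, mm.soma_diameter)
    sections = [Section(points=s.points.copy(), parent=s.parent,
                        parent_pos=s.parent_pos, region=s.region, nseg=s.nseg)
                for s in m.sections]
    base = len(sections)
    soma_idx = m.soma_sections[0]
    for s in eff:
        parent = soma_idx if s.parent == -1 else s.parent + base
        pos = 0.0 if s.parent == -1 else s.parent_pos
        sections.append(Section(points=s.points.copy(), parent=parent,
                                parent_pos=pos, region=s.region, nseg=s.nseg))
    return Morphology(sections=sections, soma_sections=list(m.soma_sections),
                      metadata=dict(m.metadata))


# ---------------------------------------------------------------------------
# Membrane specification


def _default_region_channels() -> dict:
    # proximal:distal gradient pairs for soma+proximal dendrites (mS/cm^2)
    return {
        "soma_gradients": {
            "na_fast": (15.0, 0.15),
            "k_dr": (35.0, 0.3),
            "na_persistent": (2.0, 0.015),
            "k_ca": (10.0, 0.0),
            "ca_ht": (0.008, 0.0),
            "leak": (4.4, 0.072),
        },
        "g_h": 0.1325,  # uniform over soma + dendrites
        "mid_dendrite": {"ca_lt": 0.28, "k_ca": 0.16},
        "hillock_soma_end": {"na_fast": 15.0, "k_dr": 35.0,
                             "na_persistent": 2.0, "leak": 4.4},
        "hillock_ais_end": {"na_fast": 300.0, "k_dr": 400.0,
                            "na_persistent": 10.0, "leak": 4.4},
        "ais": {"na_fast": 300.0, "k_dr": 400.0,
                "na_persistent": 10.0, "leak": 4.4},
        # Nodal fast-Na density follows the source myelinated-fiber model
        # (3.0 S/cm2): the printed 0.88 S/cm2 leaves the internodal safety
        # factor at ~1 and saltatory conduction fails under this geometry.
        "node": {"na_fast_node": 3000.0, "k_slow_node": 400.0,
                 "na_persistent_node": 4.4, "leak": 1.0},
        "MYSA": {"leak": 1.0},
        "FLUT": {"leak": 0.1},
        "STIN": {"leak": 0.1},
    }


@dataclass(frozen=True)
class RegionMembraneSpec:
    """Per-region capacitance, channel densities and gradient extents.

    Densities in mS/cm^2, capacitances uF/cm^2.  ``proximal_fraction`` and
    ``mid_band`` are fractions of the cell's mean terminal path distance.
    """

    cm: dict = field(default_factory=lambda: {
        "soma": 1.0, "dendrite": 1.0, "hillock": 1.0, "AIS": 1.0,
        "node": 2.0, "MYSA": 2.0, "FLUT": 2.0, "STIN": 2.0,
    })
    channels: dict = field(default_factory=_default_region_channels)
    e_leak: float = -72.0
    myelin_cm: float = 0.1  # uF/cm^2 per membrane pair, before lamella scaling
    myelin_g: float = 1.0  # mS/cm^2, before lamella scaling
    proximal_fraction: float = 0.1
    mid_band: tuple = (0.3, 0.6)

    def with_soma_gna(self, gna: float) -> "RegionMembraneSpec":
        ch = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in self.channels.items()}
        grads = dict(ch["soma_gradients"])
        grads["na_fast"] = (gna, grads["na_fast"][1])
        ch["soma_gradients"] = grads
        return replace(self, channels=ch)

    def with_ais_gna(self, gna: float) -> "RegionMembraneSpec":
        ch = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in self.channels.items()}
        ais = dict(ch["ais"])
        ais["na_fast"] = gna
        ch["ais"] = ais
        hil = dict(ch["hillock_ais_end"])
        hil["na_fast"] = gna
        ch["hillock_ais_end"] = hil
        return replace(self, channels=ch)


# ---------------------------------------------------------------------------
# The assembled model


@dataclass
class PlacedChannel:
    """One conductance type instantiated on a set of compartments."""

    spec: ChannelSpec
    comp_idx: np.ndarray  # int array
    gmax_uS: np.ndarray  # absolute conductance per compartment


@dataclass
class CableModel:
    """Fully assembled compartment network (arrays indexed by compartment)."""

    n: int
    parent: np.ndarray  # parent[0] == -1 (soma root)
    region: list[str]
    length: np.ndarray  # um
    diam: np.ndarray  # um
    area_cm2: np.ndarray
    cm_nF: np.ndarray  # membrane (axolemma) capacitance
    g_axial_uS: np.ndarray  # axial conductance to parent (0 at root)
    has_peri: np.ndarray  # bool
    myelin_c_nF: np.ndarray
    myelin_g_uS: np.ndarray
    g_periax_uS: np.ndarray  # periaxonal axial conductance to parent's layer
    g_periax_ground_uS: np.ndarray  # boundary leak of the layer to the bath
    channels: list[PlacedChannel]
    ca_comps: np.ndarray  # compartments carrying a Ca2+ pool
    ca_params: dict  # k, tau, ca_min, ca_o, T
    sites: dict  # name -> compartment index
    meta: dict = field(default_factory=dict)

    def site(self, name) -> int:
        if isinstance(name, (int, np.integer)):
            return int(name)
        if name not in self.sites:
            raise KeyError(f"unknown site {name!r}; have e.g. "
                           f"{sorted(self.sites)[:8]}...")
        return self.sites[name]

    @property
    def somadendritic_area_cm2(self) -> float:
        idx = [i for i, r in enumerate(self.region) if r in ("soma", "dendrite")]
        return float(self.area_cm2[idx].sum())

    def region_summary(self) -> dict:
        """Per-region compartment count, membrane area, and mean densities.

        Densities are area-weighted means in mS/cm^2; the blueprint of the
        built model in summary form.
        """
        out: dict = {}
        for r in sorted(set(self.region)):
            idx = [i for i, rr in enumerate(self.region) if rr == r]
            area = float(self.area_cm2[idx].sum())
            out[r] = {"n_compartments": len(idx), "area_cm2": area,
                      "densities_mS_cm2": {}}
        for pc in self.channels:
            for r in out:
                idx = [j for j, c in enumerate(pc.comp_idx)
                       if self.region[int(c)] == r]
                if not idx:
                    continue
                g = float(pc.gmax_uS[idx].sum()) / 1e3  # mS
                area = float(self.area_cm2[pc.comp_idx[idx]].sum())
                out[r]["densities_mS_cm2"][pc.spec.name] = g / area
        return out

    def model_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.parent, self.length, self.diam, self.area_cm2,
                    self.cm_nF, self.g_axial_uS, self.myelin_c_nF,
                    self.myelin_g_uS, self.g_periax_uS,
                    self.g_periax_ground_uS):
            h.update(np.ascontiguousarray(arr).tobytes())
        for pc in self.channels:
            h.update(pc.spec.name.encode())
            h.update(np.ascontiguousarray(pc.comp_idx).tobytes())
            h.update(np.ascontiguousarray(pc.gmax_uS).tobytes())
        return h.hexdigest()[:16]


def _compartmentize(sec: Section):
    """Split a section into nseg compartments: lengths, areas, mean diams."""
    nseg = sec.nseg
    arc = sec.arc_positions()
    total = arc[-1]
    if total == 0:
        # zero-length stub: treat as a single point compartment
        d = float(sec.points[0, 3])
        return (np.full(nseg, 0.0), np.full(nseg, 0.0), np.full(nseg, d))
    bounds = np.linspace(0.0, total, nseg + 1)
    # resample points at compartment boundaries so frusta split exactly
    allpos = np.unique(np.concatenate([arc, bounds]))
    x = np.interp(allpos, arc, sec.points[:, 0])
    yy = np.interp(allpos, arc, sec.points[:, 1])
    z = np.interp(allpos, arc, sec.points[:, 2])
    dd = np.interp(allpos, arc, sec.points[:, 3])
    pts = np.column_stack([x, yy, z, dd])
    d3 = np.diff(pts[:, :3], axis=0)
    L = np.sqrt((d3 * d3).sum(axis=1))
    r = pts[:, 3] / 2.0
    dr = np.diff(r)
    slant = np.sqrt(L * L + dr * dr)
    pair_area = math.pi * (r[:-1] + r[1:]) * slant
    pair_mid = 0.5 * (allpos[:-1] + allpos[1:])
    which = np.clip(np.searchsorted(bounds, pair_mid) - 1, 0, nseg - 1)
    lengths = np.bincount(which, weights=L, minlength=nseg)
    areas = np.bincount(which, weights=pair_area, minlength=nseg)
    dmid = 0.5 * (pts[:-1, 3] + pts[1:, 3])
    dsum = np.bincount(which, weights=dmid * L, minlength=nseg)
    with np.errstate(invalid="ignore", divide="ignore"):
        diams = np.where(lengths > 0, dsum / np.maximum(lengths, 1e-300),
                         pts[0, 3])
    return lengths, areas, diams


def _half_axial_MOhm(length_um: float, diam_um: float) -> float:
    """Half-compartment axial resistance (MOhm) of a cylinder."""
    if length_um == 0:
        return 0.0
    area_um2 = math.pi * (diam_um / 2.0) ** 2
    return RHO_AXIAL * (length_um / 2.0) * 1e4 / area_um2 * 1e-6


PERIAX_WIDTH_BY_REGION = {"MYSA": "mysa_periax_width",
                          "FLUT": "flut_periax_width",
                          "STIN": "stin_periax_width"}


def assign_conductances(
    m: Morphology,
    spec: RegionMembraneSpec,
    L_avg: float,
    efferent: EfferentSpec | None = None,
    channel_set: dict[str, ChannelSpec] | None = None,
) -> CableModel:
    """Discretise a labelled morphology into a :class:`CableModel`.

    ``m`` must already contain the efferent sections (see
    :func:`attach_efferent`); ``L_avg`` is the cell's mean terminal path
    distance, which sets the spatial extent of the dendritic conductance
    gradients.
    """
    eff = efferent or EfferentSpec()
    chans = channel_set or load_channel_set()
    c_my_eff, g_my_eff = lamella_scale(eff, spec.myelin_cm, spec.myelin_g)

    # ---- flatten sections to compartments
    comp_parent: list[int] = []
    comp_region: list[str] = []
    comp_len: list[float] = []
    comp_diam: list[float] = []
    comp_area: list[float] = []
    comp_path: list[float] = []  # path distance from soma centre (dendrites)
    first_comp: dict[int, int] = {}
    last_comp: dict[int, int] = {}

    if m.sections[m.root].region != "soma":
        raise BuildError("root section must be the soma")
    for si in range(len(m.sections)):
        sec = m.sections[si]
        lengths, areas, diams = _compartmentize(sec)
        base_path = (m.path_distance_to_start(si)
                     if sec.region == "dendrite" else 0.0)
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        for j in range(sec.nseg):
            idx = len(comp_parent)
            if j == 0:
                if sec.parent is None:
                    parent = -1
                else:
                    psec = m.sections[sec.parent]
                    pj = min(int(sec.parent_pos * psec.nseg), psec.nseg - 1)
                    parent = first_comp[sec.parent] + pj
            else:
                parent = idx - 1
            comp_parent.append(parent)
            comp_region.append(sec.region)
            comp_len.append(float(lengths[j]))
            comp_diam.append(float(diams[j]))
            comp_area.append(float(areas[j]))
            comp_path.append(base_path + float(0.5 * (cum[j] + cum[j + 1])))
        first_comp[si] = len(comp_parent) - sec.nseg
        last_comp[si] = len(comp_parent) - 1

    n = len(comp_parent)
    parent = np.array(comp_parent, dtype=np.int64)
    region = comp_region
    length = np.array(comp_len)
    diam = np.array(comp_diam)
    area_cm2 = np.array(comp_area) * 1e-8  # um^2 -> cm^2
    path = np.array(comp_path)

    if np.any(parent[1:] < 0) or parent[0] != -1:
        raise BuildError("compartment graph is not rooted at the soma")

    # ---- axial conductances (child half + parent half in series)
    half = np.array([_half_axial_MOhm(length[i], diam[i]) for i in range(n)])
    g_ax = np.zeros(n)
    for i in range(1, n):
        R = half[i] + half[parent[i]]
        if R <= 0:
            R = 1e-6  # zero-length junction: effectively fused
        g_ax[i] = 1.0 / R  # uS

    # ---- membrane capacitance
    cm_spec = spec.cm
    cm_nF = np.array([cm_spec[region[i]] * area_cm2[i] * 1e3 for i in range(n)])

    # ---- double-cable layer
    has_peri = np.array([region[i] in PERIAX_WIDTH_BY_REGION for i in range(n)])
    myelin_c_nF = np.zeros(n)
    myelin_g_uS = np.zeros(n)
    g_periax = np.zeros(n)
    g_periax_ground = np.zeros(n)
    half_peri = np.zeros(n)
    for i in range(n):
        if not has_peri[i]:
            continue
        myelin_c_nF[i] = c_my_eff * area_cm2[i] * 1e3
        myelin_g_uS[i] = g_my_eff * area_cm2[i] * 1e3
        w = getattr(eff, PERIAX_WIDTH_BY_REGION[region[i]])
        half_peri[i] = 0.5 * periaxonal_resistance(
            diam[i], w, RHO_PERIAXONAL, length[i])
    for i in range(1, n):
        p = parent[i]
        if has_peri[i] and has_peri[p]:
            g_periax[i] = 1.0 / (half_peri[i] + half_peri[p])
        elif has_peri[i] and not has_peri[p]:
            # layer opens into the bath at the node/AIS boundary
            g_periax_ground[i] += 1.0 / half_peri[i]
        elif has_peri[p] and not has_peri[i]:
            g_periax_ground[p] += 1.0 / half_peri[p]

    # ---- channel densities per compartment
    density: list[dict[str, float]] = [dict() for _ in range(n)]
    cfg = spec.channels
    prox_x = spec.proximal_fraction * L_avg
    band_lo, band_hi = spec.mid_band[0] * L_avg, spec.mid_band[1] * L_avg

    hillock_total = eff.hillock_length
    # hillock compartments: fractional position soma end -> AIS end
    hillock_pos: dict[int, float] = {}
    for si, sec in enumerate(m.sections):
        if sec.region == "hillock":
            for j in range(sec.nseg):
                hillock_pos[first_comp[si] + j] = (j + 0.5) / sec.nseg

    for i in range(n):
        r = region[i]
        dens = density[i]
        if r == "soma":
            for name, (gp, _gd) in cfg["soma_gradients"].items():
                dens[name] = gp
            dens["h_cn"] = cfg["g_h"]
        elif r == "dendrite":
            x = path[i]
            for name, (gp, gd) in cfg["soma_gradients"].items():
                if x <= prox_x and prox_x > 0:
                    dens[name] = gp + (gd - gp) * (x / prox_x)
                else:
                    dens[name] = gd
            dens["h_cn"] = cfg["g_h"]
            if band_lo < x < band_hi:
                for name, g in cfg["mid_dendrite"].items():
                    dens[name] = dens.get(name, 0.0) + g
        elif r == "hillock":
            f = hillock_pos[i]
            a, b = cfg["hillock_soma_end"], cfg["hillock_ais_end"]
            for name in a:
                dens[name] = a[name] + (b[name] - a[name]) * f
        elif r == "AIS":
            dens.update(cfg["ais"])
        elif r == "node":
            dens.update(cfg["node"])
        elif r in ("MYSA", "FLUT", "STIN"):
            dens.update(cfg[r])
        else:
            raise BuildError(f"compartment {i}: unlabeled region {r!r}")

    # ---- group into PlacedChannels
    placed: list[PlacedChannel] = []
    names = sorted({nm for d in density for nm in d})
    for nm in names:
        if nm not in chans:
            raise BuildError(f"density given for unknown channel {nm!r}")
        idx = np.array([i for i in range(n) if nm in density[i]], dtype=np.int64)
        g = np.array([density[i][nm] * area_cm2[i] * 1e3 for i in idx])
        ch = chans[nm]
        if nm == "leak":
            ch = replace(ch, reversal=spec.e_leak)
        placed.append(PlacedChannel(spec=ch, comp_idx=idx, gmax_uS=g))

    ca_comps = np.array(
        [i for i in range(n)
         if any(nm in density[i] for nm in ("ca_ht", "ca_lt", "k_ca"))],
        dtype=np.int64)

    # ---- site registry
    sites: dict[str, int] = {}
    node_counter = 0
    for si, sec in enumerate(m.sections):
        r = sec.region
        if r == "soma":
            sites["soma"] = first_comp[si]  # centre: boundary of the 2 cylinders
        elif r == "AIS":
            for j in range(sec.nseg):
                sites[f"ais[{j + 1}]"] = first_comp[si] + j
            sites["ais_mid"] = first_comp[si] + sec.nseg // 2
            sites["ais_end"] = last_comp[si]
        elif r == "hillock":
            sites["hillock"] = first_comp[si]
        elif r == "node":
            node_counter += 1
            sites[f"node[{node_counter}]"] = first_comp[si]
    sites["n_nodes"] = node_counter  # convenience, not a compartment

    n_nodes = sites.pop("n_nodes")

    model = CableModel(
        n=n, parent=parent, region=region, length=length, diam=diam,
        area_cm2=area_cm2, cm_nF=cm_nF, g_axial_uS=g_ax, has_peri=has_peri,
        myelin_c_nF=myelin_c_nF, myelin_g_uS=myelin_g_uS,
        g_periax_uS=g_periax, g_periax_ground_uS=g_periax_ground,
        channels=placed, ca_comps=ca_comps,
        # Ca influx gain corresponds to a ~0.013 um submembrane shell; with
        # the sparse high-threshold Ca density it yields a few-mV AHP with
        # the ~20 ms latency and tens-of-ms decay typical of these cells.
        ca_params={"k": 4.0, "tau": 35.0, "ca_min": 1e-4, "ca_o": 2.0,
                   "T": 309.15},
        sites=sites,
        meta={"L_avg": L_avg, "n_nodes": n_nodes,
              "efferent": eff, "membrane": spec},
    )
    return model


def build_cell(
    morph: Morphology,
    membrane: RegionMembraneSpec | None = None,
    efferent: EfferentSpec | None = None,
    channel_set: dict[str, ChannelSpec] | None = None,
) -> CableModel:
    """Somato-dendritic morphology -> complete cable model.

    Attaches the efferent pathway, measures the mean terminal path distance
    (which scales the dendritic gradients) and distributes all conductances.
    The morphology should already be resegmented to the working resolution.
    """
    membrane = membrane or RegionMembraneSpec()
    efferent = efferent or EfferentSpec()
    mm = morphometrics(morph)
    full = attach_efferent(morph, efferent)
    return assign_conductances(full, membrane, mm.mean_terminal_distance,
                               efferent=efferent, channel_set=channel_set)
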