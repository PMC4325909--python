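"""Branched neuronal morphologies: SWC I/O, validation, resegmentation, metrics.

A :class:`Morphology` is a tree of :class:`Section` objects.  Each section is
an unbranched neurite described by ordered 3D sample points with diameters
(the SWC convention); it ends where the neurite bifurcates or terminates.
Sections carry a region label (``soma``, ``dendrite``, ``hillock``, ``AIS``,
``node``, ``MYSA``, ``FLUT``, ``STIN``) and a compartment count ``nseg`` used
by the discretisation.

Spherical somata encoded as a single SWC sample are expanded to the standard
two-cylinder convention: two cylindrical compartments of diameter *d*, each
of length *d*/2, so the soma surface equals pi*d^2 (no end caps).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "MorphometricSummary",
    "SWCParseError",
    "StructureError",
    "read_swc",
    "write_swc",
    "resegment",
    "check_d_lambda",
    "morphometrics",
]

REGIONS = ("soma", "dendrite", "hillock", "AIS", "node", "MYSA", "FLUT", "STIN")


class SWCParseError(ValueError):
    """Malformed SWC content (bad column count, non-numeric field, bad radius)."""


class StructureError(ValueError):
    """Invalid tree topology (orphan parent, cycle, multiple roots)."""


@dataclass
class Section:
    """An unbranched neurite: ordered ``(x, y, z, diameter)`` samples in um."""

    points: np.ndarray  # (N, 4) float array
    parent: int | None = None  # index of parent section, None for root
    parent_pos: float = 1.0  # attachment position on parent (0..1 arc)
    region: str = "dendrite"
    nseg: int = 1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise ValueError("points must be an (N, 4) array")
        if np.any(self.points[:, 3] <= 0):
            raise ValueError("all diameters must be positive")
        if self.nseg < 1:
            raise ValueError("nseg must be >= 1")

    @property
    def length(self) -> float:
        """Arc length: sum of 3D point-to-point distances (um)."""
        d = np.diff(self.points[:, :3], axis=0)
        return float(np.sqrt((d * d).sum(axis=1)).sum())

    @property
    def area(self) -> float:
        """Lateral surface: sum of frustum areas over point pairs (um^2)."""
        return float(_pair_areas(self.points).sum())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each sample point, starting at 0."""
        d = np.diff(self.points[:, :3], axis=0)
        seg = np.sqrt((d * d).sum(axis=1))
        return np.concatenate([[0.0], np.cumsum(seg)])

    def diameter_at(self, pos: float) -> float:
        """Diameter linearly interpolated at relative arc position ``pos``."""
        arc = self.arc_positions()
        total = arc[-1]
        if total == 0:
            return float(self.points[0, 3])
        return float(np.interp(pos * total, arc, self.points[:, 3]))


def _pair_areas(points: np.ndarray) -> np.ndarray:
    """Lateral frustum area for each consecutive point pair.

    The slant height combines the 3D distance between points with the radius
    change, so a constant-diameter pair reduces to a cylinder, pi*d*L.
    """
    if len(points) < 2:
        return np.zeros(0)
    d = np.diff(points[:, :3], axis=0)
    L = np.sqrt((d * d).sum(axis=1))
    r = points[:, 3] / 2.0
    dr = np.diff(r)
    slant = np.sqrt(L * L + dr * dr)
    return math.pi * (r[:-1] + r[1:]) * slant


@dataclass
class Morphology:
    """A validated tree of sections with exactly one root."""

    sections: list[Section] = field(default_factory=list)
    soma_sections: list[int] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [i for i, s in enumerate(self.sections) if s.parent is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        for i, s in enumerate(self.sections):
            if s.parent is not None:
                if not (0 <= s.parent < i):
                    raise StructureError(
                        f"section {i}: parent index {s.parent} is not an "
                        "earlier valid section"
                    )
            if s.region not in REGIONS:
                raise StructureError(f"section {i}: unknown region {s.region!r}")
            if np.any(s.points[:, 3] <= 0):
                raise ValueError(f"section {i}: non-positive diameter")

    @property
    def root(self) -> int:
        return next(i for i, s in enumerate(self.sections) if s.parent is None)

    def children_of(self, idx: int) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == idx]

    def dendrite_sections(self) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.region == "dendrite"]

    def path_distance_to_start(self, idx: int) -> float:
        """Arc distance from the soma centre to the start of section ``idx``.

        The soma contributes nothing: dendritic path distances are measured
        from the soma centre, following the two-cylinder soma convention in
        which dendrites attach at the soma midpoint.
        """
        dist = 0.0
        s = self.sections[idx]
        while s.parent is not None:
            p = self.sections[s.parent]
            if p.region == "soma":
                break
            dist += s.parent_pos * p.length
            s = p
        return dist


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Type code 1 is soma, 3 (and, permissively, 4) dendrite.  Radii are
    converted to diameters.  A single-sample soma is expanded to the
    two-cylinder convention (two cylinders of diameter d and length d/2
    each); multi-sample somata keep their samples.
    """
    with open(path) as fh:
        text = fh.read()
    return _parse_swc(text, source=str(path))


def _parse_swc(text: str, source: str = "<string>") -> Morphology:
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(f"{source}:{lineno}: expected 7 columns, got {len(cols)}")
        try:
            sid = int(cols[0])
            typ = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            pid = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(f"{source}:{lineno}: non-numeric field ({exc})") from None
        if r <= 0:
            raise SWCParseError(f"{source}:{lineno}: non-positive radius {r}")
        if sid in samples:
            raise SWCParseError(f"{source}:{lineno}: duplicate sample id {sid}")
        samples[sid] = (typ, x, y, z, 2.0 * r, pid)
        order.append(sid)

    if not samples:
        raise SWCParseError(f"{source}: no samples")

    # topology checks: orphan parents and cycles
    for sid in order:
        pid = samples[sid][5]
        if pid != -1 and pid not in samples:
            raise StructureError(f"{source}: sample {sid} has orphan parent {pid}")
    for sid in order:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise StructureError(f"{source}: cycle detected at sample {sid}")
            seen.add(cur)
            cur = samples[cur][5]

    soma_ids = [sid for sid in order if samples[sid][0] == 1]
    if not soma_ids:
        raise StructureError(f"{source}: no soma samples (type 1)")

    sections: list[Section] = []

    # --- soma section(s): one section from the soma samples, expanded to the
    # two-cylinder convention when only a single sample is present.
    if len(soma_ids) == 1:
        typ, x, y, z, d, _ = samples[soma_ids[0]]
        pts = np.array(
            [[x, y - d / 2.0, z, d], [x, y, z, d], [x, y + d / 2.0, z, d]]
        )
        soma_sec = Section(points=pts, parent=None, region="soma", nseg=2)
        soma_converted = True
    else:
        pts = np.array([list(samples[sid][1:5]) for sid in soma_ids])
        soma_sec = Section(points=pts, parent=None, region="soma",
                           nseg=max(2, len(soma_ids) - 1))
        soma_converted = False
    sections.append(soma_sec)
    soma_set = set(soma_ids)

    # --- dendrite sections: split into unbranched chains
    children: dict[int, list[int]] = {sid: [] for sid in order}
    for sid in order:
        pid = samples[sid][5]
        if pid != -1 and sid not in soma_set:
            children.setdefault(pid, []).append(sid)

    n_children = {sid: len(children.get(sid, [])) for sid in order}

    # chain starts: non-soma samples whose parent is soma, or whose parent
    # is a branch point (>=2 children), considered in file order
    sec_of_sample: dict[int, int] = {sid: 0 for sid in soma_set}
    for sid in order:
        if sid in soma_set:
            continue
        pid = samples[sid][5]
        starts_chain = (
            pid == -1 or pid in soma_set or n_children.get(pid, 0) >= 2
        )
        if not starts_chain:
            continue
        chain = [sid]
        cur = sid
        while n_children.get(cur, 0) == 1:
            cur = children[cur][0]
            chain.append(cur)
        pid0 = samples[sid][5]
        if pid0 == -1:
            raise StructureError(f"{source}: dendrite sample {sid} has no parent")
        parent_sec = sec_of_sample[pid0]
        pts_list = []
        if pid0 not in soma_set:
            # include parent sample so the connecting segment belongs here
            pts_list.append(list(samples[pid0][1:5]))
        pts_list.extend(list(samples[c][1:5]) for c in chain)
        if len(pts_list) == 1:
            # degenerate single point attached to soma: make a zero-length stub
            pts_list = [pts_list[0], pts_list[0]]
        sec = Section(
            points=np.array(pts_list),
            parent=parent_sec,
            parent_pos=0.5 if pid0 in soma_set else 1.0,
            region="dendrite",
        )
        sections.append(sec)
        idx = len(sections) - 1
        for c in chain:
            sec_of_sample[c] = idx

    m = Morphology(
        sections=sections,
        soma_sections=[0],
        metadata={"source": source, "units": "um",
                  "soma_two_cylinder_expanded": soma_converted},
    )
    return m


def write_swc(m: Morphology, path) -> None:
    """Write a morphology back to standard SWC (soma type 1, dendrites 3)."""
    buf = io.StringIO()
    buf.write("# written by axosoma\n")
    next_id = 1
    last_id_of_section: dict[int, int] = {}
    type_code = {"soma": 1, "dendrite": 3}
    for idx, sec in enumerate(m.sections):
        tc = type_code.get(sec.region, 3)
        start = 0
        if sec.parent is not None and m.sections[sec.parent].region != "soma":
            # first point duplicates the parent's last sample
            start = 1
        for k in range(start, len(sec.points)):
            x, y, z, d = sec.points[k]
            if k == start:
                if sec.parent is None:
                    pid = -1
                else:
                    pid = last_id_of_section[sec.parent]
            else:
                pid = next_id - 1
            buf.write(f"{next_id} {tc} {x:.6f} {y:.6f} {z:.6f} {d / 2.0:.6f} {pid}\n")
            next_id += 1
        last_id_of_section[idx] = next_id - 1
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Resegmentation and the d_lambda rule


def resegment(m: Morphology, max_branch_len: float = 20.0) -> Morphology:
    """Raise ``nseg`` so every dendritic compartment is <= ``max_branch_len`` um.

    Geometry (points, lengths, surfaces) is untouched; only the compartment
    counts change, so the operation is idempotent.
    """
    if max_branch_len <= 0:
        raise ValueError("max_branch_len must be positive")
    new_sections = []
    for sec in m.sections:
        nseg = sec.nseg
        if sec.region == "dendrite" and sec.length > 0:
            nseg = max(nseg, math.ceil(sec.length / max_branch_len))
        new_sections.append(
            Section(points=sec.points.copy(), parent=sec.parent,
                    parent_pos=sec.parent_pos, region=sec.region, nseg=nseg)
        )
    return Morphology(sections=new_sections, soma_sections=list(m.soma_sections),
                      metadata=dict(m.metadata))


def check_d_lambda(
    m: Morphology,
    f: float = 100.0,
    fraction: float = 0.1,
    Ri: float = 70.0,
    cm: float = 1.0,
) -> dict[int, int]:
    """Minimal odd ``nseg`` per section under the AC length-constant rule.

    For a uniform cylinder of diameter *d* (um), axial resistivity *Ri*
    (Ohm*cm) and specific capacitance *cm* (uF/cm^2), the AC length constant
    at frequency *f* (Hz) is::

        lambda_f = 1e5 * 0.5 * sqrt(d_um / (pi * f * Ri * cm))   [um]

    Each section's compartments must be no longer than ``fraction * lambda_f``
    evaluated at the section's length-weighted mean diameter.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    out: dict[int, int] = {}
    for i, sec in enumerate(m.sections):
        L = sec.length
        if L == 0:
            out[i] = 1
            continue
        arc = sec.arc_positions()
        seglen = np.diff(arc)
        dmid = 0.5 * (sec.points[:-1, 3] + sec.points[1:, 3])
        dmean = float((dmid * seglen).sum() / seglen.sum())
        lam = 1e5 * 0.5 * math.sqrt(dmean / (math.pi * f * Ri * cm))
        n = max(1, math.ceil(L / (fraction * lam)))
        if n % 2 == 0:
            n += 1
        out[i] = n
    return out


# ---------------------------------------------------------------------------
# Morphometrics


@dataclass
class MorphometricSummary:
    """Per-cell morphometric measures of the somato-dendritic tree."""

    n_sections: int
    n_compartments: int
    n_primary_dendrites: int
    soma_diameter: float
    sum_primary_diameters: float
    soma_surface: float
    dendrite_surface: float
    dendrite_to_soma_surface_ratio: float
    mean_terminal_distance: float

    # Column names follow the imported-reconstruction summary table layout.
    CSV_COLUMNS = (
        "Number of dendritic sections",
        "Number of dendritic compartments",
        "Number of primary dendrites",
        "Soma diameter (um)",
        "Sum of the diameters of the primary dendrites (um)",
        "Soma surface (um2)",
        "Surface of dendrites tree (um2)",
        "Ratio of dendrites to soma surface",
        "Dendrites mean terminal distance",
    )

    def as_row(self) -> list[float]:
        return [
            self.n_sections, self.n_compartments, self.n_primary_dendrites,
            self.soma_diameter, self.sum_primary_diameters, self.soma_surface,
            self.dendrite_surface, self.dendrite_to_soma_surface_ratio,
            self.mean_terminal_distance,
        ]


def morphometrics(m: Morphology) -> MorphometricSummary:
    """Measure the somato-dendritic tree.

    Surfaces are sums of lateral frustum areas over consecutive point pairs.
    The mean terminal distance is the mean arc (path) distance from the soma
    centre to every dendritic terminal point.
    """
    soma_surface = 0.0
    soma_diams: list[float] = []
    for i in m.soma_sections:
        sec = m.sections[i]
        soma_surface += sec.area
        soma_diams.extend(sec.points[:, 3].tolist())
    soma_diameter = float(np.mean(soma_diams)) if soma_diams else 0.0

    dend = m.dendrite_sections()
    dendrite_surface = sum(m.sections[i].area for i in dend)
    n_compartments = sum(m.sections[i].nseg for i in dend)

    primaries = [
        i for i in dend
        if m.sections[i].parent is not None
        and m.sections[m.sections[i].parent].region == "soma"
    ]
    sum_primary = sum(float(m.sections[i].points[0, 3]) for i in primaries)

    # terminal path distances (soma centre -> dendritic tips)
    has_child = {i: False for i in dend}
    for i in dend:
        p = m.sections[i].parent
        if p in has_child:
            has_child[p] = True
    terminals = [i for i in dend if not has_child[i]]
    tdists = [m.path_distance_to_start(i) + m.sections[i].length for i in terminals]
    mean_td = float(np.mean(tdists)) if tdists else 0.0

    ratio = dendrite_surface / soma_surface if soma_surface > 0 else 0.0
    return MorphometricSummary(
        n_sections=len(dend),
        n_compartments=n_compartments,
        n_primary_dendrites=len(primaries),
        soma_diameter=soma_diameter,
        sum_primary_diameters=sum_primary,
        soma_surface=soma_surface,
        dendrite_surface=dendrite_surface,
        dendrite_to_soma_surface_ratio=ratio,
        mean_terminal_distance=mean_td,
    )
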