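"""Electrotonic analysis: length constants and directional attenuation.

For an infinite uniform cable the steady voltage decays as
``V(x) = V0 * exp(-x / lambda)`` with ``lambda = sqrt((Rm/Ri) * d/4)``.
Real neurites are neither uniform nor infinite, so the useful measure is
the electrotonic distance between two points, ``X = ln(V0 / Vx)``, obtained
from the actual voltage attenuation of the model linearized around rest
(gates frozen at their resting values, conductances at the resting chord
values).  An effective length constant for a path is then ``path
distance / X``; it differs sharply between the two directions of current
flow wherever geometry is strongly non-uniform, as at the axon-somatic
junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .builder import CableModel
from .solver import SolverState, _Workspace, _membrane_update

__all__ = [
    "ElectrotonicReport", "lambda_analytic", "linearized_matrix",
    "attenuation_profile", "directional_lambda", "path_distance",
]


def lambda_analytic(Rm: float, Ri: float, d: float) -> float:
    """DC length constant (um) of a uniform cable.

    ``Rm`` in Ohm cm^2, ``Ri`` in Ohm cm, ``d`` in um.
    """
    if Rm <= 0 or Ri <= 0 or d <= 0:
        raise ValueError("Rm, Ri, d must be positive")
    d_cm = d * 1e-4
    lam_cm = math.sqrt((Rm / Ri) * (d_cm / 4.0))
    return lam_cm * 1e4


def _resting_conductances(model: CableModel, state: SolverState):
    """Per-compartment chord membrane conductance (uS) at the given state."""
    ws = _Workspace(model, dt=0.025, theta=0.5)
    probe = state.copy()
    _membrane_update(model, probe, ws, dt=1e-9)  # negligible gate motion
    return ws.g_mem.copy(), ws

Complex = np.complex128


def linearized_matrix(model: CableModel, state: SolverState,
                      frequency: float = 0.0):
    """Sparse admittance matrix of the model linearized at ``state``.

    Unknowns are the intracellular potentials followed by the periaxonal
    potentials of double-cable compartments.  At ``frequency`` > 0 (Hz) the
    matrix is complex, including the capacitive admittance j*2*pi*f*C.
    """
    n = model.n
    g_mem, ws = _resting_conductances(model, state)
    peri_ids = np.nonzero(model.has_peri)[0]
    peri_pos = {int(c): n + j for j, c in enumerate(peri_ids)}
    ntot = n + len(peri_ids)
    dtype = Complex if frequency > 0 else float
    A = sp.lil_matrix((ntot, ntot), dtype=dtype)

    jw = 2j * math.pi * frequency * 1e-3 if frequency > 0 else 0.0  # 1/ms

    for i in range(n):
        ym = g_mem[i] + jw * model.cm_nF[i]  # uS (nF/ms == uS)
        if model.has_peri[i]:
            pi = peri_pos[i]
            A[i, i] += ym
            A[i, pi] -= ym
            A[pi, i] -= ym
            A[pi, pi] += ym
            ymy = model.myelin_g_uS[i] + jw * model.myelin_c_nF[i]
            A[pi, pi] += ymy + model.g_periax_ground_uS[i]
        else:
            A[i, i] += ym
    for i in range(1, n):
        p = model.parent[i]
        a = model.g_axial_uS[i]
        A[i, i] += a
        A[p, p] += a
        A[i, p] -= a
        A[p, i] -= a
        gpx = model.g_periax_uS[i]
        if gpx > 0:
            pi, pp = peri_pos[i], peri_pos[int(p)]
            A[pi, pi] += gpx
            A[pp, pp] += gpx
            A[pi, pp] -= gpx
            A[pp, pi] -= gpx
    return A.tocsc()


def transfer_voltages(model: CableModel, state: SolverState, source,
                      frequency: float = 0.0, amp_nA: float = 1.0):
    """Voltage deviation at every compartment for a small source current."""
    src = model.site(source)
    if model.area_cm2[src] == 0:
        raise ValueError(f"source {source!r} is a zero-area compartment")
    A = linearized_matrix(model, state, frequency)
    rhs = np.zeros(A.shape[0], dtype=A.dtype)
    rhs[src] = amp_nA
    v = spla.spsolve(A, rhs)
    return v[: model.n]


def attenuation_profile(
    model: CableModel,
    state: SolverState,
    source,
    measure_sites,
    frequency: float = 0.0,
) -> dict:
    """Attenuation ``V0/Vx`` and ``X = ln(V0/Vx)`` per measurement site."""
    v = transfer_voltages(model, state, source, frequency)
    v0 = abs(v[model.site(source)])
    out = {}
    for site in measure_sites:
        vx = abs(v[model.site(site)])
        ratio = v0 / vx
        out[site] = {"ratio": float(ratio), "X": float(np.log(ratio))}
    return out


def path_distance(model: CableModel, a, b) -> float:
    """Arc distance (um) between the centres of two compartments."""
    ia, ib = model.site(a), model.site(b)

    def chain(i):
        out = [i]
        while model.parent[out[-1]] >= 0:
            out.append(int(model.parent[out[-1]]))
        return out

    ca, cb = chain(ia), chain(ib)
    sb = set(cb)
    common = next(x for x in ca if x in sb)

    def up_to_common(start):
        # centre of start -> centre of common: half of each endpoint, full
        # lengths of strict intermediates
        if start == common:
            return 0.0
        d = model.length[start] / 2.0 + model.length[common] / 2.0
        i = int(model.parent[start])
        while i != common:
            d += model.length[i]
            i = int(model.parent[i])
        return d

    return float(up_to_common(ia) + up_to_common(ib))


@dataclass
class ElectrotonicReport:
    """Directional attenuation between two sites."""

    source: str
    destination: str
    direction: str
    X: float  # ln attenuation
    distance: float  # um
    effective_lambda: float  # um

    def as_dict(self):
        return {
            "source": self.source, "destination": self.destination,
            "direction": self.direction, "ln_attenuation": self.X,
            "distance_um": self.distance, "lambda_um": self.effective_lambda,
        }


def directional_lambda(
    model: CableModel,
    state: SolverState,
    A="soma",
    B="ais[1]",
    frequency: float = 0.0,
) -> tuple[ElectrotonicReport, ElectrotonicReport]:
    """Effective length constants in both directions between two sites.

    For each direction the source current is injected at the upstream site,
    ``X = ln(V_source / V_destination)`` measured, and ``lambda = path
    distance / X``.  Returns the (A->B, B->A) report pair.

    The default destination is the proximal AIS compartment: measured there,
    the soma->AIS attenuation reflects the junction rather than the AIS's
    own cable decay (with its high leak the 450 um AIS spans ~3 DC length
    constants), which is the convention under which the directional
    asymmetry of the axon-somatic junction is visible.  The endpoints and
    distance are recorded in the reports.
    """
    if model.site(A) == model.site(B):
        raise ValueError("sites must differ")
    dist = path_distance(model, A, B)
    reports = []
    for src, dst in ((A, B), (B, A)):
        prof = attenuation_profile(model, state, src, [dst], frequency)
        X = prof[dst]["X"]
        lam = dist / X if X > 0 else float("inf")
        reports.append(ElectrotonicReport(
            source=str(src), destination=str(dst),
            direction=f"{src}->{dst}", X=X, distance=dist,
            effective_lambda=lam))
    return reports[0], reports[1]
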