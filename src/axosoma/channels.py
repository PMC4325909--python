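"""Membrane mechanisms: HH-style gated conductances, Ca2+ pool, leak.

Every conductance follows the Hodgkin-Huxley formalism: a maximal density
``gmax`` (mS/cm^2), a reversal potential (mV, or a dynamic Ca2+ Nernst
potential), and a product of gating variables ``x^p`` whose kinetics are
given either as forward/backward rates ``alpha(V), beta(V)`` (1/ms) or as
steady-state/time-constant pairs ``x_inf(V), tau_x(V)``.  Rate functions are
parametric expressions loaded from a versioned YAML data file so the full
kinetic scheme is auditable and swappable.

Two deliberate kinetic shifts reproduce the model's Na+ current alignment:
the fast Na+ gates are shifted 5 mV toward hyperpolarized potentials and the
persistent Na+ activation 15 mV toward depolarized potentials.  A shift
``delta`` is applied by evaluating the unshifted rates at ``V - delta``.

Intracellular Ca2+ follows a first-order pool: influx proportional to the
Ca2+ current and decay with a single time constant toward a resting floor;
the Ca2+ reversal potential is recomputed from the Nernst equation as the
pool fills.  The Ca2+-activated K+ conductance is gated by the pool through
a Michaelis saturation term rather than by voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "RateFn", "GateSpec", "ChannelSpec", "CaPool",
    "steady_state", "channel_current", "ca_reversal", "update_ca",
    "persistent_fraction", "load_channel_set", "dump_channel_set",
    "ProtocolError",
]

R_GAS = 8.31446  # J/(mol K)
FARADAY = 96485.33  # C/mol
DEFAULT_T = 309.15  # K (36 C)


class ProtocolError(RuntimeError):
    """A measurement protocol could not produce its defining feature."""


# ---------------------------------------------------------------------------
# Parametric rate functions


@dataclass(frozen=True)
class RateFn:
    """A parametric voltage (or calcium) function used in gate kinetics.

    Kinds
    -----
    ``exp_linear``   A*(V-vhalf) / (1 - exp(-(V-vhalf)/k)); the removable
                     singularity at V=vhalf is evaluated by series limit A*k.
    ``sigmoid``      A / (1 + exp(-(V-vhalf)/k))
    ``exponential``  A * exp((V-vhalf)/k)
    ``boltzmann``    1 / (1 + exp(-(V-vhalf)/k))       (steady states)
    ``bell``         base + amp / cosh((V-vhalf)/width) (time constants)
    ``constant``     A
    ``ca_michaelis`` ca / (ca + kd)                    (Ca-gated activation)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, V, ca=None):
        p = self.params
        V = np.asarray(V, dtype=float)
        if self.kind == "exp_linear":
            A, vh, k = p["A"], p["vhalf"], p["k"]
            x = (V - vh) / k
            with np.errstate(over="ignore"):
                denom = -np.expm1(-x)
            small = np.abs(x) < 1e-6
            safe = np.where(small, 1.0, denom)
            out = np.where(small, A * k * (1.0 + x / 2.0), A * (V - vh) / safe)
            return out
        if self.kind == "sigmoid":
            A, vh, k = p["A"], p["vhalf"], p["k"]
            return A / (1.0 + np.exp(-(V - vh) / k))
        if self.kind == "exponential":
            A, vh, k = p["A"], p["vhalf"], p["k"]
            return A * np.exp((V - vh) / k)
        if self.kind == "boltzmann":
            vh, k = p["vhalf"], p["k"]
            return 1.0 / (1.0 + np.exp(-(V - vh) / k))
        if self.kind == "bell":
            return p["base"] + p["amp"] / np.cosh((V - p["vhalf"]) / p["width"])
        if self.kind == "constant":
            return p["A"] * np.ones_like(V)
        if self.kind == "ca_michaelis":
            ca = np.asarray(ca, dtype=float)
            return ca / (ca + p["kd"])
        raise ValueError(f"unknown rate kind {self.kind!r}")


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: exponent, kinetics, and voltage shift (mV)."""

    name: str
    p: int = 1
    shift: float = 0.0
    alpha: RateFn | None = None
    beta: RateFn | None = None
    inf: RateFn | None = None
    tau: RateFn | None = None

    def __post_init__(self) -> None:
        has_ab = self.alpha is not None and self.beta is not None
        has_it = self.inf is not None and self.tau is not None
        if not (has_ab or has_it):
            raise ValueError(f"gate {self.name}: need alpha/beta or inf/tau")
        if self.p < 0:
            raise ValueError("gate exponent must be >= 0")

    @property
    def ca_dependent(self) -> bool:
        return self.inf is not None and self.inf.kind == "ca_michaelis"


def steady_state(gate: GateSpec, V, ca=None):
    """Steady-state activation and time constant at potential ``V`` (mV).

    For alpha/beta kinetics: ``x_inf = a/(a+b)``, ``tau = 1/(a+b)`` (ms).
    The gate's shift ``delta`` is applied by evaluating at ``V - delta``.
    """
    Veff = np.asarray(V, dtype=float) - gate.shift
    if gate.alpha is not None:
        a = gate.alpha(Veff)
        b = gate.beta(Veff)
        s = a + b
        return a / s, 1.0 / s
    inf = gate.inf(Veff, ca=ca)
    tau = gate.tau(Veff, ca=ca)
    return inf, tau


@dataclass(frozen=True)
class ChannelSpec:
    """A named conductance: density, reversal, and gate list.

    ``reversal`` is a potential in mV, or the marker ``"dynamic-Ca"`` for
    conductances whose reversal follows the Ca2+ Nernst potential.
    """

    name: str
    gmax: float  # mS/cm^2
    reversal: float | str
    gates: tuple[GateSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if isinstance(self.reversal, str) and self.reversal != "dynamic-Ca":
            raise ValueError("reversal must be a number or 'dynamic-Ca'")

    @property
    def dynamic_ca(self) -> bool:
        return self.reversal == "dynamic-Ca"

    def with_gmax(self, gmax: float) -> "ChannelSpec":
        return replace(self, gmax=gmax)


def channel_current(ch: ChannelSpec, V, gate_values, E: float | None = None):
    """Ionic current density I = gmax * prod(x^p) * (V - E) in uA/cm^2.

    ``gate_values`` maps gate name to value (or is a sequence in gate order).
    mS/cm^2 times mV gives uA/cm^2 directly.
    """
    if E is None:
        if ch.dynamic_ca:
            raise ValueError("dynamic-Ca channel needs an explicit reversal")
        E = float(ch.reversal)
    open_frac = 1.0
    for i, g in enumerate(ch.gates):
        x = gate_values[g.name] if isinstance(gate_values, dict) else gate_values[i]
        open_frac = open_frac * np.asarray(x, dtype=float) ** g.p
    return ch.gmax * open_frac * (np.asarray(V, dtype=float) - E)


# ---------------------------------------------------------------------------
# Calcium pool


@dataclass
class CaPool:
    """First-order intracellular Ca2+ pool (concentrations in mM).

    ``d[Ca]/dt = -k * I_Ca - ([Ca] - ca_min) / tau`` with inward (negative)
    Ca2+ current raising the concentration; ``k`` converts a current density
    (mA/cm^2) into mM/ms and corresponds to influx into a thin submembrane
    shell.
    """

    ca_i: float = 1e-4  # mM
    ca_o: float = 2.0  # mM
    k: float = 0.518  # mM cm^2 / (mA ms); 0.1 um shell, 1/(2 F depth)
    tau: float = 35.0  # ms
    ca_min: float = 1e-4  # mM

    def __post_init__(self) -> None:
        if self.ca_min <= 0 or self.ca_i < self.ca_min:
            raise ValueError("require ca_i >= ca_min > 0")


def ca_reversal(pool: CaPool, T: float = DEFAULT_T):
    """Nernst Ca2+ reversal potential (mV) at temperature ``T`` (K), z = 2."""
    ca_i = np.asarray(pool.ca_i, dtype=float)
    if np.any(ca_i <= 0) or pool.ca_o <= 0:
        raise ValueError("concentrations must be positive")
    return 1e3 * R_GAS * T / (2.0 * FARADAY) * np.log(pool.ca_o / ca_i)


def update_ca(pool: CaPool, I_ca, dt: float) -> CaPool:
    """Advance the pool one implicit (backward-Euler) step of ``dt`` ms.

    ``I_ca`` is the Ca2+ current density in mA/cm^2 (inward negative).  The
    concentration never falls below ``ca_min``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca = np.asarray(pool.ca_i, dtype=float)
    new = (ca + dt * (-pool.k * np.asarray(I_ca, dtype=float))
           + dt / pool.tau * pool.ca_min) / (1.0 + dt / pool.tau)
    new = np.maximum(new, pool.ca_min)
    out = replace(pool)
    out.ca_i = float(new) if np.ndim(new) == 0 else new
    return out


# ---------------------------------------------------------------------------
# Channel-set I/O


def _ratefn_from_dict(d: dict) -> RateFn:
    d = dict(d)
    kind = d.pop("kind")
    return RateFn(kind=kind, params=d)


def _ratefn_to_dict(r: RateFn) -> dict:
    return {"kind": r.kind, **r.params}


def load_channel_set(path=None) -> dict[str, ChannelSpec]:
    """Load named channel definitions from YAML (default: packaged set)."""
    if path is None:
        src = resources.files("axosoma").joinpath("data/channels.yaml")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    out: dict[str, ChannelSpec] = {}
    for name, cd in doc["channels"].items():
        gates = []
        for gd in cd.get("gates", []):
            gd = dict(gd)
            kw = {
                "name": gd.pop("name"),
                "p": int(gd.pop("p", 1)),
                "shift": float(gd.pop("shift", 0.0)),
            }
            for key in ("alpha", "beta", "inf", "tau"):
                if key in gd:
                    kw[key] = _ratefn_from_dict(gd.pop(key))
            gates.append(GateSpec(**kw))
        out[name] = ChannelSpec(
            name=name,
            gmax=float(cd.get("gmax", 0.0)),
            reversal=cd["reversal"],
            gates=tuple(gates),
        )
    return out


def dump_channel_set(channels: dict[str, ChannelSpec], path) -> None:
    """Write channel definitions to a YAML file (round-trips with load)."""
    doc = {"version": 1, "channels": {}}
    for name, ch in channels.items():
        gates = []
        for g in ch.gates:
            gd: dict = {"name": g.name, "p": g.p}
            if g.shift:
                gd["shift"] = g.shift
            for key in ("alpha", "beta", "inf", "tau"):
                r = getattr(g, key)
                if r is not None:
                    gd[key] = _ratefn_to_dict(r)
            gates.append(gd)
        doc["channels"][name] = {
            "gmax": ch.gmax, "reversal": ch.reversal, "gates": gates,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Persistent/transient Na+ ratio (voltage-clamp, analytic gate relaxation)


def persistent_fraction(
    gnaf: float = 15.0,
    gnap: float = 2.0,
    channels: dict[str, ChannelSpec] | None = None,
    v_rest: float = -70.0,
    v_step: float | None = None,
    t_end: float = 50.0,
    dt: float = 0.005,
) -> float:
    """Persistent Na+ plateau as % of the peak transient Na+ current.

    An isopotential somatic patch carrying the fast (``gnaf``) and persistent
    (``gnap``) Na+ densities (mS/cm^2) is voltage-clamped from rest to a
    depolarizing step.  Under clamp every gate relaxes exponentially, so the
    current time course is evaluated in closed form.  If ``v_step`` is None
    the step potential is scanned for the one maximizing the transient peak
    (the protocol used to calibrate the ~20% ratio).  Raises
    :class:`ProtocolError` when no transient peak stands out.
    """
    chans = channels if channels is not None else load_channel_set()
    naf = chans["na_fast"].with_gmax(gnaf)
    nap = chans["na_persistent"].with_gmax(gnap)

    if v_step is None:
        grid = np.arange(-40.0, 15.1, 2.5)
        peaks = [_clamp_na(naf, nap, v_rest, v, t_end, dt)[0] for v in grid]
        v_step = float(grid[int(np.argmax(peaks))])

    peak, plateau, transient_end = _clamp_na(naf, nap, v_rest, v_step,
                                             t_end, dt)
    if gnaf > 0 and peak <= transient_end * 1.05:
        raise ProtocolError(
            f"no transient peak detected at step to {v_step} mV")
    if peak == 0.0:
        return 0.0
    return 100.0 * plateau / peak


def _clamp_na(naf, nap, v_rest, v_step, t_end, dt):
    """Peak and plateau magnitude of total Na+ current under a voltage step."""
    t = np.arange(0.0, t_end + dt / 2.0, dt)
    E = float(naf.reversal)
    drive = v_step - E

    def gate_course(gate):
        x0, _ = steady_state(gate, v_rest)
        xinf, tau = steady_state(gate, v_step)
        return xinf + (x0 - xinf) * np.exp(-t / tau)

    open_f = np.ones_like(t)
    for g in naf.gates:
        open_f = open_f * gate_course(g) ** g.p
    open_p = np.ones_like(t)
    for g in nap.gates:
        open_p = open_p * gate_course(g) ** g.p
    transient = np.abs(naf.gmax * open_f * drive)  # uA/cm^2
    persistent = np.abs(nap.gmax * open_p * drive)
    # transient peak within the early window; persistent plateau at the end
    early = t <= min(10.0, t_end)
    peak = float(transient[early].max())
    plateau = float(persistent[-1])
    return peak, plateau, float(transient[-1])
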