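"""Electrophysiological protocols on assembled motoneuron models.

Basal characterisation -- rheobase (1 s somatic steps, bisection),
strength-duration curves, single-spike and AHP metrics from a brief 0.5 ms
suprathreshold pulse, and input impedance from a small somatic sinusoid --
and the antidromic protocols: a 5 nA / 0.1 ms pulse at node[15] of the
myelinated axon (17.25 mm from the soma under the node-count convention),
classification of the invasion outcome, and sweeps of AIS diameter, AIS
fast-Na+ density and somatic fast-Na+ density that map when the antidromic
spike can invade the soma.

The invasion outcome has three regimes: the spike dies before the AIS
(``FAIL_AT_AIS``), it fires the AIS but not the soma (``AIS_ONLY``, the
classical NM spike), or it invades the soma (``SOMA_INVADED``).  An AIS
"spike" requires the AIS midpoint to cross 0 mV with a peak above +10 mV,
distinguishing full spikes from large passive depolarizations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .builder import (CableModel, EfferentSpec, RegionMembraneSpec,
                      build_cell)
from .morphology import Morphology
from .channels import ProtocolError
from .solver import (Protocol, SimulationTrace, SolverState, Stimulus,
                     detect_spikes, init_steady_state, run)

__all__ = [
    "SearchError", "CellReport", "InvasionOutcome", "InvasionResult",
    "SweepResult", "rheobase", "strength_duration", "spike_metrics",
    "trace_metrics", "input_impedance", "antidromic", "characterize",
    "build_variant", "sweep_soma_gna", "sweep_ais", "spontaneous_flag",
]

AIS_SPIKE_PEAK = 10.0  # mV; full AIS spike must exceed this
SETTLE_MS = 300.0


class SearchError(RuntimeError):
    """A threshold search failed at its bound."""


# ---------------------------------------------------------------------------
# Basal characterisation


def _evokes_spike(model, state, amp, dur, dt=0.025, site="soma",
                  post_ms=20.0, max_ms=None) -> bool:
    tstop = (max_ms if max_ms is not None else dur + post_ms)
    proto = Protocol(
        stimuli=(Stimulus(site=site, delay=1.0, duration=dur, amplitude=amp),),
        record=(site,), tstop=tstop + 1.0, dt=dt)
    tr = run(model, proto, state=state, stop_after_spike_at=site,
             stop_when_settled=True)
    return len(tr.spikes[site]) > 0


def rheobase(model: CableModel, state: SolverState | None = None,
             max_duration: float = 1000.0, tol: float = 0.1,
             upper: float = 200.0) -> float:
    """Minimal long-pulse somatic current (nA) that evokes a spike.

    Bisection over the amplitude of a ``max_duration`` (default 1 s) somatic
    step, to a tolerance of ``tol`` nA.  Raises :class:`SearchError` if even
    ``upper`` nA does not fire the cell.
    """
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    lo, hi = 0.0, None
    amp = 5.0
    while amp <= upper:
        if _evokes_spike(model, state, amp, max_duration, max_ms=max_duration):
            hi = amp
            break
        lo = amp
        amp *= 2.0
    if hi is None:
        raise SearchError(f"no spike up to {upper} nA with "
                          f"{max_duration} ms pulses")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _evokes_spike(model, state, mid, max_duration, max_ms=max_duration):
            hi = mid
        else:
            lo = mid
    return hi


def strength_duration(model: CableModel, durations,
                      state: SolverState | None = None,
                      tol: float = 0.1, upper: float = 2000.0) -> dict:
    """Threshold amplitude (nA) for each stimulus duration (ms)."""
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    out = {}
    for dur in durations:
        if dur <= 0:
            raise ValueError("durations must be positive")
        lo, hi = 0.0, None
        amp = 1.0
        while amp <= upper:
            if _evokes_spike(model, state, amp, dur, max_ms=dur + 20.0):
                hi = amp
                break
            lo = amp
            amp *= 2.0
        if hi is None:
            raise SearchError(f"no spike up to {upper} nA at {dur} ms")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _evokes_spike(model, state, mid, dur, max_ms=dur + 20.0):
                hi = mid
            else:
                lo = mid
        out[float(dur)] = hi
    return out


@dataclass
class CellReport:
    """Basal electrophysiological features of one model cell."""

    rest_potential: float  # mV
    rheobase: float  # nA
    suprathreshold_stimulus: float  # nA (0.5 ms pulse, 10 nA grid)
    peak_latency: float  # ms from stimulus onset
    peak_amplitude: float  # mV, absolute maximum
    ahp_amplitude: float  # mV, min(V) - V_rest (negative)
    ahp_latency: float  # ms from stimulus onset
    ahp_duration: float  # ms below rest after the spike
    z_in_low: float  # MOhm at 0.1 Hz
    z_in_high: float  # MOhm at 100 Hz

    CSV_COLUMNS = (
        "Rest potential (mV)", "Rheobase (nA)", "Suprathreshold stimulus (nA)",
        "Peak latency (from stimulus, ms)", "Peak amplitude (mV)",
        "Maximal AHP amplitude (mV)", "Maximal AHP latency (ms)",
        "AHP duration (ms)", "Z_IN at 0.1 Hz (MOhm)", "Z_IN at 100 Hz (MOhm)",
    )

    def as_row(self):
        return [self.rest_potential, self.rheobase,
                self.suprathreshold_stimulus, self.peak_latency,
                self.peak_amplitude, self.ahp_amplitude, self.ahp_latency,
                self.ahp_duration, self.z_in_low, self.z_in_high]


def spike_metrics(model: CableModel, amplitude: float | None = None,
                  state: SolverState | None = None,
                  duration: float = 0.5, tstop: float = 150.0) -> dict:
    """Single-spike and AHP metrics from a brief somatic pulse.

    The stimulus is a ``duration`` (0.5 ms) somatic step.  When
    ``amplitude`` is None, the smallest 10 nA multiple that evokes exactly
    one spike is used.  Latencies are measured from stimulus onset; the AHP
    amplitude is ``min(V) - V_rest`` (negative) and its duration the time V
    stays below rest after the spike.
    """
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    v_rest = float(state.V[model.site("soma")])

    def run_amp(amp):
        proto = Protocol(
            stimuli=(Stimulus(site="soma", delay=1.0, duration=duration,
                              amplitude=amp),),
            record=("soma",), tstop=tstop, dt=0.025)
        return run(model, proto, state=state)

    if amplitude is None:
        amplitude = 0.0
        for mult in range(1, 41):
            tr = run_amp(10.0 * mult)
            if len(tr.spikes["soma"]) == 1:
                amplitude = 10.0 * mult
                break
        if amplitude == 0.0:
            raise ProtocolError("no 10 nA multiple up to 400 nA evokes "
                                "exactly one spike")
    tr = run_amp(amplitude)
    n_spk = len(tr.spikes["soma"])
    if n_spk != 1:
        raise ProtocolError(f"stimulus evoked {n_spk} spikes, need exactly 1")

    out = trace_metrics(tr.t, tr.V["soma"], onset=1.0, v_rest=v_rest)
    out["suprathreshold_stimulus"] = float(amplitude)
    out["trace"] = tr
    return out


def trace_metrics(t, v, onset: float, v_rest: float) -> dict:
    """Spike/AHP metrics of a single-spike voltage trace.

    Peak latency and AHP latency are measured from ``onset``; the AHP
    amplitude is ``min(V) - v_rest`` after the peak (negative for a true
    after-hyperpolarization) and its duration the contiguous time V stays
    below ``v_rest`` following the spike.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    ipk = int(np.argmax(v))
    imin = ipk + int(np.argmin(v[ipk:]))
    below = v[ipk:] < v_rest
    if below.any():
        start = int(np.argmax(below))
        after = np.nonzero(~below[start:])[0]
        n_below = int(after[0]) if len(after) else len(below) - start
        ahp_dur = float(n_below * (t[1] - t[0]))
    else:
        ahp_dur = 0.0
    return {
        "peak_latency": float(t[ipk] - onset),
        "peak_amplitude": float(v[ipk]),
        "ahp_amplitude": float(v[imin] - v_rest),
        "ahp_latency": float(t[imin] - onset),
        "ahp_duration": ahp_dur,
        "v_rest": float(v_rest),
    }


def input_impedance(model: CableModel, f: float, amp: float = 0.1,
                    state: SolverState | None = None) -> float:
    """Somatic input impedance magnitude (MOhm) at frequency ``f`` (Hz).

    Injects a small sinusoid, discards the first cycle, and divides the
    steady peak-to-peak voltage by the peak-to-peak current.  For very low
    frequencies the integration step is widened (the response is passive
    and slow) to keep the run length practical.  Raises if the stimulus
    triggers a spike.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    period = 1e3 / f  # ms
    dt = min(0.025, period / 2000.0) if period < 50.0 else min(5.0, period / 400.0)
    proto = Protocol(
        stimuli=(Stimulus(site="soma", sine_freq=f, sine_amp=amp,
                          duration=0.0),),
        record=("soma",), tstop=2.0 * period, dt=dt)
    tr = run(model, proto, state=state)
    if len(tr.spikes["soma"]) > 0:
        raise ProtocolError("sinusoid triggered a spike; reduce amp")
    mask = tr.t >= period  # keep the second cycle
    v = tr.V["soma"][mask]
    vpp = float(v.max() - v.min())
    ipp = 2.0 * amp
    return vpp / ipp  # mV / nA == MOhm


def characterize(model: CableModel, state: SolverState | None = None) -> CellReport:
    """Full basal characterisation of one cell (rheobase, spike, Z_IN)."""
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    rb = rheobase(model, state)
    sm = spike_metrics(model, state=state)
    return CellReport(
        rest_potential=sm["v_rest"], rheobase=rb,
        suprathreshold_stimulus=sm["suprathreshold_stimulus"],
        peak_latency=sm["peak_latency"], peak_amplitude=sm["peak_amplitude"],
        ahp_amplitude=sm["ahp_amplitude"], ahp_latency=sm["ahp_latency"],
        ahp_duration=sm["ahp_duration"],
        z_in_low=input_impedance(model, 0.1, state=state),
        z_in_high=input_impedance(model, 100.0, state=state),
    )


# ---------------------------------------------------------------------------
# Antidromic stimulation and sweeps


class InvasionOutcome(enum.Enum):
    FAIL_AT_AIS = "FAIL_AT_AIS"
    AIS_ONLY = "AIS_ONLY"
    SOMA_INVADED = "SOMA_INVADED"

    @property
    def rank(self) -> int:
        return ("FAIL_AT_AIS", "AIS_ONLY", "SOMA_INVADED").index(self.value)


@dataclass
class InvasionResult:
    """Outcome of one antidromic stimulation."""

    outcome: InvasionOutcome
    peak_ais: float  # mV at AIS midpoint
    peak_soma: float  # mV
    node10_spike: bool
    trace: SimulationTrace | None = None


def antidromic(model: CableModel, state: SolverState | None = None,
               site: str = "node[15]", amp: float = 5.0, dur: float = 0.1,
               tstop: float = 30.0, keep_trace: bool = False) -> InvasionResult:
    """Stimulate a distal node and classify soma invasion.

    Default protocol: 5 nA for 0.1 ms at node[15].  Records the AIS
    midpoint, the soma, and nodes 1 and 10.
    """
    if site not in model.sites:
        raise ProtocolError(f"stimulation site {site} absent "
                            f"(model has {model.meta.get('n_nodes')} nodes)")
    if state is None:
        state = init_steady_state(model, t_settle=SETTLE_MS)
    proto = Protocol(
        stimuli=(Stimulus(site=site, delay=0.5, duration=dur, amplitude=amp),),
        record=("soma", "ais_mid", "node[1]", "node[10]"),
        tstop=tstop, dt=0.025)
    tr = run(model, proto, state=state)
    peak_ais = tr.peak("ais_mid")
    peak_soma = tr.peak("soma")
    ais_spike = (len(tr.spikes["ais_mid"]) > 0) and (peak_ais > AIS_SPIKE_PEAK)
    soma_spike = len(tr.spikes["soma"]) > 0
    if soma_spike:
        out = InvasionOutcome.SOMA_INVADED
    elif ais_spike:
        out = InvasionOutcome.AIS_ONLY
    else:
        out = InvasionOutcome.FAIL_AT_AIS
    return InvasionResult(
        outcome=out, peak_ais=peak_ais, peak_soma=peak_soma,
        node10_spike=len(tr.spikes["node[10]"]) > 0,
        trace=tr if keep_trace else None)


def spontaneous_flag(model: CableModel, t_check: float = 300.0,
                     v_sustained: float = -40.0,
                     sustain_ms: float = 50.0) -> bool:
    """True if the unstimulated model fires or sits depolarized.

    Runs ``t_check`` ms without stimuli from a uniform start and flags any
    somatic spike, or V > ``v_sustained`` sustained longer than
    ``sustain_ms``.
    """
    proto = Protocol(stimuli=(), record=("soma",), tstop=t_check, dt=0.025)
    state = SolverState(
        V=np.full(model.n, -70.0), Vp=np.zeros(model.n),
        gates=None, ca=None, t=0.0)
    # reuse init path for gates/ca, but keep the full trace: settle manually
    from .solver import _init_gates
    state.gates = _init_gates(model, state.V, model.ca_params["ca_min"])
    state.ca = np.full(len(model.ca_comps), model.ca_params["ca_min"])
    tr = run(model, proto, state=state)
    v = tr.V["soma"]
    if len(detect_spikes(tr.t, v)) > 0:
        return True
    above = v > v_sustained
    # longest run of consecutive samples above the level
    longest, cur = 0, 0
    for a in above:
        cur = cur + 1 if a else 0
        longest = max(longest, cur)
    return longest * tr.dt > sustain_ms


@dataclass
class SweepResult:
    """Grid sweep outcomes over (AIS diameter, g_Na) or somatic g_Na."""

    diameters: np.ndarray  # um (single entry for soma sweeps)
    g_values: np.ndarray  # S/cm^2
    outcomes: list  # [i_diam][j_g] -> InvasionOutcome
    minimal_pair: tuple | None  # (diameter um, g_Na S/cm^2) or None
    spontaneous: list = field(default_factory=list)  # [(diam, g)] flagged
    monotonicity_violations: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def outcome_at(self, diam: float, g: float) -> InvasionOutcome:
        i = int(np.argmin(np.abs(self.diameters - diam)))
        j = int(np.argmin(np.abs(self.g_values - g)))
        return self.outcomes[i][j]


def build_variant(morph: Morphology, membrane: RegionMembraneSpec,
                  efferent: EfferentSpec, *, soma_gna: float | None = None,
                  ais_gna: float | None = None,
                  ais_diameter: float | None = None) -> CableModel:
    """Build a model with swept AIS geometry / Na+ densities (S/cm^2)."""
    mem = membrane
    if soma_gna is not None:
        mem = mem.with_soma_gna(soma_gna * 1e3)  # S/cm^2 -> mS/cm^2
    if ais_gna is not None:
        mem = mem.with_ais_gna(ais_gna * 1e3)
    eff = efferent
    if ais_diameter is not None:
        from dataclasses import replace
        eff = replace(eff, ais_diameter=ais_diameter)
    return build_cell(morph, membrane=mem, efferent=eff)


def sweep_soma_gna(
    morph: Morphology,
    g_values,  # S/cm^2
    membrane: RegionMembraneSpec | None = None,
    efferent: EfferentSpec | None = None,
    check_spontaneous_above: float = 10.0,
) -> SweepResult:
    """Antidromic outcome for each somatic fast-Na+ density.

    Each density is applied to the soma (the dendritic gradient endpoints
    stay basal), the model is settled, and the standard antidromic protocol
    runs.  Densities above ``check_spontaneous_above`` S/cm^2 are also
    screened for spontaneous sustained depolarization during an
    unstimulated 300 ms window.
    """
    membrane = membrane or RegionMembraneSpec()
    efferent = efferent or EfferentSpec()
    g_values = np.asarray(list(g_values), dtype=float)
    outcomes = [[]]
    spont = []
    for g in g_values:
        model = build_variant(morph, membrane, efferent, soma_gna=g)
        if g > check_spontaneous_above and spontaneous_flag(model):
            spont.append((efferent.ais_diameter, float(g)))
            outcomes[0].append(InvasionOutcome.FAIL_AT_AIS)
            continue
        res = antidromic(model)
        outcomes[0].append(res.outcome)
    minimal = None
    for j, g in enumerate(g_values):
        if outcomes[0][j] == InvasionOutcome.SOMA_INVADED:
            minimal = (float(efferent.ais_diameter), float(g))
            break
    return SweepResult(
        diameters=np.array([efferent.ais_diameter]), g_values=g_values,
        outcomes=outcomes, minimal_pair=minimal, spontaneous=spont,
        meta={"swept": "soma_gna"})


def sweep_ais(
    morph: Morphology,
    diameters,  # um
    g_values,  # S/cm^2
    membrane: RegionMembraneSpec | None = None,
    efferent: EfferentSpec | None = None,
) -> SweepResult:
    """Full (AIS diameter x AIS g_Na) outcome matrix.

    The minimal invading pair is found by scanning g ascending within each
    diameter and keeping the smallest invading g across diameters (ties
    resolved toward the smaller diameter).  Monotonicity of the outcome in
    g at fixed diameter is checked and violations reported, not raised.
    """
    membrane = membrane or RegionMembraneSpec()
    efferent = efferent or EfferentSpec()
    diameters = np.asarray(list(diameters), dtype=float)
    g_values = np.asarray(list(g_values), dtype=float)
    order = np.argsort(g_values)
    outcomes = []
    violations = []
    minimal = None
    for d in diameters:
        row = [None] * len(g_values)
        for j in order:
            g = g_values[j]
            model = build_variant(morph, membrane, efferent,
                               ais_diameter=float(d), ais_gna=float(g))
            row[j] = antidromic(model).outcome
        outcomes.append(row)
        ranks = [row[j].rank for j in order]
        for a, b in zip(ranks, ranks[1:]):
            if b < a:
                violations.append((float(d), "non-monotone in g"))
                break
        for j in order:
            if row[j] == InvasionOutcome.SOMA_INVADED:
                if minimal is None or g_values[j] < minimal[1]:
                    minimal = (float(d), float(g_values[j]))
                break
    return SweepResult(
        diameters=diameters, g_values=g_values, outcomes=outcomes,
        minimal_pair=minimal, monotonicity_violations=violations,
        meta={"swept": "ais", "scan": "g ascending within each diameter"})
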