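"""Integrator correctness: conservation, analytic limits, convergence."""

import numpy as np
import pytest

from axosoma.builder import EfferentSpec, RegionMembraneSpec, build_cell
from axosoma.channels import load_channel_set, steady_state
from axosoma.morphology import Morphology, Section
from axosoma.solver import (
    NumericError, Protocol, SolverState, Stimulus, _init_gates, _Workspace,
    assemble_system, detect_spikes, init_steady_state, run, step,
)

from conftest import cable_morphology, passive_membrane
from axosoma.builder import assign_conductances


def passive_cable_model(length=1000.0, diam=2.0, nseg=101, leak=0.25):
    m = cable_morphology(length, diam, nseg)
    return assign_conductances(m, passive_membrane(leak), L_avg=length)


def soma_patch_model():
    """Isopotential somatic patch with the full somatic channel set."""
    soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                    [0, 25, 0, 50.]]),
                   parent=None, region="soma", nseg=2)
    m = Morphology(sections=[soma], soma_sections=[0])
    return assign_conductances(m, RegionMembraneSpec(), L_avg=1000.0)


class TestAssembleSystem:
    def test_two_compartment_offdiagonal(self):
        model = passive_cable_model(nseg=1)
        A = assemble_system(model).toarray()
        # soma comps 0-1 plus one dendrite comp
        g = model.g_axial_uS[2]
        assert A[2, 1] == pytest.approx(-g)
        assert A[1, 2] == pytest.approx(-g)

    def test_kirchhoff_row_sums_vanish(self, mini_cell):
        A = assemble_system(mini_cell)
        rs = np.abs(np.asarray(A.sum(axis=1))).max()
        assert rs < 1e-12

    def test_double_cable_adds_one_unknown_per_compartment(self, mini_cell):
        n_peri = int(mini_cell.has_peri.sum())
        n_myelin = sum(1 for r in mini_cell.region
                       if r in ("MYSA", "FLUT", "STIN"))
        assert n_peri == n_myelin > 0


class TestSteadyState:
    def test_passive_model_settles_to_leak_reversal(self):
        model = passive_cable_model()
        st = init_steady_state(model, t_settle=150.0)
        np.testing.assert_allclose(st.V, -72.0, atol=0.01)

    def test_full_model_is_settled(self, mini_cell):
        st = init_steady_state(mini_cell, t_settle=600.0)
        ws = _Workspace(mini_cell, 0.025, 0.5)
        before = st.V.copy()
        step(st, mini_cell, _ws=ws)
        rate = np.abs(st.V - before).max() / 0.025
        assert rate < 1e-4  # mV/ms

    def test_saved_state_persists_without_drift(self, mini_cell, mini_state):
        proto = Protocol(stimuli=(), record=("soma",), tstop=50.0)
        tr = run(mini_cell, proto, state=mini_state)
        drift = np.abs(tr.V["soma"] - tr.V["soma"][0]).max()
        assert drift < 0.01

    def test_cache_roundtrip(self, tmp_path):
        model = passive_cable_model(nseg=11)
        p = tmp_path / "steady.npz"
        st1 = init_steady_state(model, t_settle=50.0, cache_path=p)
        st2 = init_steady_state(model, t_settle=50.0, cache_path=p)
        np.testing.assert_array_equal(st1.V, st2.V)

    def test_invalid_settle_time(self, mini_cell):
        with pytest.raises(ValueError):
            init_steady_state(mini_cell, t_settle=0.0)


class TestStep:
    def test_pure_capacitor_ramps_linearly(self):
        model = passive_cable_model(nseg=1, leak=0.0)
        # isolate: zero out axial coupling so the dendrite comp is a capacitor
        model.g_axial_uS[:] = 0.0
        ws = _Workspace(model, 0.025, 0.5)
        st = SolverState(V=np.full(model.n, -70.0), Vp=np.zeros(model.n),
                         gates=_init_gates(model, np.full(model.n, -70.0),
                                           1e-4),
                         ca=np.full(len(model.ca_comps), 1e-4))
        comp = model.n - 1
        I = np.zeros(model.n)
        I[comp] = 0.5  # nA
        C = model.cm_nF[comp]
        for _ in range(200):
            step(st, model, stim_current=I, _ws=ws)
        want = -70.0 + 0.5 * 200 * 0.025 / C
        assert st.V[comp] == pytest.approx(want, rel=1e-9)

    def test_hh_patch_matches_reference_ode(self):
        """Somatic patch spike vs an independent adaptive-step integration."""
        from scipy.integrate import solve_ivp

        model = soma_patch_model()
        area = model.area_cm2.sum()
        chans = {pc.spec.name: pc for pc in model.channels}
        st0 = init_steady_state(model, t_settle=300.0)
        v0 = st0.V[0]
        I_stim = 60.0  # nA, constant for the whole window

        gate_specs = []
        x0 = [v0]
        for pc in model.channels:
            for g in pc.spec.gates:
                if g.ca_dependent:
                    continue
                gate_specs.append((pc, g))
                x0.append(float(st0.gates[(pc.spec.name, g.name)][0]))

        ca_fixed = float(st0.ca.mean()) if len(st0.ca) else 1e-4
        e_ca = 1e3 * 8.31446 * 309.15 / (2 * 96485.33) * np.log(2.0 / ca_fixed)
        z_fixed = ca_fixed / (ca_fixed + 2e-3)

        def rhs(t, x):
            V = x[0]
            I_ion = 0.0  # nA
            k = 1
            for pc, g in gate_specs:
                pass
            vals = {}
            k = 1
            for pc, g in gate_specs:
                vals[(pc.spec.name, g.name)] = x[k]
                k += 1
            for pc in model.channels:
                gtot = float(pc.gmax_uS.sum())
                open_frac = 1.0
                for g in pc.spec.gates:
                    if g.ca_dependent:
                        open_frac *= z_fixed ** g.p
                    else:
                        open_frac *= vals[(pc.spec.name, g.name)] ** g.p
                E = e_ca if pc.spec.dynamic_ca else float(pc.spec.reversal)
                I_ion += gtot * open_frac * (V - E)
            dV = (I_stim - I_ion) / model.cm_nF.sum()
            out = [dV]
            for pc, g in gate_specs:
                inf, tau = steady_state(g, V)
                out.append((float(inf) - vals[(pc.spec.name, g.name)])
                           / float(tau))
            return out

        sol = solve_ivp(rhs, (0.0, 20.0), x0, rtol=1e-9, atol=1e-9,
                        dense_output=True, max_step=0.05)

        # fix Ca (and hence E_Ca, KCa) to the resting values in both paths
        model2 = soma_patch_model()
        model2.ca_params["k"] = 0.0
        st = init_steady_state(model2, t_settle=300.0)
        ws = _Workspace(model2, 0.025, 0.5)
        I = np.zeros(model2.n)
        I[0] = I_stim
        errs = []
        for i in range(800):
            step(st, model2, stim_current=I, _ws=ws)
            ref = sol.sol((i + 1) * 0.025)[0]
            errs.append(abs(st.V[0] - ref))
        assert max(errs) < 0.5  # mV at dt = 0.025

    def test_crank_nicolson_second_order(self):
        """dt-refinement on a passive cable with smooth drive: error ~ dt^2."""
        def solve(dt):
            model = passive_cable_model(nseg=21)
            ws = _Workspace(model, dt, 0.5)
            st = SolverState(V=np.full(model.n, -72.0),
                             Vp=np.zeros(model.n),
                             gates=_init_gates(model,
                                               np.full(model.n, -72.0), 1e-4),
                             ca=np.full(len(model.ca_comps), 1e-4))
            I = np.zeros(model.n)
            site = model.n // 2
            n = int(round(4.0 / dt))
            for k in range(n):
                tmid = (k + 0.5) * dt
                I[site] = 2.0 * np.sin(2 * np.pi * tmid / 4.0)
                step(st, model, stim_current=I, _ws=ws)
            return st.V[site]

        ref = solve(0.003125)
        e1 = abs(solve(0.05) - ref)
        e2 = abs(solve(0.025) - ref)
        ratio = e1 / e2
        assert 3.0 < ratio < 5.0

    def test_divergence_guard_names_compartment(self):
        model = passive_cable_model(nseg=3)
        ws = _Workspace(model, 0.025, 0.5)
        st = SolverState(V=np.full(model.n, -70.0), Vp=np.zeros(model.n),
                         gates=_init_gates(model, np.full(model.n, -70.0),
                                           1e-4),
                         ca=np.full(len(model.ca_comps), 1e-4))
        I = np.zeros(model.n)
        I[-1] = 1e7
        with pytest.raises(NumericError, match="compartment"):
            for _ in range(10):
                step(st, model, stim_current=I, _ws=ws)

    def test_stable_at_4x_dt_on_full_model(self, mini_cell):
        st = init_steady_state(mini_cell, t_settle=20.0, dt=0.1)
        assert np.all(np.abs(st.V) < 150.0)


class TestRun:
    def test_no_stimulus_no_spikes(self, mini_cell, mini_state):
        proto = Protocol(stimuli=(), record=("soma", "ais_mid", "node[10]"),
                         tstop=30.0)
        tr = run(mini_cell, proto, state=mini_state)
        assert all(len(s) == 0 for s in tr.spikes.values())

    def test_bit_identical_reruns(self, mini_cell, mini_state):
        proto = Protocol(
            stimuli=(Stimulus(site="soma", delay=1.0, duration=0.5,
                              amplitude=80.0),),
            record=("soma",), tstop=20.0)
        a = run(mini_cell, proto, state=mini_state)
        b = run(mini_cell, proto, state=mini_state)
        assert np.array_equal(a.V["soma"], b.V["soma"])

    def test_detect_spikes_upward_crossings(self):
        t = np.arange(6.0)
        v = np.array([-70.0, 10.0, -70.0, -70.0, 5.0, -70.0])
        np.testing.assert_array_equal(detect_spikes(t, v), [1.0, 4.0])

    def test_passive_cable_profile_matches_cosh(self):
        """DC steady profile on a sealed finite cable vs analytic solution."""
        length, diam, leak = 1000.0, 2.0, 0.25
        model = passive_cable_model(length, diam, nseg=101, leak=leak)
        st = init_steady_state(model, t_settle=100.0)
        ws = _Workspace(model, 0.025, 0.5)
        I = np.zeros(model.n)
        first = next(i for i, r in enumerate(model.region) if r == "dendrite")
        I[first] = 0.05
        for _ in range(int(400 / 0.025)):
            step(st, model, stim_current=I, _ws=ws)
        nd = model.n - first
        x = (np.arange(nd) + 0.5) * (length / nd)
        v = st.V[first:] - (-72.0)
        Rm = 1.0 / (leak * 1e-3)  # Ohm cm2
        lam = np.sqrt((Rm / 70.0) * (diam * 1e-4 / 4.0)) * 1e4  # um
        ana = np.cosh((length - x) / lam) / np.cosh((length - x[0]) / lam)
        np.testing.assert_allclose(v / v[0], ana, rtol=0.01)

    def test_saltatory_conduction_uniform_internodal_delays(self, pool_cells,
                                                            pool_states):
        cell, st = pool_cells[0], pool_states[0]
        proto = Protocol(
            stimuli=(Stimulus(site="node[15]", delay=0.2, duration=0.1,
                              amplitude=5.0),),
            record=tuple(f"node[{k}]" for k in range(5, 14)),
            tstop=4.0, dt=0.005)
        tr = run(cell, proto, state=st)
        # skip the first two internodes after the stimulation site, where
        # the wavefront is still forming from the pulse transient
        arrivals = []
        for k in range(12, 4, -1):
            v = tr.V[f"node[{k}]"]
            idx = np.nonzero((v[:-1] < 0.0) & (v[1:] >= 0.0))[0]
            assert len(idx) >= 1, f"node {k} did not spike"
            i = idx[0]
            # sub-sample crossing time by linear interpolation
            frac = (0.0 - v[i]) / (v[i + 1] - v[i])
            arrivals.append(tr.t[i] + frac * proto.dt)
        delays = np.diff(arrivals)
        assert np.all(delays > 0)
        assert np.max(np.abs(delays - delays.mean())) <= 0.05 * delays.mean()
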