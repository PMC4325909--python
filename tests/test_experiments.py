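"""Protocols: rheobase, strength-duration, spike metrics, Z_IN, antidromic."""

import numpy as np
import pytest

from axosoma.builder import assign_conductances, RegionMembraneSpec, EfferentSpec
from axosoma.channels import ProtocolError
from axosoma.experiments import (
    InvasionOutcome, SearchError, antidromic, input_impedance, rheobase,
    spike_metrics, strength_duration, sweep_ais, sweep_soma_gna,
    trace_metrics, build_variant,
)
from axosoma.solver import init_steady_state

from conftest import cable_morphology, passive_membrane


@pytest.fixture(scope="module")
def passive_model():
    # thick cable: low input resistance keeps the passive response far from
    # the spike-detection threshold within the search bound
    model = assign_conductances(cable_morphology(500.0, 10.0, 26),
                                passive_membrane(4.0), L_avg=500.0)
    return model, init_steady_state(model, t_settle=100.0)


class TestRheobase:
    def test_passive_model_cannot_spike(self, passive_model):
        # the search bound keeps the passive response below the detection
        # threshold, so no amplitude can register a spike
        model, st = passive_model
        with pytest.raises(SearchError):
            rheobase(model, st, upper=8.0)

    def test_bisection_matches_grid_scan(self, mini_cell, mini_state):
        rb = rheobase(mini_cell, mini_state, tol=0.5)
        from axosoma.experiments import _evokes_spike
        # brute-force scan on a 0.5 nA grid around the bisection result
        lo = rb - 2.0
        grid = None
        for amp in np.arange(max(lo, 0.5), rb + 2.5, 0.5):
            if _evokes_spike(mini_cell, mini_state, amp, 1000.0,
                             max_ms=1000.0):
                grid = amp
                break
        assert grid is not None
        assert abs(rb - grid) <= 0.5

    def test_in_physiological_range(self, pool_cells, pool_states):
        rb = rheobase(pool_cells[0], pool_states[0], tol=0.5)
        assert 2.0 < rb < 60.0


class TestStrengthDuration:
    def test_monotone_and_consistent_with_rheobase(self, mini_cell,
                                                   mini_state):
        curve = strength_duration(mini_cell, [0.5, 2.0, 10.0, 200.0],
                                  state=mini_state, tol=0.5)
        vals = [curve[d] for d in (0.5, 2.0, 10.0, 200.0)]
        assert all(a >= b - 0.5 for a, b in zip(vals, vals[1:]))
        assert vals[0] > vals[2]
        rb = rheobase(mini_cell, mini_state, tol=0.5, max_duration=200.0)
        assert curve[200.0] == pytest.approx(rb, abs=1.0)


class TestSpikeMetrics:
    def test_artificial_trace_oracle(self):
        dt = 0.1
        t = np.arange(0.0, 60.0, dt)
        rest = -70.0
        v = np.full_like(t, rest)
        v[(t >= 2.0) & (t < 3.0)] = 20.0  # flat-top spike, peak at t=2
        ahp = (t >= 5.0) & (t < 45.0)
        v[ahp] = rest - 4.0  # flat AHP floor
        m = trace_metrics(t, v, onset=1.0, v_rest=rest)
        assert m["peak_amplitude"] == pytest.approx(20.0)
        assert m["peak_latency"] == pytest.approx(1.0)
        assert m["ahp_amplitude"] == pytest.approx(-4.0)
        assert m["ahp_latency"] == pytest.approx(4.0)
        assert m["ahp_duration"] == pytest.approx(40.0, abs=2 * dt)

    def test_full_cell_metrics(self, mini_cell, mini_state):
        m = spike_metrics(mini_cell, state=mini_state)
        assert m["ahp_amplitude"] <= 0.0
        assert m["peak_amplitude"] > -20.0
        assert m["suprathreshold_stimulus"] % 10.0 == 0.0
        assert m["peak_latency"] < 5.0

    def test_subthreshold_stimulus_rejected(self, mini_cell, mini_state):
        with pytest.raises(ProtocolError):
            spike_metrics(mini_cell, amplitude=0.1, state=mini_state)


class TestInputImpedance:
    def test_passive_dc_limit(self, passive_model):
        model, st = passive_model
        from axosoma.electrotonus import transfer_voltages
        r_dc = abs(transfer_voltages(model, st, "soma")[model.site("soma")])
        z = input_impedance(model, 0.5, amp=0.05, state=st)
        assert z == pytest.approx(r_dc, rel=0.02)

    def test_rc_patch_matches_analytic(self):
        import math
        from axosoma.morphology import Morphology, Section
        soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                        [0, 25, 0, 50.]]),
                       parent=None, region="soma", nseg=2)
        model = assign_conductances(
            Morphology(sections=[soma], soma_sections=[0]),
            passive_membrane(1.0), L_avg=100.0)
        st = init_steady_state(model, t_settle=50.0)
        area = model.area_cm2.sum()
        R = 1.0 / (1.0e-3 * area * 1e6)  # MOhm
        C = 1.0 * area * 1e3  # nF
        for f in (10.0, 100.0):
            want = R / math.sqrt(1.0 + (2e-3 * math.pi * f * R * C) ** 2)
            z = input_impedance(model, f, amp=0.5, state=st)
            assert z == pytest.approx(want, rel=0.02)

    def test_low_pass(self, mini_cell, mini_state):
        z_low = input_impedance(mini_cell, 0.1, state=mini_state)
        z_high = input_impedance(mini_cell, 100.0, state=mini_state)
        assert z_high < z_low


class TestAntidromic:
    def test_zero_amplitude_no_spikes(self, pool_cells, pool_states):
        res = antidromic(pool_cells[0], pool_states[0], amp=0.0)
        assert res.outcome == InvasionOutcome.FAIL_AT_AIS
        assert not res.node10_spike

    def test_basal_fails_with_conducting_axon(self, pool_cells, pool_states):
        res = antidromic(pool_cells[0], pool_states[0])
        assert res.outcome == InvasionOutcome.FAIL_AT_AIS
        assert res.node10_spike
        assert res.peak_soma < -50.0

    def test_missing_site_rejected(self, pool_cells, pool_states):
        with pytest.raises(ProtocolError):
            antidromic(pool_cells[0], pool_states[0], site="node[99]")

    def test_invaded_implies_ais_spike(self, pool_morphs):
        res = antidromic(build_variant(pool_morphs[0], RegionMembraneSpec(),
                                    EfferentSpec(), ais_diameter=2.5,
                                    ais_gna=4.0))
        assert res.outcome == InvasionOutcome.SOMA_INVADED
        assert res.peak_ais > 10.0


class TestSweeps:
    def test_singleton_grid_matches_antidromic(self, pool_morphs):
        sw = sweep_ais(pool_morphs[0], diameters=[3.0], g_values=[0.3])
        assert sw.outcomes[0][0] == InvasionOutcome.FAIL_AT_AIS
        assert sw.minimal_pair is None

    def test_basal_soma_density_reproduces_baseline(self, pool_morphs):
        sw = sweep_soma_gna(pool_morphs[0], g_values=[0.015])
        assert sw.outcomes[0][0] == InvasionOutcome.FAIL_AT_AIS
        assert sw.spontaneous == []

    def test_minimal_pair_scanning(self, pool_morphs):
        sw = sweep_ais(pool_morphs[0], diameters=[2.0, 2.5],
                       g_values=[0.3, 4.0])
        assert sw.minimal_pair == (2.5, 4.0)
        assert sw.outcome_at(2.0, 0.3) == InvasionOutcome.AIS_ONLY
        assert sw.monotonicity_violations == []

    def test_larger_trees_need_more_ais_sodium(self):
        """Dendritic load ranks the minimal invading AIS density."""
        from axosoma.morphology import resegment
        from axosoma.synth import SynthMorphParams, generate
        surfaces = [140_000.0, 260_000.0]
        minima = []
        for k, surf in enumerate(surfaces):
            p = SynthMorphParams(seed=31 + k, soma_diameter=70.0,
                                 n_primary=10, target_dendrite_surface=surf,
                                 mean_terminal_distance=700.0)
            morph = resegment(generate(p))
            sw = sweep_ais(morph, diameters=[2.5], g_values=[4.0, 8.0])
            minima.append(sw.minimal_pair[1] if sw.minimal_pair
                          else float("inf"))
        assert np.isfinite(minima[0])
        assert minima[0] <= minima[1]
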