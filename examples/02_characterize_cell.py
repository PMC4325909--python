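"""Build a full model cell and measure its basal electrophysiology.

Assembles morphology + hillock + AIS + 23 mm myelinated axon with the basal
conductance tables, settles it for 300 ms, and prints resting potential,
rheobase (1 s somatic steps, bisection), single-spike/AHP metrics from a
0.5 ms suprathreshold pulse, and the somatic input impedance at 0.1 and
100 Hz.  A smaller-than-average cell is used to keep this quick (~2 min).
"""

from axosoma import (SynthMorphParams, build_cell, generate, init_steady_state,
                     input_impedance, resegment, rheobase, spike_metrics)

params = SynthMorphParams(seed=7, soma_diameter=55.0, n_primary=9,
                          target_dendrite_surface=140_000.0,
                          mean_terminal_distance=520.0)
cell = build_cell(resegment(generate(params)))
print(f"model: {cell.n} compartments, hash {cell.model_hash()}")

state = init_steady_state(cell)  # 300 ms unperturbed settling
print(f"resting potential   {state.V[cell.site('soma')]:8.2f} mV")

rb = rheobase(cell, state)
print(f"rheobase            {rb:8.2f} nA  (1 s somatic step)")

m = spike_metrics(cell, state=state)
print(f"suprathreshold stim {m['suprathreshold_stimulus']:8.1f} nA (0.5 ms)")
print(f"spike peak          {m['peak_amplitude']:8.2f} mV at "
      f"{m['peak_latency']:.2f} ms")
print(f"AHP                 {m['ahp_amplitude']:8.2f} mV at "
      f"{m['ahp_latency']:.1f} ms, below rest for "
      f"{m['ahp_duration']:.0f} ms")

z_lo = input_impedance(cell, 0.1, state=state)
z_hi = input_impedance(cell, 100.0, state=state)
print(f"Z_in  0.1 Hz        {z_lo:8.3f} MOhm")
print(f"Z_in  100 Hz        {z_hi:8.3f} MOhm")
print("\nLarge motoneurons pair low input impedance with high rheobase; "
      "the AHP (Ca-activated K+) sets the minimum firing interval.")
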