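"""Stimulate a distal node of Ranvier and watch the spike fail at the AIS.

With basal parameters a 5 nA / 0.1 ms pulse at node[15] (17.25 mm from the
soma) launches a regularly conducted antidromic spike that dies at the
myelinated-axon-to-AIS transition: the soma barely moves.  Thinning the AIS
to 2 um rescues the AIS spike (the classical NM spike: the soma still sees
only a subthreshold bump), and raising the AIS fast-Na+ density on top of
that lets the spike invade the soma.
"""

from axosoma import (EfferentSpec, RegionMembraneSpec, SynthMorphParams,
                     antidromic, generate, resegment)
from axosoma.experiments import build_variant

params = SynthMorphParams(seed=7, soma_diameter=55.0, n_primary=9,
                          target_dendrite_surface=140_000.0,
                          mean_terminal_distance=520.0)
morph = resegment(generate(params))
mem, eff = RegionMembraneSpec(), EfferentSpec()

print(f"{'AIS diam':>9s} {'AIS g_Na':>9s} {'outcome':>14s} "
      f"{'peak AIS':>9s} {'peak soma':>10s} {'node10?':>8s}")
for d, g in [(3.0, None), (2.0, None), (2.5, 4.0)]:
    cell = build_variant(morph, mem, eff, ais_diameter=d, ais_gna=g)
    res = antidromic(cell)  # settles 300 ms, then 5 nA / 0.1 ms at node[15]
    print(f"{d:9.1f} {(g if g else 0.3):9.1f} {res.outcome.value:>14s} "
          f"{res.peak_ais:9.1f} {res.peak_soma:10.1f} "
          f"{str(res.node10_spike):>8s}")

print("\nVoltages in mV; g_Na in S/cm2 (basal 0.3). The three rows show the "
      "three regimes: conduction failure before the AIS, an AIS-only (NM) "
      "spike, and full somatic invasion once the AIS carries ~10-20x the "
      "basal Na+ density.")
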