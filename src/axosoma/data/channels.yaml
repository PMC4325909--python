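# Channel kinetics, version 1.
#
# Rates are 1/ms, potentials mV, time constants ms, densities mS/cm^2, at
# 36 C (temperature factors folded into the constants; no runtime scaling).
#
# Somato-dendritic / initial-segment set: motoneuron-style transient Na+,
# persistent Na+, delayed-rectifier K+, Ca-activated K+, high- and
# low-threshold Ca2+ and H conductances in inf/tau form.  The fast Na+
# gates carry a -5 mV shift and the persistent Na+ activation a +15 mV
# shift (applied by evaluating the base curves at V - shift); with the
# soma densities (g_Naf 15, g_Nap 2) these kinetics put the persistent
# plateau near 20% of the peak transient current.
#
# Nodal set: MRG-style fast Na+ (m3h), persistent Na+ (p3) and slow K+ (s)
# in alpha/beta form, supporting saltatory conduction in the double-cable
# myelinated axon.
#
# gmax values below are the basal *soma* or *node* densities; the model
# builder overrides gmax per region and per compartment.
version: 1
channels:
  na_fast:
    gmax: 15.0
    reversal: 50.0
    gates:
      - name: m
        p: 3
        shift: -5.0
        inf: {kind: boltzmann, vhalf: -41.5, k: 5.5}
        tau: {kind: bell, base: 0.05, amp: 0.12, vhalf: -41.5, width: 15.0}
      - name: h
        p: 1
        shift: -5.0
        inf: {kind: boltzmann, vhalf: -53.0, k: -5.0}
        tau: {kind: bell, base: 0.49, amp: 1.8, vhalf: -50.0, width: 16.0}
  na_persistent:
    gmax: 2.0
    reversal: 50.0
    gates:
      - name: p
        p: 1
        shift: 15.0
        inf: {kind: boltzmann, vhalf: -47.0, k: 3.1}
        tau: {kind: bell, base: 1.0, amp: 3.0, vhalf: -40.0, width: 12.0}
  k_dr:
    gmax: 35.0
    reversal: -77.0
    gates:
      - name: n
        p: 4
        inf: {kind: boltzmann, vhalf: -28.0, k: 15.0}
        tau: {kind: bell, base: 0.8, amp: 4.0, vhalf: -40.0, width: 30.0}
  k_ca:
    gmax: 10.0
    reversal: -77.0
    gates:
      - name: z
        p: 1
        inf: {kind: ca_michaelis, kd: 2.0e-3}
        tau: {kind: constant, A: 2.0}
  ca_ht:
    gmax: 0.008
    reversal: dynamic-Ca
    gates:
      - name: m
        p: 2
        inf: {kind: boltzmann, vhalf: -20.0, k: 6.0}
        tau: {kind: constant, A: 3.0}
  ca_lt:
    gmax: 0.28
    reversal: dynamic-Ca
    gates:
      - name: m
        p: 1
        inf: {kind: boltzmann, vhalf: -35.0, k: 5.0}
        tau: {kind: constant, A: 40.0}
  h_cn:
    gmax: 0.1325
    reversal: -43.0
    gates:
      - name: r
        p: 1
        inf: {kind: boltzmann, vhalf: -80.0, k: -6.0}
        tau: {kind: constant, A: 30.0}
  leak:
    gmax: 4.4
    reversal: -72.0
    gates: []
  na_fast_node:
    gmax: 880.0
    reversal: 50.0
    gates:
      - name: m
        p: 3
        alpha: {kind: exp_linear, A: 6.57, vhalf: -20.4, k: 10.3}
        beta: {kind: exp_linear, A: -0.304, vhalf: -25.7, k: -9.16}
      - name: h
        p: 1
        alpha: {kind: exp_linear, A: -0.34, vhalf: -114.0, k: -11.0}
        beta: {kind: sigmoid, A: 12.6, vhalf: -31.8, k: 13.4}
  na_persistent_node:
    gmax: 4.4
    reversal: 50.0
    gates:
      - name: p
        p: 3
        alpha: {kind: exp_linear, A: 0.0353, vhalf: -27.0, k: 10.2}
        beta: {kind: exp_linear, A: -0.000883, vhalf: -34.0, k: -10.0}
  k_slow_node:
    gmax: 400.0
    reversal: -77.0
    gates:
      - name: s
        p: 1
        alpha: {kind: sigmoid, A: 0.3, vhalf: -53.0, k: 5.0}
        beta: {kind: sigmoid, A: 0.03, vhalf: -90.0, k: 1.0}
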