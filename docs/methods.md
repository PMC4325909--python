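# Methods

## The model

`axosoma` builds conductance-based compartmental models of adult cat spinal
alpha motoneurons and uses them to study why antidromic action potentials
— spikes evoked in the distal motor axon and travelling back toward the
cell body — often fail to invade the soma. Each model cell has four parts:

1. **Soma and dendrites.** A 3D reconstructed morphology (standard SWC) or
   a synthetic tree from the built-in generator. Spherical somata encoded
   as a single SWC sample are expanded to the standard two-cylinder
   convention (two cylinders of diameter *d* and length *d*/2, surface
   πd²). Dendritic branches longer than 20 µm are subdivided so no
   compartment exceeds 20 µm; the AC length-constant (d_lambda) rule is
   available as a check on the resulting grid.
2. **Axon hillock.** A 25 µm frustum in 7 compartments whose diameter
   interpolates linearly from the soma to the AIS value.
3. **Axon initial segment (AIS).** A 450 µm unmyelinated cylinder in nine
   50 µm compartments, default diameter 3 µm; both diameter and fast-Na⁺
   density are sweepable.
4. **Myelinated axon.** Twenty internodes of the double-cable
   (MRG-style) motor-fiber geometry: per internode one 1 µm node of
   Ranvier (3.3 µm diameter), two 3 µm paranodal myelin attachment
   segments (MYSA, 3.6 µm), two 46 µm juxtaparanodal segments (FLUT,
   6.9 µm) and six ~175.2 µm internodal sub-segments (STIN, 6.9 µm),
   tiling a 1.150 mm node-to-node separation (the STIN pieces absorb the
   sub-micron rounding). Node-to-node separation is counted
   center-to-center, so node[k] is reported at k × 1.150 mm from the soma
   (the true path adds the 0.475 mm hillock + AIS). The first MYSA
   attaches directly to the distal AIS end, with no intervening node.
   Internodal compartments are double-cable: the axolemma (2 µF/cm²,
   passive leak) faces a resistive periaxonal space, which is separated
   from the grounded bath by the myelin sheath. With N = 120 lamellae
   (two membranes each in series) the effective sheath has
   0.1/(2N) µF/cm² and 1/(2N) mS/cm². Periaxonal axial resistances come
   from the annulus formula ρL/π((d/2+w)² − (d/2)²) with widths of
   0.002 µm (MYSA) and 0.004 µm (FLUT/STIN) and ρ = 70 Ω·cm; the layer
   opens into the bath at each node. Nodes themselves are single-cable.

Passive parameters: 1 µF/cm² everywhere except myelin (above) and
nodal/internodal axolemma (2 µF/cm²); axial and periaxonal resistivity
70 Ω·cm; E_Na = +50 mV, E_K = −77 mV, E_leak = −72 mV; Ca²⁺ reversal from
the Nernst equation at 36 °C as the intracellular pool fills.

### Membrane mechanisms

Conductance densities follow the model's basal tables: the soma carries
fast Na⁺ (15 mS/cm²), delayed-rectifier K⁺ (35), persistent Na⁺ (2),
Ca²⁺-activated K⁺ (10), high-threshold Ca²⁺ (0.008), H (0.1325) and leak
(4.4). Along the proximal dendrites — out to 10% of the cell's mean
terminal path distance — every density falls linearly to its distal value
(0.15 / 0.3 / 0.015 / 0 / 0 / 0.072), except H, which is uniform.
Dendritic compartments between 30% and 60% of the mean terminal distance
additionally carry a low-threshold Ca²⁺ conductance (0.28 mS/cm²) — the
dendritic persistent inward current — and extra Ca²⁺-activated K⁺ (0.16).
The hillock cross-fades linearly from the somatic set (15/35/2/4.4) to the
AIS set (300/400/10/4.4); the AIS is uniform. Nodes carry MRG-style fast
Na⁺, slow K⁺ (400 mS/cm²), persistent Na⁺ (4.4) and leak (1); paranodal
and internodal axolemma is passive (1 / 0.1 / 0.1 mS/cm² leak).

**Nodal fast-Na⁺ density.** The nodal density defaults to 3.0 S/cm², the
value of the source myelinated-fiber model. A tabulated alternative of
0.88 S/cm² puts the total nodal Na⁺ conductance (~0.09 µS) at par with the
internodal axial drain (~0.09 µS), a relay safety factor of ~1 at which
saltatory conduction fails for any gating kinetics we tested; 3.0 S/cm²
restores full nodal spikes, the attenuated spike at node[1], and the basal
failure at the AIS. The density is a per-region config value.

### Channel kinetics

All gates follow the Hodgkin–Huxley formalism; every rate function is a
parametric expression stored in the versioned data file
`src/axosoma/data/channels.yaml`, so the full kinetic scheme is auditable
and swappable. Temperature is fixed at 36 °C with any temperature factors
folded into the stored constants. Somato-dendritic/AIS kinetics are
motoneuron-style inf/tau forms; nodal kinetics are MRG-style α/β forms.
The fast Na⁺ gates carry a −5 mV shift and the persistent Na⁺ activation a
+15 mV shift, applied by evaluating the unshifted curves at V − Δ.

Because the exact source rate equations are not published alongside the
tables, the free kinetic constants were calibrated against the model's
stated behavioral anchors, in this order of priority:

- **Persistent/transient ratio.** With the somatic densities (g_Naf 15,
  g_Nap 2 mS/cm²), a voltage step from rest to the potential maximizing
  the transient peak must leave a persistent plateau of ~20% of that peak.
  This pins the somatic fast-Na⁺ activation midpoint near −48 mV
  (effective) — much further left and the maximizing step slides to
  potentials where the +15 mV-shifted persistent conductance has not
  activated, collapsing the ratio.
- **Stability of the swept AIS.** The AIS must rest stably at up to
  ~4 S/cm² fast Na⁺. This bounds the steady-state window current
  (m∞³h∞): the inactivation slope is steepened to k = 5 mV, without which
  a window-current plateau near −30 mV latches the AIS after any spike.
- **Basal conduction and invasion structure** (below).

The calibrated ratio is 20.1%. The Ca²⁺ pool is first-order: influx
proportional to the Ca²⁺ current (gain 4.0 mM·cm²·mA⁻¹·ms⁻¹, an effective
~0.013 µm submembrane shell), decay to a 0.1 µM floor with τ = 35 ms,
external Ca²⁺ 2 mM. With the sparse high-threshold Ca²⁺ density this
yields a somatic AHP of a few mV peaking ~15 ms after the spike and
lasting on the order of 100 ms.

### Numerics

The cable equations are integrated with a theta-method (Crank–Nicolson,
θ = 0.5; backward Euler available) at the working step of 0.025 ms, with
staggered updates: gating variables advance by their exact exponential
solution at the current voltage (unconditionally bounded in [0, 1] for any
step size), Ca²⁺ pools by an implicit first-order step, and the voltages
by one exact direct solve. Ordering each compartment's intracellular and
periaxonal potentials as a 2×2 block makes the full matrix
block-tridiagonal along every branch, so a two-pass block elimination
(children before parents) solves it with zero fill-in; the kernel is
JIT-compiled. The solve is exact and deterministic — identical inputs give
bit-identical traces. A divergence guard aborts any run where |V| exceeds
150 mV. Verified properties: passive sealed-cable profiles match the
analytic cosh solution to <1%, dt-refinement shows the expected
second-order error decay, the assembled axial graph conserves current to
<1e-12, and a somatic patch matches an independent adaptive-step reference
integration to <0.5 mV at dt = 0.025 ms.

Every simulation starts from a 300 ms unperturbed settling run (cacheable,
keyed by a model hash). Spike detection is an upward crossing of 0 mV; an
AIS spike additionally requires a peak above +10 mV to exclude large
passive depolarizations.

## Protocols

- **Rheobase**: bisection (0.1 nA default tolerance) on the amplitude of a
  1 s somatic step; runs stop early once a spike is seen or the membrane
  has settled under constant drive. **Strength–duration**: the same
  search per duration. **Spike/AHP metrics**: a 0.5 ms somatic pulse at
  the smallest 10 nA multiple evoking exactly one spike; peak latency and
  amplitude, AHP amplitude (min V − rest), latency, and time below rest.
  **Input impedance**: small somatic sinusoid, first cycle discarded,
  peak-to-peak V over peak-to-peak I; at very low frequencies the
  (subthreshold, passive) response is integrated with a proportionally
  wider step.
- **Antidromic stimulation**: 5 nA / 0.1 ms at node[15]; outcomes
  classified as FAIL_AT_AIS, AIS_ONLY (the classical NM spike) or
  SOMA_INVADED from the AIS-midpoint and somatic traces, with node[1] and
  node[10] recorded.
- **Sweeps**: outcome matrices over AIS diameter × AIS g_Na, or somatic
  g_Na; within each diameter, densities are scanned ascending and the
  minimal invading pair kept (ties toward smaller diameter). Outcome
  monotonicity in g is checked and violations reported, not raised.
  Somatic densities above 10 S/cm² are additionally screened for
  spontaneous sustained depolarization (any spike, or V > −40 mV for
  >50 ms, during an unstimulated 300 ms run).
- **Electrotonus**: the model is linearized at rest (gates frozen, chord
  conductances) and steady (or phasor) transfer solved directly;
  X = ln(V0/Vx) between sites, effective λ = distance/X per direction.
  Default endpoints are the soma and the *proximal* AIS compartment:
  with the AIS leak of 4.4 mS/cm² the 450 µm AIS spans ~3 DC length
  constants, so a midpoint measurement would be dominated by the AIS's own
  cable decay in both directions and mask the junctional asymmetry that
  the proximal endpoint exposes (forward X ≈ 0.18, backward ≈ 1.5–1.7,
  backward λ ≈ 40–45 µm, asymmetry ratio ≈ 8–9 on synthetic pools).

## The synthetic morphology generator

The generator emulates the morphometrics of the 14 imported cat lumbar
motoneuron reconstructions: soma diameter 50–120 µm, 8–16 primary
dendrites, dendritic surface 1.4–8×10⁵ µm², mean terminal path distance
450–1180 µm. Growth is recursive: exponential segment lengths (mean
80 µm), branching with probability 0.004/µm, child diameters from a
Rall-type power rule (exponent 1.5) with ±20% noise, linear taper, and a
per-trunk terminal path-distance budget (±15% jitter); diameters floor at
0.5 µm but growth continues to the budget, so terminal distances track
their target. A final global diameter rescale of the dendrites (topology
preserved) hits the surface target exactly. Pool generation jitters the
targets by a uniform ±fraction per cell. Everything derives from one
integer seed; no global random state is touched.

What the generator does *not* emulate: real dendrograms' diameter
profiles, 3D space-filling, spines, or the correlation structure between
morphometric quantities across real cells. Passing tests on synthetic
pools therefore demonstrate the mechanism (geometry- and density-dependent
invasion failure and rescue) rather than per-cell quantitative agreement
with any particular reconstruction.

## Study design reproduced on synthetic pools

With basal parameters, the antidromic spike conducts saltatorially
(uniform internodal delays to within a few percent), already attenuates at
node[1], and dies at the myelinated-axon→AIS transition: no AIS or
somatic spike, in every pool cell. Reducing the AIS diameter to ~2 µm
rescues the AIS spike through a sealed-end effect but the soma still sees
only a few-mV bump (AIS_ONLY). Raising the AIS fast-Na⁺ density rescues
full invasion: on a 5-cell pool at the small end of the observed
morphometric ranges the minimal invading density is 4–5 S/cm² at 2.5 µm
diameter, i.e. ~13–17× basal (the 20-fold increase at the basal 3 µm
geometry also invades). Somatic density increases never rescue invasion
(tested to 10 S/cm²) because the failing wave delivers almost no somatic
depolarization for the extra conductance to amplify.

Two quantitative differences from the study conditions are documented
rather than tuned away. First, the minimal invading pairs sit at slightly
larger diameter/density than the reported per-cell values — the somatic
takeoff voltage in this implementation is ~−52 mV, bounded below by the
persistent-fraction calibration above. Second, the somatic
spontaneous-depolarization boundary sits near 20–25 S/cm² rather than
just above 10: destabilizing the somatic rest at 10–12 S/cm² requires a
resting Na⁺ window that is incompatible with the AIS resting stably at
its swept densities, given that both regions share the same fast-Na⁺
channel and rest within a millivolt of each other. The corresponding
acceptance check is left failing by design.

## Known limitations

- Channel kinetics are authored, calibrated to the stated behavioral
  anchors; per-cell agreement with the reported basal tables
  (rheobase, spike shape, AHP depth) is approximate.
- No synaptic input, repetitive-stimulation protocols, recurrent (Renshaw)
  circuitry, extracellular stimulation, or Na⁺ channel subtype
  segregation along the AIS.
- The two-cylinder soma and center-attachment of dendrites make the soma
  effectively isopotential; fine peri-somatic geometry is not represented.
- Electrotonic measurements depend on the chosen endpoints (recorded in
  every report); midpoint-based values differ systematically, as
  discussed above.
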