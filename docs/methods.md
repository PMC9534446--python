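# Model and methods

## The biophysical model

Each compartment of a branched passive dendrite obeys the current-balance
equation

    Cm dVm/dt = −g_pas (Vm − Vrest) − Isyn + Iaxial + Iext ,

with axial currents given by Ohm's law between adjacent compartment
centres.  There are no active conductances: the model isolates how passive
cable structure and chloride homeostasis shape the efficacy of GABAergic
inhibition.  Synaptic current is ohmic, Isyn = g(t)·(Vm − Esyn), with the
GABA_A current split into its chloride and bicarbonate components

    ICl   = χ·g·(Vm − ECl),      IHCO3 = (1−χ)·g·(Vm − EHCO3),
    χ     = (EHCO3 − EGABA)/(EHCO3 − ECl),

so that ICl + IHCO3 = g·(Vm − EGABA) identically.  ECl is the Nernst
potential of the chloride pools and EGABA the two-anion
Goldman–Hodgkin–Katz potential with a 4:1 Cl⁻:HCO₃⁻ permeability ratio.
Intracellular chloride evolves per compartment as

    d[Cl⁻]i/dt = ICl/(F·Vol) − (area/(F·Vol))·P_KCC2·([K⁺]i[Cl⁻]i − [K⁺]o[Cl⁻]o)
                 + axial diffusion,

i.e. synaptic influx (an outward-positive anion current loads the
compartment), KCC2 extrusion that vanishes at the cotransporter equilibrium
[K⁺]i[Cl⁻]i = [K⁺]o[Cl⁻]o, and conservative second-difference diffusion
along the tree.  Extracellular chloride, both bicarbonate pools and both
potassium pools are clamped; only [Cl⁻]i, and hence ECl and EGABA, is
dynamic.

## Units and default parameters

All code uses one coherent unit system: μm, ms, mV, nA, μS, nF, MΩ, mM,
μm³.  Defaults (configurable everywhere):

| parameter | value | meaning |
|---|---|---|
| r | 0.5 μm | branch radius |
| Rm | 20 kΩ·cm² | membrane resistivity (τm = Rm·Cm = 20 ms) |
| Ra | 100 Ω·cm | axial resistivity |
| Cm | 1 μF/cm² | specific capacitance |
| Vrest | −65 mV | resting / leak reversal potential |
| L | λ = √(r·Rm/2Ra) ≈ 707 μm | branch length (1.0 X) |
| junction | 0.01 μm long, child diameter | electrically negligible coupling compartment |
| ⟨g⟩ | 0.001 μS | gclamp mean GABA_A conductance |
| σ_g | 0.1·⟨g⟩ | gclamp stationary standard deviation |
| τ_g | 10 ms | gclamp correlation time (see below) |
| Iext | 0.001 nA | excitatory probe current |
| [Cl⁻]i(0) / [Cl⁻]o | 7.25 / 135 mM | ECl = −78.2 mV |
| [HCO₃⁻]i / [HCO₃⁻]o | 12 / 23 mM | EHCO3 = −17.4 mV (fixed) |
| P_Cl : P_HCO3 | 0.8 : 0.2 | EGABA(0) = −70 mV |
| [K⁺]i | 140 mM | KCC2 set point (with [K⁺]o below) |
| [K⁺]o | [K⁺]i·[Cl⁻]i(0)/[Cl⁻]o ≈ 7.519 mM | makes the initial state an exact pump equilibrium |
| P_KCC2 | 1.9297·10⁻⁵ mA·mM⁻²·cm⁻² | extrusion strength |
| D_Cl | 2.03 μm²/ms | chloride diffusion coefficient |
| dt / dx | 0.025 ms / 0.01 X | integration steps |

Two parameter conventions matter enough to state explicitly.  First, the
membrane and axial resistivities are interpreted as 20 kΩ·cm² and
100 Ω·cm; these give τm = 20 ms and λ = 707 μm for a 0.5 μm radius, the
only combination consistent with both the stated branch length and the
observed ~150 ms settling of the IL (a 20 s membrane time constant would
contradict both).  Second, [K⁺]o is derived from the KCC2 equilibrium
condition at the initial chloride rather than fixed independently — any
other value would make the resting state drift with no input.

## Numerics

Voltage uses backward Euler with all conductances implicit.  The
tree-structured symmetric system is solved exactly in O(N) per step by
leaf-to-root elimination and back-substitution on a Hines-ordered
compartment list (parent index < child index); the same kernel is reused
for all steady-state (t → ∞, capacitance dropped) solves in the passive
analytics.  The solver is unconditionally stable for the passive system and
is verified against dense linear solves on random trees to 10⁻¹⁰ relative.

Chloride advances by operator splitting after each voltage step: synaptic
influx is explicit (using the just-computed voltage), while diffusion and
the (linear-in-Cl) KCC2 term are implicit in the same tree solve.  Implicit
diffusion is not optional: the 0.01 μm junction compartment has a ~10⁻²
μm³ volume and makes any explicit scheme unstable at dt = 0.025 ms.
Diffusive couplings between compartments are built like axial conductances,
from the series resistance of the two half-compartments, which makes the
scheme conservative (total Cl⁻ amount drifts < 10⁻¹⁰ relative over 10³
steps) and monotone (no new concentration extrema under pure diffusion).
The reversal potentials used by the voltage step lag chloride by one step;
halving dt or dx changes reported ILs by < 1%.

The fluctuating synaptic conductance ("gclamp") is an exact-discretisation
Ornstein–Uhlenbeck process with mean ⟨g⟩, stationary sd 0.1·⟨g⟩, clipped at
zero.  Its correlation time is not constrained by the phenomena modelled
(the IL integrates voltage over 5–50 ms windows), so a conventional 10 ms
is used; with sd = 0 the process degenerates to a constant conductance,
which is the deterministic mode used for argmax-type scans and most tests.
Stochastic protocols average the IL over ≥ 5 seeds, with paired runs (the
no-inhibition run has no stochastic elements).

## The IL protocol

IL is always computed from two runs sharing the excitatory probe and solver
settings.  The probe sits at the readout location d; IL_0 therefore means
"probe and readout at the junction".  Voltage-deflection integrals use each
compartment's V(t=0) as baseline (identical to Vrest here, since all
protocols start from rest), a backward window of 5 ms for time-resolved
traces and evaluation at 150 ms by default, by which time the passive
membrane (τm = 20 ms) has settled (the suite verifies IL(150 ms) is within
2% of IL(500 ms)).  For shunting synapses IL ∈ [0, 1); for hyperpolarising
synapses the IPSP term can exceed the probe deflection (the probe is only
1 pA), so IL is *not* bounded by 1, and focal chloride loading can drive it
negative — both are properties of the metric, not artefacts.

AccIdx = IL_0/IL_{d=i}.  When branches carry unequal synapse counts (an
occupancy sweep off a multiple of 100%), IL_{d=i} is read on a branch with
the maximal per-branch count, and the argmax over occupancy prefers the
smaller occupancy within a 10⁻³ relative tie band, since complete
occupancies tie to numerical precision for hyperpolarising synapses.

## Synapse distributions and scans

*Tree*: one synapse per branch at a common X = i (wrapping around branches
when there are more synapses than branches).  *Focal*: all synapses in one
compartment.  *Branch*: n synapses at k/(n+1) X, k = 1..n, on one branch,
rigidly shifted by the scanned anchor i — the even-spacing pattern is the
natural reading of "evenly spaced along a single branch", and scanning a
rigid offset keeps the pattern comparable across i.  Placement scans use a
0.01 X grid near the junction (needed to separate optima at 0.05 vs
0.07 X) and 0.05 X beyond 0.2 X.  Synapse and probe coordinates snap to the
nearest compartment centre, resolving exact grid-boundary ties toward the
junction; X = 0 addresses the junction compartment itself.

## What the generator emulates — and what it does not

The star-tree generator reproduces the study conditions exactly: identical
sealed cylindrical branches of one space constant joined at a tiny
junction, optionally with one synapse-free parent branch ("chloride sink")
of configurable diameter, fixed or λ-preserving length.  It does not model
tapering, spines, reconstructed morphologies, active conductances,
electrodiffusion, or transmitter-gated (two-state kinetic) GABA_A channels
— the binding constants α_GABA, β_GABA are carried in `SynapseSpec` for
completeness but the persistent gclamp conductance bypasses gating.
Conclusions validated here therefore speak to passive, frequency-
independent inhibition on idealised trees; on real morphologies the
*positions* of optima will shift with local surface-to-volume ratios and
branch asymmetries even though the trade-off (accumulation at junctions vs
pooled chloride loading) is generic.

## Problem sizes

Default grids put 100 compartments on each branch (401 compartments for
the 4-branch tree, 1601 for 16 branches).  The test suite and the
acceptance script run the full study protocols — 150 ms static sweeps,
500 ms placement scans on 0.01 X grids, 1000 ms chloride time courses — at
the default dt and dx; deterministic (sd = 0) gclamp mode is used for all
argmax-type scans, which reproduces the seed-averaged optima of the
stochastic mode, and five seeds are used where a stochastic quantity itself
is reported.

## Known limitations

- The 2 μm-sink placement optimum is grid-fragile: the IL(i) landscape is
  flat to ~1% between the junction and 0.02 X, and this implementation
  resolves the argmax at 0.02 X rather than exactly 0.00 X.  The direction
  and size of the sink effect (0.07 X → ≈0 X as the sink widens) are
  robust.
- Static-chloride runs hold EGABA at its initial value rather than
  modelling slow homeostasis; dynamic runs clamp all pools except [Cl⁻]i.
- The semi-analytic and analytic IL routes are steady-state constructs;
  only the numerical IL is meaningful for time-varying questions.
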