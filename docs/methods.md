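# Methods

## The model

`periax` implements a multi-compartment CA1 pyramidal neuron — a cylindrical
soma (15 × 10 µm), five 20 µm dendritic branches, a 50 µm axon initial
segment (AIS), and a myelinated axon with 21 nodes of Ranvier spaced 100 µm
apart — driven extracellularly by a biphasic 100 Hz pulse train, with
explicit potassium dynamics in the peri-axonal space under the myelin.
Each internodal stretch is the anatomical repeat PNJ–JXP–IND–JXP–PNJ
(paranodal junction 3 µm, juxtaparanode 5 µm, internode 83 µm), whose
lengths together with the 1 µm node close the 100 µm node spacing exactly.
The internode is subdivided into ≥ 3 computational compartments so the
peri-axonal diffusion chain is resolved; other sections map one-to-one to
compartments at the default 30 µm discretization.

Membrane dynamics are Hodgkin–Huxley-type.  Conductance densities follow
the model's electrical-parameter table: somato-dendritic Na (8×10⁻³ S/cm²),
fast K (2×10⁻³), slow K (3×10⁻⁵), Ca-dependent K (3×10⁻⁴) and HVA Ca
(3×10⁻⁵); AIS Na and K at the midpoints (0.215, 0.06 S/cm²) of their
stated ranges; nodal Na_X 0.86 and M-type K_M 0.02 S/cm²; juxtaparanodal
fast K_f 0.02 S/cm²; passive myelin 0.001 S/cm² and 0.1 µF/cm² elsewhere
on the internode.  Membrane capacitance is 1 µF/cm², E_Na +45 mV, E_Ca
+140 mV, leak −65 mV, and the K reversal is −90 mV on somatic structures
but dynamic (Nernst of the local peri-axonal [K⁺]ₒ, [K⁺]ᵢ = 106 mM,
37 °C) on the axonal K conductances.  A juxtaparanodal background K
conductance (2.5×10⁻³ S/cm², dynamic reversal) represents the resting K
permeability of the internodal axolemma; it is the pathway through which
peri-axonal K⁺ accumulation depolarizes the fibre.  Axial resistivity is
80 Ω·cm (not stated by the source model; standard CNS value).

### Gating kinetics

The source model's rate equations are not published, so all kinetics here
are the package's own: Boltzmann steady states `1/(1+exp(−(V−V½)/k))` and
bell-shaped time constants, defined in one file (`periax/kinetics.py`) and
overridable from a run configuration.  They were calibrated once so the
qualitative phenomenology holds — reliable 100 Hz tonic following near the
electrode, antidromic invasion of the soma, potassium-dependent conduction
failure before initiation failure with distance, and depolarization block
at elevated [K⁺]ₒ:

- nodal Na_X: m³h, m½ = −45 mV (k 6), fast (τ ≤ 0.1 ms); h½ = −65.9 mV
  (k 4.5, τ up to ~6 ms).  The h midpoint sets the conduction-safety
  window in local [K⁺]ₒ and is the single most sensitive number in the
  model (±0.5 mV moves the conduction-failure threshold by ~1 mM K_bath).
- nodal K_M: single slow gate (z½ = −43 mV, τ 0.2–3 s), a slow
  adaptation current.
- juxtaparanodal K_f: n⁴, n½ = −55 mV (k 5) with deliberately slow τ
  (10–30 ms): the channel responds to the mean depolarization of the
  juxtaparanode over many pulses rather than to individual spikes.  This
  keeps the per-pulse K⁺ efflux small (steady elevations of a few tenths
  of a mM in the tonic regime) while preserving the activity- and
  state-dependence of accumulation.
- AIS Na: m³h with m½ = −52 mV — the low-threshold relay without which
  antidromic spikes fail to invade the soma against its capacitive load.
- somatic channels: conventional reduced pyramidal-cell forms; the Ca
  pool behind K(Ca) is first-order (τ 100 ms, entry 0.5 µM·cm²/µA·ms,
  K_d 2 µM).

Rates carry Q10 = 3 scaling about the 37 °C reference.

## Peri-axonal potassium

Each internodal compartment owns a peri-axonal pool of volume
π·d·w·L (annulus of width w = 4 nm at the PNJ, 12 nm at JXP/IND).  Only
the K_f current feeds its local pool.  Clearance is (1) Fickian diffusion
J = D·A·d[K]/dx along the chain (D = 1.85 µm²/ms; interface areas 0.009 µm²
at PNJ interfaces, 0.03 µm² elsewhere) with radial escape to the bath at
the node-facing paranode ends (area 8.16 µm² over a path length taken
equal to the 3 µm PNJ length — the path is not stated and is exposed in
configuration), and (2) Na–K pump reuptake along the internodal membrane,
I = I_max·[Ko/(Ko+K_mK)]·[Naᵢ^1.5/(Naᵢ^1.5+K_mNa^1.5)]·(V+150)/(V+200)
with I_max = 2.46 µA/cm², K_mK = 5.3 mM, K_mNa = 27.9 mM, [Na⁺]ᵢ = 10 mM,
and 2 K⁺ imported per cycle.  The pump term is applied relative to its
resting rate at the bath concentration, so an unstimulated pool is exactly
stationary and sub-baseline pools recover; the pump's net membrane current
(≲ 0.1 µA/cm²) is not added to the cable equation.  The resulting chain
drains on a ~0.3–0.6 s timescale, set by the narrow paranodal necks.

Baseline `K_bath` defaults to 3.66 mM — the concentration whose Nernst
potential is exactly the −90 mV baseline K reversal — so the resting model
is internally consistent.

## Stimulation

The electrode is a quasi-static point source in a homogeneous medium of
conductivity 0.3 S/m (the finite-element field of the original study is
replaced by this analytic surrogate; externally computed field grids can
be imported instead).  Pulses are charge-balanced biphasic rectangles,
0.1 ms per phase, cathodic first, 100 Hz for 10 s.  Coupling into the
cable uses the equivalent-injection form: each compartment receives
I_stim(t)·Σⱼ gⱼᵢ(wⱼ−wᵢ), the discrete activating function of the
unit-current potential weights w.

The stimulus amplitude is not stated by the source study; a calibration
routine selects the smallest amplitude on a log grid within the
experimental 0.03–0.1 mA range for which the near configuration
(x = z = 10 µm, electrode over node_10) follows every pulse with perfect
initiation and conduction over the final 8 s — and does so both at the
configured time step and at half that step, so the frozen amplitude is a
dt-converged operating point rather than a numerical threshold artifact.
With the default kinetics this yields 0.0486 mA, which is then frozen
for every sweep.

## Numerics

Backward-Euler voltage update with conductances frozen over the step
(gates advance first by exponential integration at the pre-step voltage),
solved directly on the tree in O(N) per step; the peri-axonal pools are
operator-split at the same dt — explicit channel efflux and pump, implicit
(unconditionally stable) tridiagonal diffusion per chain.  dt defaults to
0.01 ms (ten steps per pulse phase); spike counts are dt-converged at the
default (halving dt moves spike times by < 0.1 ms on the reference
configurations).  Runs start from the gate steady state at −68 mV and
settle for 200 ms before stimulation.  Recordings sample at 20 kHz.
Everything is deterministic: identical configurations give bit-identical
recordings; the `rng_seed` field is reserved for future stochastic
extensions and is not consumed by the core dynamics.

Cumulative ion budgets (channel efflux in, pump uptake and diffusive
export out) are tracked every step; over a full 10 s run the closure
|efflux − (Δcontent + pumped + diffused)| is at machine-precision level
(asserted < 10⁻⁴ relative in the tests).

## Analysis layer

Spikes are upward 0 mV crossings with a 2 ms refractory veto.  The ISI
statistics use the sample SD (n−1) and a 1 ms-bin histogram mode (bin
centres on integers, ties toward the shortest ISI): CV = SD/mean,
BI = mean/mode.  Experimental classification: CV > 1.5 long clustered;
CV ≤ 1.5 and BI > 5 short clustered; otherwise regular.  Simulation
classification: empty somatic train blocked; CV > 0.8 clustered (long
vs short split where the median inter-cluster gap exceeds 10× the median
intra-cluster ISI, clusters segmented at ISIs above 5× the mode); else
tonic (≥ 95 % of the stimulus rate), low-rate regular (< half the
stimulus rate), or regular.  Initiation ratio counts node spikes per
pulse; conduction ratio greedily matches soma spikes to node spikes
within a 0–5 ms latency window (measured antidromic delay in this model
is < 0.5 ms, so the window starts at zero).  Analyses default to the
final 8 s of the 10 s train.

Fixed-[K⁺]ₒ scans disable accumulation, impose the concentration
uniformly, and measure V_m1 (mean potential over the 2 ms before each
pulse) and V_m2 (mean per-pulse peak) at a named node; scan runs are 3 s
long with the second half analysed, since without accumulation the
response is strictly periodic within a few hundred ms.  The transition
detector reports the grid interval where V_m2 falls by > 20 mV.

## Synthetic spike trains

The generators emulate the statistical structure of the recorded firing
classes for testing the analysis layer: regular trains (constant ISI +
Gaussian jitter), baseline-like burst trains (geometric burst sizes, mean
3 spikes at 5 ms intra-burst ISI, exponential gaps tuned to the target
rate — at 4.6 spikes/s this reproduces CV ≈ 2 and a ~5 ms autocorrelogram
peak), and clustered trains (activity stretches alternating with
log-normal silences; the long variant uses ~40-spike clusters and
second-scale gaps, the short variant 2–3-spike clusters with ~10× gaps,
landing in the CV > 1.5 and CV ≤ 1.5/BI > 5 regions respectively).  All
are seed-deterministic.  They deliberately do not emulate raw voltage
noise spectra or electrode artifacts beyond the rectangular-artifact
fixture used to exercise artifact interpolation and detection end to end;
passing tests show the statistics pipeline is correct, not that the
generators reproduce every property of the in vivo data.

## Reproduction scope and known limitations

The model reproduces, at the calibrated amplitude: perfect tonic
following at (10, 10) µm; conduction failure emerging from (30, 30)
while initiation remains perfect out to beyond 60 µm and fails only near
100 µm — the central conduction-before-initiation ordering; a
conduction-perfect K_bath plateau up to ≈ 3.5 mM with monotone
degradation above it and collapse of somatic following to a few Hz
around ≈ 7.5 mM; and steady peri-axonal elevations of ≈ 0.4–0.5 mM
during tonic HFS.

Known deviations, documented rather than tuned away:

- The deterministic single-cable reduction mode-locks into clean
  subharmonic conduction ratios (1:2, 1:3 …, ISI CV ≤ ~0.35) where the
  original model produced irregular clustered firing; the clustered label
  therefore rarely appears in sweeps, and at high K_bath a few-Hz
  conduction trickle persists instead of an absolutely silent soma.
- Imposing [K⁺]ₒ uniformly (accumulation disabled) collapses conduction
  below ≈ 6 mM in this reduction, well below the mid-teens seen with a
  double-cable geometry; the fixed-[K⁺]ₒ bifurcation scan over 14–15 mM
  consequently finds no transition.  The accumulation-driven thresholds
  were preferred when the two could not be reconciled.
- With the analytic point-source field, the far (100, 100) µm
  configuration initiates nothing and is silent rather than firing at a
  low regular rate, and conduction along the distance axis is
  non-monotone in a narrow 40–60 µm band (a standing-pattern interaction
  between the field and the accumulated zone).
- No axonal branching, astrocytic buffering, extracellular-volume
  dynamics, or Na⁺/Cl⁻ concentration dynamics.
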