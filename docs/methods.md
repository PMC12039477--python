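# Methods

This note documents the models and procedures implemented in `sncdev`, the
parameters that matter, and the choices made where the design was genuinely
open.

## Scientific setting

Substantia nigra pars compacta (SNc) dopaminergic neurons are spontaneous
pacemakers with two morphological peculiarities: in roughly 87% of cells the
axon arises not from the soma but from one dendrite — the axon-bearing
dendrite (ABD) — at a variable distance from the soma, and the somatic
action potential (AP) is broad, with its duration shaped by the dendritic
arbor.  During the first three postnatal weeks (stages P3, P7, P14, P21)
the ABD elongates several-fold, soma volume roughly doubles, and the AP
narrows and grows; most of the change is concentrated between P7 and P14.
The package reproduces the computational side of that analysis:
morphometry of reconstructed or synthetic neurons, a multicompartment
conductance-based model on branched morphologies with homogeneous
(Model 1) versus ABD-enriched (Model 2) dendritic sodium/calcium
densities, AP-waveform decomposition, a sodium-conductance screening
procedure, and the developmental-stage statistics.

## Morphometry (`sncdev.morphology`)

A morphology is a rooted tree of frustum sections labelled soma / dendrite
/ axon_start / AIS / axon.  Conventions:

- A *dendritic segment* runs branch point to branch point, or branch point
  to tip; the stem from the soma to the first branch point is one segment,
  so an unbranched dendrite counts 1.  The axon leaving a dendrite is not a
  dendritic branch point.
- *Axon–soma distance* is the arc-length path distance from the soma to the
  axon origin (the additive identity AIS–soma = axon–soma + axon-start
  length, which holds in the population means, supports the path-distance
  reading).  The origin may lie beyond the first branch point.
- The soma is represented by an *equivalent cylinder* with length equal to
  diameter and π d³/4 equal to the measured soma volume.  The aspect ratio
  is a convention (one free parameter); it is the standard somatic
  representation in compartmental modelling.
- Non-primary dendrites taper linearly along path distance from the
  primary-stem diameter to 0.5 µm, reached exactly at the most distal tip
  passing through each section; primary stems keep their diameter and the
  axon is a constant 0.7 µm.
- Somatic-axon neurons have no ABD; their ABD metrics are reported as NaN
  (missing), never as zero, and are excluded from paired and population
  statistics.

SWC input/output uses the standard 7-column format.  SWC has no type code
for the AIS, so the axon_start/AIS extents (and optionally soma volume)
travel in a side-car JSON file, or are supplied as arguments.

## Synthetic morphology generator (`sncdev.synthetic`)

The study's reconstructions are not deposited with a usable accession, so
the generator turns the published per-stage population statistics (mean,
SD, range, n of each morphometric quantity, plus the per-stage
somatic-axon counts 2/10, 4/23, 1/13, 4/38) into a sampling model:

- **Distribution family.** Each drawn field follows a truncated normal.
  The truncation window is the published range width inflated by 1.3,
  centred on the mean and floored at zero: the expected range of 10–50
  normal draws is ≈3 SD, so the printed (finite-sample) range understates
  the population support, and without inflation no truncated normal on
  that window can reach the published SD (truncation at ±1.45 σ caps the
  SD at ≈0.84 σ).
- **Moment matching.** Location and scale are fitted so the *truncated*
  mean equals the published mean exactly, and the truncated SD is as close
  to the published SD as the support permits.  One field is infeasible:
  the P3 axon–soma distance has SD > mean with a floor at 0, a shape no
  truncated normal can produce (the family's limit is the exponential
  shape, SD ≈ mean); its realised SD is ≈16–20% low.  All other 35
  field×stage combinations land within 15% on SD and exactly on the mean.
- **Stratified population sampling.** `sample_population` draws each
  field through Latin-hypercube-style stratified uniforms (an independent
  random permutation per field) and quota-samples the somatic-axon flag,
  so population-level sample moments pin tightly to the published values —
  the generator's purpose is to emulate population statistics.  Fully
  independent neurons are available with `stratified=False`.
- **Topology.** Dendritic trees are random binary trees grown by
  bifurcating a uniformly chosen terminal segment until the drawn segment
  count is met (counts are rounded stochastically to the nearest odd
  integer, unbiased); drawn total lengths are partitioned over segments by
  Dirichlet weights with a 5% floor.  Length and segment count of the same
  dendrite therefore co-vary; cross-field correlations are otherwise
  independent — a documented simplification (real neurons correlate, e.g.,
  soma volume with total length).
- **Axon placement.** With the per-stage somatic-axon probability the axon
  sits on the soma; otherwise at the drawn arc distance along the longest
  root-to-tip path of the ABD, reallocating length onto that path when the
  draw overshoots it (total ABD length preserved) and clamping the rare
  draws longer than 95% of the whole ABD.
- **Electrophysiological features.** For the statistics layer,
  `sample_feature_table` adds AP-shape columns drawn from the published
  per-stage distributions; they are *drawn*, not simulated per neuron, and
  are independent of the morphological columns — adequate for testing
  between-stage separation, not within-stage structure.
- Primary-dendrite stem diameters per stage (1.2/1.5/2.0/2.0 µm) are
  configuration defaults, not published values.

Derived quantities (total length, total segment count, per-nABD averages,
AIS–soma distance) are computed per neuron from the drawn components, so
the additive identities hold exactly by construction; their population
means consequently track the published values only approximately (the
published rows have differing n).

## Biophysics (`sncdev.channels`)

Seven conductances: fast Na, delayed-rectifier K (KDR), A-type K, L-type
Ca (CaL), SK-type Ca-activated K (KCa), H current, and leak.  Gate
kinetics are data: Boltzmann steady states `1/(1+exp(-(V-Vh)/k))` and
bell-shaped time constants, packed into a parameter vector consumed by the
integration kernel.  The study states its kinetics descend from published
SNc models (Migliore-type Na, Schild-type KDR, published A/CaL/SK/H forms)
without printing rate equations; the shipped set is therefore a
*reconstruction* tuned so the intact model expresses the study's
documented behaviour — spontaneous regular pacemaking, AIS-first spike
initiation, a broad somatic AP (half-width ≈1.3–1.4 ms at the default P21
heterogeneous densities, against a biological mean of 1.30 ms), and a
monotone decrease of somatic AP half-width with dendritic gNa — rather
than to reproduce specific voltage-clamp curves.  Key default parameters:

| element | value | note |
|---|---|---|
| Na m³h | m: Vh −37, k 6; h: Vh −52, k −6.5 | the subthreshold Na window is the pacemaker engine |
| KDR n³ | Vh −28, k 9 | repolarisation, deep AHP (E_K −90 mV) |
| A a²b | a: Vh −30, k 8; b: Vh −80 (dend) / −70 (soma), k −8 | somatic variant: depolarised, slower inactivation |
| CaL d | Vh −30, k 5 | high-voltage activated; fixed +60 mV reversal (no GHK) |
| KCa (SK) | Hill of [Ca], Kd 1 µM, n_H 4, τ 5 ms | spike-triggered AHP, not a subthreshold brake |
| H q | Vh −80, k −8, τ up to 650 ms | small density: strongly accelerates the pacemaker if large |
| Ca pool | rest 50 nM, τ 5 ms, whole-compartment volume | single-exponential decay; influx from CaL only |
| reversals | Na +60, K −90, Ca +60, H −35, leak −50 mV | not printed in the study; standard values |

Densities (pS/µm²; 1 pS/µm² = 10⁻⁴ S/cm²): Model 2 (heterogeneous) uses
the study's ABD-enriched values gNa 120 (ABD) vs 50 (nABD) and gCa 2.2 vs
1.0, with soma and axon-start at the ABD level; Model 1 (homogeneous) sets
ABD = nABD.  KDR 40, A 40 (soma) / 20 (dendrites), SK 4, H 0.1, leak 0.1
(= Rm 100 kΩ·cm²) everywhere.  The AIS carries only Na, KDR and leak, at
multiplier-defined densities (default 15× the somatodendritic gNa maximum,
8× for KDR, consistent with the study's 10–15× constraint and AIS-first
initiation); the distal axon carries somatodendritic-level Na/KDR.  The
AIS row is derived once from the base scheme and held fixed during gNa
sweeps (`ConductanceScheme.with_density`), so a dendritic sweep does not
drag the AIS along.

## Cable solver (`sncdev.cable`)

Sections are discretized into frustum compartments no longer than a rule
(default 10 µm; the scaled-down protocols use 15 µm, ≈200 compartments on
a typical P21 neuron).  Passive constants: Ra 150 Ω·cm, Cm 0.75 µF/cm²,
Rm 100 kΩ·cm² with leak reversal −50 mV; runs start at −70 mV, last
6,000 ms at dt 0.01 ms by default, and analysis discards the first
2,000 ms (steady-state pacemaking).

The integrator advances gates by Rush–Larsen exponential updates at the
current voltage, then solves the branched voltage system implicitly with a
Hines-ordered direct solve (exact tree LU, O(n) per step).  The voltage
step is θ-weighted (θ = 1 backward Euler, θ = 0.5 Crank–Nicolson);
the default θ = 0.6 damps the stiff AIS modes while keeping
near-second-order phase accuracy (halving dt from 0.01 ms moves the
steady-state spike pattern by <0.1 ms; halving the compartment rule moves
the somatic half-width by <2%).  The kernel is compiled with numba.
Verification is against closed forms and an independent adaptive-step
reference: passive fixed point at the leak reversal, RC charging with
τ = RmCm = 75 ms (<1%), steady-state attenuation matching exp(−x/λ) with
λ = √(Rm·d/4Ra) (<1%), charge balance (<0.5%), and a full
single-compartment model within 0.5 mV RMS of an LSODA solution over 1 s.

Calcium: the pool uses the whole compartment volume with a fast (5 ms)
decay; this keeps subthreshold SK activation negligible while APs drive
µM-scale transients that produce the SK-mediated AHP.  A thin-shell pool
with slower decay saturates SK at subthreshold voltages and locks the
membrane at a stable sub-threshold equilibrium — the single most
pacemaking-critical configuration choice in the model.

## AP waveform analysis (`sncdev.waveform`)

Spikes are upward crossings of −20 mV with a 2 ms refractory; averaged
waveforms are spike-triggered averages aligned on the AP peak.  Threshold
is the voltage where dV/dt first crosses 20 mV/ms before the peak
(sub-sample interpolated); amplitude is threshold-to-peak (the
trough-referenced alternative is a documented option; the study does not
state its reference); half-width is measured at 50% of that amplitude.
The initial-segment (IS) and somatodendritic (SD) components are the two
largest local maxima of d²V/dt² between threshold and peak, in temporal
order, with the search window opened 0.5 ms before the threshold crossing
(for shallow upstrokes the IS acceleration peak can precede the 20 mV/ms
point).  Optional Savitzky–Golay smoothing suppresses sampling noise.
Simulated APs at the default densities sometimes express a single merged
acceleration peak (SD fields then NaN, recorded, not fatal) — a known
limitation of the reconstructed kinetics.  Pacemaking regularity is the
ISI coefficient of variation (sample SD over mean); AIS-first initiation
is the per-spike lead of the AIS threshold crossing over the somatic one.

## Sodium-conductance screening (`sncdev.screen`)

The heterogeneous (mature-stage) screen varies ABD gNa over 50–150 pS/µm²
in steps of 10 with gCa fixed; the homogeneous (early-stage) screen varies
ABD and nABD together over 25–165 pS/µm².  For each neuron the somatic
half-width is measured at every grid point; the gNa matching a target
half-width is found by piecewise-linear interpolation, linearly
extrapolated from the nearest two points outside the achieved range, with
a closest-bracket rule (and warning) under non-monotonicity.  Whether the
achieved half-width is re-simulated or interpolated at the optimum is a
config choice (default: interpolated).  Sensitivity is the coefficient of
variation (sample SD, n−1) of half-width over a fixed threefold gNa range
(50–150 heterogeneous, 55–165 homogeneous).  On synthetic P21 neurons the
half-width falls monotonically with ABD gNa (≈1.50→1.28 ms over the
default grid), so recovery of a known gNa is exact on-grid and well within
half a grid step off-grid.

Not every synthetic neuron is gNa-sensitive: a minority show a near-flat,
slightly non-monotone half-width/gNa relation (total variation below
0.05 ms over the threefold range), and no single morphological feature
predicts this — it is an electrotonic property of the whole arbor.  The
inversion is only defined where the relation is invertible, so the
parameter-recovery experiment in `scripts/acceptance.py` verifies the
premise first (half-width must fall by at least 0.1 ms from the low to
the high end of the grid, checked with two short simulations) before
selecting the experiment's neuron; insensitive neurons are themselves a
model observation, reported through the closest-bracket rule and its
warning when screened.

## Developmental statistics (`sncdev.devstats`)

Per parameter, a Shapiro–Wilk gate (α = 0.05 in every group) selects
one-way ANOVA with Tukey's post hoc test or Kruskal–Wallis with Dunn's
post hoc test (rank z-tests, tie-corrected, Bonferroni-adjusted over the
six stage pairs); the study names the tests but not the normality
criterion.  Paired ABD-vs-nABD comparisons use a paired t test with
somatic-axon neurons excluded pairwise; regressions are Pearson with
two-sided t-distribution p-values.  The stacking matrix arranges the six
stage-pair bands (ns, <0.05, <0.01, <0.001) over the 20-parameter panel.
AHC z-scores the 12-parameter panel (AP half-width, IS and SD peaks,
SD/IS ratio, amplitude, soma volume, axon-start length, AIS–soma
distance, average and total nABD length, overall and ABD length), applies
Ward linkage on Euclidean distance, and cuts at the largest gap between
successive merge dissimilarities ("automatic threshold"); linkage and cut
are configurable.  LDA uses nine parameters; the study does not enumerate
them, so the default is the 12-parameter panel minus its three
arithmetically derived columns (SD/IS ratio, overall length, average nABD
length).  All multivariate steps are deterministic given the table.

## Scaled-down protocols

The default published protocol (6 s at dt 0.01 ms, 10 µm compartments) is
expensive at population scale; tests and the acceptance script use a
scaled protocol — 3 s at dt 0.02 ms, 15 µm compartments, 1.5 s discard —
chosen after verifying temporal and spatial convergence (above).  Steady
state is reached well before 1.5 s at the default densities.

## Known limitations

- Channel kinetics are reconstructed, not transcribed; quantities tied to
  kinetic detail (absolute IS/SD peak amplitudes, threshold) match the
  biology only loosely (model threshold ≈ −47 mV vs −44.7 measured), while
  the tuned-for properties (pacemaking, AIS initiation, half-width and its
  gNa dependence) are quantitative.
- The generator reproduces marginal per-field distributions, not the full
  correlation structure of real neurons; passing separation tests shows
  the pipeline detects between-stage differences of the published size,
  not that it would reproduce within-stage covariances.
- Fixed calcium reversal (no GHK), no spines, no synapses, no stochastic
  gating, no temperature scaling.
- The screening comparison against the study's per-neuron optimal-gNa
  means requires the original reconstructions, which have no deposited
  accession; the package reports the same screen on synthetic neurons.
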