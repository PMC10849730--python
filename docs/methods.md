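# Methods

## The model

The package implements a conductance-based network model of the insect
antennal lobe (AL): `n_PN` excitatory projection neurons (PNs) and `n_LN`
inhibitory local neurons (LNs), each a single Hodgkin–Huxley compartment.
Membrane potentials obey

    Cm dV/dt = −gL (V−EL) − gKL (V−EKL) − Σ_c I_c − I_GABA_A − I_slow − I_nACh + I_stim

with intrinsic currents I_c = g_c m^M h^N (V−E_c): Na, K, A, T and h
currents for PNs; Na, K and T for LNs.  Passive parameters: PN Cm =
2.9·10⁻⁴ µF, gL = 0.01, gKL = 0.012 mS/cm²; LN Cm = 1.43·10⁻⁴ µF, gL =
0.05, gKL = 0.018 mS/cm²; EL = −70 mV, EKL = −95 mV; maximal conductance
densities gNa = 90 (PN) / 100 (LN), gK = 10, gA = 10 (PN), gT = 2 (PN) /
1.75 (LN), gh = 0.02 (PN) mS/cm²; ENa = 50 mV, EK = −95 mV, ECa = 140 mV.
Intracellular Ca²⁺ follows dCa/dt = −A·I_T − (Ca − Ca_inf)/τ with Ca_inf =
2.4·10⁻⁴ mM, A = 5.2·10⁻⁵ mM·cm²/(ms·µA), τ = 5 ms.

Because capacitance is printed as a total (µF) and conductances as
densities (mS/cm²), each cell type carries an explicit membrane `area`
(PN 2.9·10⁻⁴ cm², LN 1.43·10⁻⁴ cm², i.e. a specific capacitance of
1 µF/cm²) so that total conductance = density × area and every printed
value is usable verbatim.

### Gating kinetics

The gating steady states and time constants are not original to this model;
they are adopted from the established AL/thalamic modelling lineage:
Traub–Miles rate functions for Na and K (with a −50 mV threshold shift,
placing the spike threshold near −50 mV given the −70/−95 mV leak
reversals), Huguenard–McCormick kinetics for the transient K⁺ A-current and
low-threshold Ca²⁺ T-current, and McCormick–Pape kinetics for Ih (reversal
−43 mV, a value this parameter set leaves unstated).  They live in
`alnet.kinetics` behind a per-channel registry so alternative published
forms can be swapped in.

### Synapses

Fast GABA_A (E = −70 mV, α = 10 ms⁻¹, β = 0.2 ms⁻¹) and nicotinic ACh
(E = 0 mV, α = 1 ms⁻¹, β = 0.2 ms⁻¹) synapses follow the first-order
scheme dO/dt = α(1−O)T − βO.  GABA transmitter is the sigmoid
T = 1/(1+exp(−(V_pre+20)/1.5)) of the instantaneous presynaptic voltage;
ACh transmitter is a square pulse (amplitude 0.5, 0.3 ms) triggered by each
presynaptic spike.  Slow inhibition uses the G-protein cascade dR/dt =
r1(1−R)T − r2 R, dG/dt = r3 R − r4 G, I = g·G⁴/(G⁴+K)·(V+95) with r1 = 0.5,
r2 = 0.0013, r3 = 0.1, r4 = 0.033 ms⁻¹, K = 100 µM⁴; its transmitter is the
same presynaptic-voltage sigmoid as fast GABA (both are LN release).

Class conductances (small network): LN→LN GABA_A 0.02 µS, LN→PN GABA_A
0.015 µS + slow 0.02 µS, PN→LN ACh 0.3 µS; large network: 0.024 / 0.019 /
0.075 µS.  These are interpreted as *totals per postsynaptic cell and
class*, shared equally among the cell's realised inputs of that class.
Under a per-connection reading a single GABA_A input would exceed the whole
PN leak conductance ~5×, and ~50 such inputs would swamp every other
current; sharing also makes the total synaptic drive independent of network
scale, which the reduced networks rely on.

### Network geometry

Small network: 20 glomeruli × (5 PNs + 12 unipolar LNs) plus 40 multipolar
LNs (100 PNs / 280 LNs).  Connections are independent Bernoulli draws:
PN→LN 0.4; unipolar LN→PN 0.5 across glomeruli, 0 within; unipolar
LN→unipolar LN 0.4 across, 0 within; unipolar LN→multipolar 0.3;
multipolar→PN 0.3, →multipolar 0.1, →unipolar 0.4; no PN→PN anywhere; no
self-connections.  Each LN→PN connection carries both the fast and the slow
component.  The large variant (400 PNs / 1120 LNs) uses uniform p = 0.125
for LN→LN, LN→PN and PN→LN.  A reduced variant keeps the per-glomerulus
composition with fewer glomeruli (8 glomeruli → the 40 PN / 112 LN network;
4 glomeruli → 20 PN / 56 LN) and is the workhorse of the test suite.

### Stimuli

An odor is a set of active *percepts* — contiguous PN (and mirrored
unipolar-LN) blocks standing for single volatile chemicals.  Within a
block, activation is a Gaussian of the normalised block coordinate with the
odor's per-percept width (standard deviation as a fraction of the
half-block, so width 0.372 means the same at any scale).  The temporal
envelope is a 500 ms pulse with first-order rise (τ = 66.7 ms) and decay
(τ = 200 ms), normalised to unit peak — the simplest form with exactly the
two stated time constants.  Gaussian current noise (resampled every 1 ms)
is added to every cell at all times.  Blend odors map each chemical
component's proportion to its percept's width, with the last percept
inactive; gas-sensor odors convert per-sensor feature triples into pulse
parameters: τ_rise = c_r/ema_max, τ_decay = c_d/ema_min, amplitude =
c_a·ΔR with c_r = c_d = c_a = 1 by default (the proportionality constants
are free choices; the surrogate dataset generates ema features near
0.005–0.02 so the resulting time constants land in the 50–200 ms range).

Input amplitudes are not part of the published parameter set; the defaults
(PN 1.2·10⁻³ µA, LN 2.4·10⁻⁴ µA peak, multipolar LNs driven at the mean
unipolar drive, noise sd 1.5·10⁻⁴ / 1.2·10⁻⁵ µA) were calibrated once so
that odor-driven PNs fire a few tens of Hz at percept centers, LNs ~20 Hz,
and the median spontaneous PN rate stays below 3 Hz.

### Plasticity

Every inhibitory connection (LN→PN, LN→LN) carries a facilitation variable
F ≥ 1 multiplying its conductance.  During training, a presynaptic LN spike
in the presence of a rewarded odor adds dF_pre = 0.15 (associative,
octopamine-gated pathway); a postsynaptic spike in the presence of a
habituated odor adds dF_post = 0.15 (nonassociative pathway).  Between
events F decays toward 1 with τ = 30 s:
F(t) = 1 + (F_i − 1)·exp(−(t − t_i)/τ).  Excitatory synapses are never
plastic.  After training (default 30 presentations, 2 s each, randomized
order, one continuous simulation) the weights are frozen for testing.

Facilitation applies to the fast GABA_A component only by default.  Whether
the slow component shares F is left open by the parameter set; with shared
F the slow synapse's ~1 s receptor memory (1/r2 ≈ 770 ms) integrated over
training clamps the entire PN population at strongly negative potentials,
erasing the odor-specific contrast the learning is supposed to create, so
the shared variant is available as `facilitate_slow=True` but is not the
default.

Events are counted over the full trial (spiking outside the pulse is
essentially absent at the calibrated noise level), and the decay also runs
during training (its effect within one 2 s trial is ~10⁻³ of F−1).

### Forgetting across environments

When training moves to a new odor environment, connections that receive no
facilitation event in the new environment relax toward baseline with
τ_forget = 300 s = 10 × the decay constant ("slow" forgetting: one 60 s
training recovers ~18% of F−1, so the old memory is weakened but not
erased).  A facilitation event returns a connection to the ordinary 30 s
decay regime.  Applying the 30 s decay to carried-over weights instead
would erase the first environment's memory almost completely
(exp(−60/30) ≈ 0.14 retained) within a single training, which contradicts
the intended partial-recovery behaviour.  In scaled-down protocols
τ_forget is scaled with total training time (τ_forget =
300 s × T_train/60 s) to preserve the forgetting-to-training ratio.

### Integration

The full coupled system is advanced with classical fixed-step RK4 at
dt = 0.04 ms.  Spikes are detected after each step as upward 0 mV crossings
with a 1 ms lockout; ACh pulses start and facilitation updates apply after
the step, so each spike is seen exactly once.  Two exact algebraic
reductions keep the inner loop fast: receptor states (O, R, G) follow
identical ODEs for all connections sharing a presynaptic neuron and are
integrated once per neuron (facilitation stays per-connection, so
weight-specific learning is untouched), and gating steady states/time
constants are interpolated from a 0.05 mV voltage grid built from the exact
kinetics functions (interpolation error ≪ integration error; the engine is
validated against a transparent per-state reference integrator in the
tests).  Gating variables, open fractions and concentrations are clipped to
their invariant ranges after each step as a numerical guard; the clip is
inactive in normal operation.  Initial conditions: V = EL, gates at
x_inf(EL), Ca at equilibrium, synapses closed, with the first 200 ms of
each trial left out of analysis.  Non-finite state aborts integration with
the offending neuron identified.

Determinism: every random element (connectivity, odor widths, presentation
order, injected noise) is driven by an explicit integer seed; identical
seeds reproduce spike times bit-identically.

## Analysis

Representation correlation: PN spike counts in 100 ms bins over the 500 ms
odor window, each PN normalised by its maximum count across the trials of
the comparison (unit-max; a z-score variant is available — the normalisation
is stated only as "normalized" in the source parameter set), Pearson
correlation per (trial pair, bin), averaged over bins then pairs;
zero-variance bins are skipped.  PCA trajectories use 40 ms bins with the
model fitted jointly over all compared conditions so trajectories share
axes.  Per-unit uniqueness index UI = (act_rew − act_hab)/act_hab and
activity change (act_post − act_ref)/act_ref use mean spike counts per
percept block averaged over a class's odors and trials; units with zero
reference activity are excluded.  Contrast enhancement is the OLS fit of
change vs UI (slope, R², F-test p).  Condition comparisons use unpaired
two-tailed t-tests (Wilcoxon available); direction claims across seeds use
one-sided sign tests.

## The GCN analogue

A 17-node graph (16 sensor nodes + 1 reward node) processes 16×8 sensor
feature matrices through two graph-convolution layers
H_{l+1} = relu(A·H_l·W_l) (8 → 8 → 4 features per node), a flatten, and two
fully connected layers (hidden width 16) to a 2-way rewarded/habituated
score.  Sensor–sensor adjacency entries are 1 with no self-loops (with
self-loops every sensor node would aggregate the identical sum and the
node-level analysis would be degenerate); during training the reward node's
edges are +1 for rewarded and −1 for habituated samples, and 0 at test time
so no label leaks.  The flatten feeds the 16 sensor (data) nodes only: the
reward node's activation is label-determined during training and zero at
test, and including it in the head teaches a shortcut that vanishes at test
time, making held-out accuracy strongly seed-dependent.  Features are standardized per sensor-feature over the
pooled train and test sets; training uses cross-entropy, Adam, lr 0.01,
20 epochs, minibatch 16, seed-fixed stratified 80/20 split.  The layer-1
hidden width, the FC hidden width, the nonlinearity (rectifier), the raw
(unnormalised) adjacency and the split are free choices exposed in
`GCNSpec`.  The network and its backpropagation are plain numpy; gradients
are verified against finite differences in the tests.  The layer-wise
analysis computes per-sensor-node UI from layer-1 mean activations
(rewarded vs habituated) and change = layer-2 − layer-1 mean activation for
rewarded inputs, then fits change vs UI.

## Synthetic data

The generators provide every input class with known ground truth:
the minimal two-class layout (rewarded {1,2,3} vs habituated {2,3,4} of 7
percepts, 10 odors per class with jittered widths drawn uniformly from
[0.25, 0.45]); blend classes as Dirichlet draws around per-class mean
proportions (same six components, different ratios; the default class means
used in the examples and acceptance runs are synthetic stand-ins shaped
like two flower-variety blends, led by a 0.372 component); the four
environment-overlap layouts on 8 percepts; a surrogate 6-class × 16-sensor
× 8-feature dataset with class-dependent means, positive ema features among
them, and a sample-wide drift term; and 24-glomerulus response matrices
with a planted change-vs-UI slope for recovery tests.  The surrogate sensor
data emulate class-conditional structure only — not the batch/drift
structure of a real sensor array — and the glomerular patterns plant a
linear effect; passing recovery tests therefore demonstrates estimator
correctness, not realism of the noise model.

## Problem sizes

The published protocol (100 PNs / 280 LNs, 30 × 2 s presentations, 10
trials) is implemented and available, but the test suite and the
acceptance script run the same protocols on the reduced 4-glomerulus
network (20 PNs / 56 LNs, ~2,200 connections), 1.5 s training trials with
odor onset at 300 ms, 10 presentations (5 odors per class), 1 s probe
trials and 2 probe trials per odor, with 2–5 seeds per claim.  These sizes
are the package's own desk-scale choice; they preserve protocol structure
and the directional results while keeping a full run in minutes.

## Known limitations

* At 20–56 neurons per population, LN odor selectivity is structurally
  weak: each LN receives cholinergic input from ~40% of all PNs, and with
  the 0.3 µS class conductance a single PN spike produces a transiently
  suprathreshold EPSP, so LNs respond to every odor (~1.7:1 selectivity).
  Presynaptic (associative) facilitation is therefore nearly as disruptive
  to the representations as full differential conditioning at this scale,
  and environment relearning re-reinforces old weights through these
  nonselective LNs, muting the forgetting-driven recovery effects.
* Facilitation saturates (F ~ 10–20 on driven pathways) at the stated
  per-spike increment and decay once LN rates reach ~20 Hz; the
  decorrelation direction is robust to this, but magnitudes are not
  comparable across scales.
* For the same reason, reduced-scale decorrelation is carried largely by
  the overall increase in inhibition rather than its learned structure, so
  weight-shuffled controls decorrelate almost as much as structured trained
  networks at this scale; the structured-vs-shuffled contrast needs the
  full-size network to be resolved.
* On the surrogate sensor dataset the odor classes are separable from the
  features alone, so the reward-edge signal is redundant: ablating the
  reward edges during training does not reduce (and can slightly improve)
  held-out accuracy.  The reward-edge mechanism only becomes load-bearing
  when features carry little class information — in which case neither
  model can classify at test time, where reward edges are zeroed.
* The GCN's layer-wise change-vs-uniqueness regression comes out with a
  *negative* slope under this architecture, systematically across seeds.
  A complete sensor graph with self-loops gives every sensor node the
  identical aggregate (per-node analysis degenerates); without self-loops
  node i aggregates (sum − x_i), anti-correlating its layer-1 activation
  with its own sensor's response, and the second aggregation re-inverts —
  so the per-node change/uniqueness relation is inverted by construction.
  A per-node contrast-enhancement readout like the spiking model's would
  require an aggregation that preserves node identity (e.g., a sparser or
  self-weighted adjacency), which the stated architecture does not include.
* The slow-inhibition facilitation switch (above) is a genuine model
  choice, not derivable from the printed parameters.
* Multipolar LNs' odor drive is not specified anywhere; they receive the
  mean unipolar drive scaled by a config gain (default 1.0).
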