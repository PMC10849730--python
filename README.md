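# alnet — inhibitory plasticity and pattern separation in the antennal lobe

`alnet` is a research package for studying how plasticity of *inhibitory*
circuits in the insect antennal lobe (AL) — the first relay of the
olfactory system — reshapes odor representations during reward learning.
It provides:

* a conductance-based spiking network of Hodgkin–Huxley projection neurons
  (PNs) and inhibitory local neurons (LNs) organised into glomeruli, with
  fast GABA_A, slow (G-protein-coupled) inhibitory and nicotinic synapses;
* valence-gated facilitation of inhibitory synapses: presynaptic
  facilitation during rewarded odors (the octopamine-gated, associative
  pathway) and postsynaptic facilitation during habituated odors
  (nonassociative), with exponential decay and post-training weight
  freezing;
* odor stimuli built from *percepts* (Gaussian activation blocks standing
  for single volatile chemicals), including blend-proportion odors and
  pulses derived from gas-sensor feature triples;
* training/testing protocols: differential and absolute conditioning,
  pathway-specific (associative-only / nonassociative-only) training,
  weight-shuffling controls, and sequential learning across two odor
  environments with slow forgetting;
* representation analysis: binned-population-vector Pearson correlation,
  PCA response trajectories, per-unit uniqueness index and activity change,
  and the contrast-enhancement regression;
* a small graph-convolutional network (GCN) analogue — 16 sensor nodes plus
  a reward node whose edge signs encode trial valence — trained on the same
  kind of odor data, with the matching layer-wise analysis;
* seed-deterministic synthetic-data generators for every input class.

## The model in brief

Each neuron is a single compartment, Cm dV/dt = −Σ I_intrinsic − Σ I_syn +
I_stim, with Na/K spike currents plus A-, T- and h-currents (PNs) following
standard Hodgkin–Huxley kinetics.  Every inhibitory connection (LN→PN,
LN→LN) carries a facilitation variable F ≥ 1 multiplying its conductance:

    presynaptic LN spike during a rewarded odor:   F ← F + 0.15
    postsynaptic spike during a habituated odor:   F ← F + 0.15
    otherwise F decays:  F(t) = 1 + (F_i − 1)·exp(−(t − t_i)/30 s)

Differential conditioning (one odor class rewarded, an overlapping class
habituated, 30 randomized 2 s presentations) restructures the inhibitory
network so that PN population vectors of the two classes decorrelate, and
per-percept activity changes align with each percept's *uniqueness index*
UI = (act_rewarded − act_habituated)/act_habituated — activity rises for
percepts unique to rewarded odors and falls for shared ones ("contrast
enhancement").

## Worked example

`examples/03_differential_conditioning.py` trains a reduced network
(4 glomeruli, 20 PNs / 56 LNs) on a rewarded class (percepts {1,2,3}) vs a
habituated class ({2,3,4}) and probes it with plasticity off:

```
corr(rewarded, habituated)         naive: +0.605
corr(rewarded, habituated)  differential: -0.187
contrast enhancement: slope=+0.278 R^2=0.31 p=0.251 (n=6 percepts)
```

The correlation between the two classes' PN population vectors drops from
clearly positive to around zero or below — the trained inhibitory network
pushes the representations apart — and the positive slope shows percepts
unique to the rewarded odors gaining activity relative to percepts shared
with the habituated odors.  The other examples cover single-neuron
behaviour, a naive odor response, sequential environments, and the GCN
analogue (`python examples/05_gcn_analogue.py` prints 97.2% held-out
accuracy; see `docs/methods.md` on why its layer-wise change-vs-uniqueness
slope comes out negative under the all-to-all sensor graph).

## Layout

```
src/alnet/
  neurons.py     single-compartment PN/LN models, reference integrator
  kinetics.py    gating-rate functions (Traub–Miles, Huguenard–McCormick, …)
  synapses.py    fast GABA_A / nACh and slow inhibitory synapse models
  plasticity.py  valence-gated facilitation, decay, freezing, forgetting
  network.py     glomerular network construction, shuffling control, tables
  stimuli.py     percepts, odors, pulse envelopes, blends, sensor features
  simulator.py   RK4 trial/training/testing and environment protocols
  _engine.py     numba inner loop
  analysis.py    correlations, PCA trajectories, UI / contrast enhancement
  synthetic.py   generators for odors, sensor data, glomerular patterns
  gcn.py         the graph-convolutional analogue (numpy + Adam)
  config.py      YAML configs and table IO
examples/        one short narrative script per capability
docs/methods.md  model equations, parameters, numerical choices, limits
```
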