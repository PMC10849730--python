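"""Synapse models of the antennal-lobe network.

Three synapse classes connect the populations:

* fast GABA_A (LN -> PN and LN -> LN): first-order receptor scheme
  dO/dt = alpha (1 - O) T - beta O with transmitter T a sigmoid of the
  presynaptic voltage, current I = gmax O (V - E), E = -70 mV;
* nicotinic ACh (PN -> LN): same receptor scheme with a square transmitter
  pulse (amplitude 0.5, 0.3 ms) triggered by each presynaptic spike,
  E = 0 mV;
* slow inhibition (LN -> PN, G-protein coupled): receptor/effector cascade
  dR/dt = r1 (1 - R) T - r2 R, dG/dt = r3 R - r4 G and current
  I = gmax * G^4 / (G^4 + K) * (V - EK), EK = -95 mV.

Inhibitory conductances are multiplied by a facilitation variable F >= 1
managed by :mod:`alnet.plasticity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class FastSynapseSpec:
    """First-order fast synapse (GABA_A or nACh)."""

    kind: str                  # "GABA_A" | "nACh"
    gmax: float                # maximal conductance, uS
    Esyn: float = None         # reversal, mV (fixed per kind)
    alpha: float = None        # opening rate, 1/ms
    beta: float = 0.2          # closing rate, 1/ms

    def __post_init__(self):
        defaults = {"GABA_A": (-70.0, 10.0), "nACh": (0.0, 1.0)}
        if self.kind not in defaults:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        e, a = defaults[self.kind]
        if self.Esyn is None:
            object.__setattr__(self, "Esyn", e)
        if self.alpha is None:
            object.__setattr__(self, "alpha", a)
        if self.gmax < 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gmax >= 0 and positive rates required")
        if self.Esyn != e:
            raise ValueError(f"{self.kind} reversal must be {e} mV")


@dataclass(frozen=True)
class AChPulseSpec:
    """Square transmitter pulse released on each presynaptic spike."""

    A_t: float = 0.5     # transmitter amplitude, dimensionless
    tmax: float = 0.3    # pulse duration, ms

    def __post_init__(self):
        if self.A_t <= 0 or self.tmax <= 0:
            raise ValueError("A_t and tmax must be positive")


@dataclass(frozen=True)
class GABAReleaseSpec:
    """Sigmoidal voltage-to-transmitter function of GABAergic release."""

    V0: float = -20.0    # half-activation voltage, mV
    sigma: float = 1.5   # slope, mV

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SlowSynapseSpec:
    """Slow (G-protein-coupled) inhibitory synapse."""

    gmax: float           # maximal conductance, uS
    EK: float = -95.0     # potassium reversal, mV
    r1: float = 0.5       # receptor opening, 1/(mM*ms)
    r2: float = 0.0013    # receptor closing, 1/ms
    r3: float = 0.1       # G-protein production, 1/ms
    r4: float = 0.033     # G-protein decay, 1/ms
    K: float = 100.0      # half-activation constant, uM^4

    def __post_init__(self):
        if min(self.r1, self.r2, self.r3, self.r4) <= 0 or self.K <= 0:
            raise ValueError("rates and K must be positive")


@dataclass
class SynapseState:
    """Continuous state of one connection."""

    O: float = 0.0    # open fraction (fast component)
    R: float = 0.0    # activated receptor fraction (slow component)
    G: float = 0.0    # G-protein concentration, uM

    def __post_init__(self):
        if not (0.0 <= self.O <= 1.0 and 0.0 <= self.R <= 1.0 and self.G >= 0.0):
            raise ValueError("O, R in [0,1] and G >= 0 required")


# Baseline conductance totals (uS) for the small network; see network module
# for how they are shared among a cell's inputs.
SMALL_NET_CONDUCTANCES = {
    "gaba_ln_ln": 0.02,
    "gaba_ln_pn": 0.015,
    "ach_pn_ln": 0.3,
    "slow_ln_pn": 0.02,
}
LARGE_NET_CONDUCTANCES = {
    "gaba_ln_ln": 0.024,
    "gaba_ln_pn": 0.019,
    "ach_pn_ln": 0.075,
    "slow_ln_pn": 0.02,
}


def ach_transmitter(t: float, t0: float, spec: AChPulseSpec = AChPulseSpec()) -> float:
    """Transmitter concentration of a cholinergic synapse at time ``t`` for a
    presynaptic spike at ``t0``: A_t on [t0, t0 + tmax], else 0."""
    return spec.A_t if t0 <= t <= t0 + spec.tmax else 0.0


def gaba_transmitter(V_pre: float, spec: GABAReleaseSpec = GABAReleaseSpec()) -> float:
    """Sigmoidal transmitter release 1 / (1 + exp(-(V - V0)/sigma))."""
    return 1.0 / (1.0 + math.exp(-(V_pre - spec.V0) / spec.sigma))


def receptor_derivative(O: float, T: float, spec: FastSynapseSpec) -> float:
    """dO/dt = alpha (1 - O) T - beta O."""
    return spec.alpha * (1.0 - O) * T - spec.beta * O


def fast_synaptic_current(spec: FastSynapseSpec, F: float, O: float,
                          V_post: float) -> float:
    """I = gmax * F * O * (V_post - Esyn), in uA when gmax is in mS.

    ``F`` is the facilitation multiplier (1 for non-plastic synapses).
    """
    return spec.gmax * F * O * (V_post - spec.Esyn)


def slow_synapse_derivatives(state: SynapseState, T: float,
                             spec: SlowSynapseSpec):
    """(dR/dt, dG/dt) of the G-protein cascade."""
    dR = spec.r1 * (1.0 - state.R) * T - spec.r2 * state.R
    dG = spec.r3 * state.R - spec.r4 * state.G
    return dR, dG


def slow_synaptic_current(spec: SlowSynapseSpec, F: float, G: float,
                          V_post: float) -> float:
    """I = gmax * F * G^4/(G^4 + K) * (V_post - EK), uA for gmax in mS."""
    g4 = G ** 4
    return spec.gmax * F * g4 / (g4 + spec.K) * (V_post - spec.EK)
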