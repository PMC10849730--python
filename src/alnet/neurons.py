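"""Single-compartment Hodgkin-Huxley models of projection neurons (PNs) and
local neurons (LNs).

Both cell types follow

    Cm dV/dt = -gL (V - EL) - gKL (V - EKL) - sum_c I_c - I_syn + I_stim

with intrinsic currents I_c = g_c m^M h^N (V - E_c).  PNs carry Na, K, A, T
and h currents; LNs carry Na, K and T.  The printed parameters mix a total
capacitance (microfarads) with conductance densities (mS/cm^2); an explicit
membrane ``area`` reconciles the two (total conductance = density * area), so
all printed values are usable verbatim.  I_stim > 0 is depolarizing.

Units: mV, ms, uF, mS/cm^2, cm^2, uA, mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0

PN_CHANNEL_NAMES = ("Na", "K", "A", "T", "h")
LN_CHANNEL_NAMES = ("Na", "K", "T")


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters of one cell type."""

    Cm: float          # total membrane capacitance, uF
    gL: float          # leak conductance density, mS/cm^2
    gKL: float         # potassium leak conductance density, mS/cm^2
    EL: float          # leak reversal, mV
    EKL: float         # potassium leak reversal, mV
    area: float        # effective membrane area, cm^2

    def __post_init__(self):
        if self.Cm <= 0 or self.area <= 0:
            raise ValueError("Cm and area must be positive")
        if self.gL < 0 or self.gKL < 0:
            raise ValueError("conductances must be non-negative")


@dataclass(frozen=True)
class ChannelSpec:
    """One intrinsic current I = gmax * m^M * h^N * (V - E)."""

    name: str          # one of Na, K, A, T, h
    gmax: float        # maximal conductance density, mS/cm^2
    E: float           # reversal potential, mV
    M: int             # activation exponent
    N: int             # inactivation exponent (0 = no h gate)
    kinetics: str = ""  # key into kinetics.RATE_FUNCTIONS; defaults to name

    def __post_init__(self):
        if self.gmax < 0:
            raise ValueError("gmax must be non-negative")
        if self.M not in (0, 1, 2, 3, 4) or self.N not in (0, 1, 2, 3, 4):
            raise ValueError("gate exponents must be in 0..4")
        if not self.kinetics:
            object.__setattr__(self, "kinetics", self.name)


@dataclass
class GatingState:
    m: float = 0.0
    h: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("gating variables must lie in [0, 1]")


@dataclass
class CalciumState:
    Ca: float = 2.4e-4       # intracellular Ca2+, mM
    Ca_inf: float = 2.4e-4   # equilibrium concentration, mM
    A_ca: float = 5.2e-5     # current-to-concentration factor, mM*cm^2/(ms*uA)
    tau_ca: float = 5.0      # relaxation time, ms

    def __post_init__(self):
        if self.Ca < 0 or self.tau_ca <= 0:
            raise ValueError("Ca >= 0 and tau_ca > 0 required")


@dataclass
class NeuronState:
    V: float
    gating: dict[str, GatingState]
    calcium: CalciumState
    role: str                     # "PN" | "LN"
    last_spike_time: float | None = None

    def channel_names(self):
        return PN_CHANNEL_NAMES if self.role == "PN" else LN_CHANNEL_NAMES


# Passive parameters per cell type.
PN_PASSIVE = PassiveParams(Cm=2.9e-4, gL=0.01, gKL=0.012, EL=-70.0, EKL=-95.0,
                           area=2.9e-4)
LN_PASSIVE = PassiveParams(Cm=1.43e-4, gL=0.05, gKL=0.018, EL=-70.0, EKL=-95.0,
                           area=1.43e-4)

# Intrinsic channel sets.  ENa = 50 mV, EK = -95 mV, ECa = 140 mV for all
# cells; the Ih reversal is -43 mV.
PN_CHANNELS = (
    ChannelSpec("Na", 90.0, 50.0, 3, 1),
    ChannelSpec("K", 10.0, -95.0, 4, 0),
    ChannelSpec("A", 10.0, -95.0, 4, 1),
    ChannelSpec("T", 2.0, 140.0, 2, 1),
    ChannelSpec("h", 0.02, -43.0, 1, 0),
)
LN_CHANNELS = (
    ChannelSpec("Na", 100.0, 50.0, 3, 1),
    ChannelSpec("K", 10.0, -95.0, 4, 0),
    ChannelSpec("T", 1.75, 140.0, 2, 1),
)


def channels_for_role(role: str):
    if role == "PN":
        return PN_CHANNELS
    if role == "LN":
        return LN_CHANNELS
    raise ValueError(f"unknown role {role!r}")


def passive_for_role(role: str) -> PassiveParams:
    return PN_PASSIVE if role == "PN" else LN_PASSIVE


def gating_rates(V: float, channel: ChannelSpec, gate: str):
    """Steady state and relaxation time of one gate at voltage ``V``.

    ``gate`` is "activation" or "inactivation".  Raises ``ValueError`` when
    the inactivation gate of a channel with N = 0 is requested.
    """
    act, inact = kinetics.RATE_FUNCTIONS[channel.kinetics]
    if gate == "activation":
        fn = act
    elif gate == "inactivation":
        if channel.N == 0 or inact is None:
            raise ValueError(f"channel {channel.name} has no inactivation gate")
        fn = inact
    else:
        raise ValueError(f"unknown gate {gate!r}")
    x_inf, tau = fn(float(V))
    return x_inf, tau


def intrinsic_current(channel: ChannelSpec, gating: GatingState, V: float) -> float:
    """Current density gmax * m^M * h^N * (V - E) in uA/cm^2."""
    return channel.gmax * gating.m ** channel.M * gating.h ** channel.N * (V - channel.E)


def membrane_derivative(state: NeuronState, passive: PassiveParams,
                        channels, I_syn_total: float = 0.0,
                        I_stim: float = 0.0) -> float:
    """dV/dt in mV/ms for total synaptic current I_syn_total (uA, positive =
    hyperpolarizing outward) and injected current I_stim (uA, positive =
    depolarizing)."""
    names = {c.name for c in channels}
    if names != set(state.channel_names()):
        raise ValueError(f"channel set {sorted(names)} does not match role {state.role}")
    V = state.V
    a = passive.area
    I = passive.gL * a * (V - passive.EL) + passive.gKL * a * (V - passive.EKL)
    for c in channels:
        I += a * intrinsic_current(c, state.gating[c.name], V)
    I += I_syn_total
    return (-I + I_stim) / passive.Cm


def calcium_derivative(cal: CalciumState, I_T: float) -> float:
    """First-order intracellular Ca2+ model: dCa/dt = -A*I_T - (Ca - Ca_inf)/tau."""
    return -cal.A_ca * I_T - (cal.Ca - cal.Ca_inf) / cal.tau_ca


def detect_spikes(voltage_trace, dt: float,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = SPIKE_REFRACTORY_MS):
    """Spike times (ms) at upward threshold crossings of a sampled trace.

    At most one spike per contiguous supra-threshold excursion; crossings
    within ``refractory`` ms of the previous spike are ignored.
    """
    v = np.asarray(voltage_trace, dtype=float)
    if v.size == 0:
        return []
    above = v >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = []
    last = -np.inf
    for idx in crossings:
        t = idx * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return times


def initial_state(role: str, V: float | None = None) -> NeuronState:
    """Neuron state at rest: V = EL, gates at x_inf(V), Ca at equilibrium."""
    passive = passive_for_role(role)
    V0 = passive.EL if V is None else V
    gating = {}
    for c in channels_for_role(role):
        m, _ = gating_rates(V0, c, "activation")
        h = 1.0
        if c.N > 0:
            h, _ = gating_rates(V0, c, "inactivation")
        gating[c.name] = GatingState(m=m, h=h)
    return NeuronState(V=V0, gating=gating, calcium=CalciumState(), role=role)


def _derivatives(state: NeuronState, passive, channels, I_stim):
    dV = membrane_derivative(state, passive, channels, 0.0, I_stim)
    dgate = {}
    I_T = 0.0
    for c in channels:
        g = state.gating[c.name]
        m_inf, tau_m = gating_rates(state.V, c, "activation")
        dm = (m_inf - g.m) / tau_m
        dh = 0.0
        if c.N > 0:
            h_inf, tau_h = gating_rates(state.V, c, "inactivation")
            dh = (h_inf - g.h) / tau_h
        dgate[c.name] = (dm, dh)
        if c.name == "T":
            I_T = passive.area * intrinsic_current(c, g, state.V)
    dCa = calcium_derivative(state.calcium, I_T)
    return dV, dgate, dCa


def _advance(state, dV, dgate, dCa, dt):
    gating = {n: GatingState(m=min(1.0, max(0.0, g.m + dt * dgate[n][0])),
                             h=min(1.0, max(0.0, g.h + dt * dgate[n][1])))
              for n, g in state.gating.items()}
    cal = replace(state.calcium, Ca=max(0.0, state.calcium.Ca + dt * dCa))
    return NeuronState(V=state.V + dt * dV, gating=gating, calcium=cal,
                       role=state.role)


def integrate_single_neuron(role: str, I_stim, duration: float, dt: float,
                            method: str = "rk4", V0: float | None = None):
    """Reference integrator for one isolated neuron.

    ``I_stim`` is either a constant (uA) or a callable of time (ms).  Returns
    (times, voltages).  This slow, transparent path is the oracle against
    which the vectorized network engine is validated.
    """
    passive = passive_for_role(role)
    channels = channels_for_role(role)
    stim = I_stim if callable(I_stim) else (lambda t, c=float(I_stim): c)
    n_steps = int(round(duration / dt))
    state = initial_state(role, V=V0)
    times = np.arange(n_steps + 1) * dt
    volts = np.empty(n_steps + 1)
    volts[0] = state.V

    def deriv_at(s, t):
        return _derivatives(s, passive, channels, stim(t))

    for i in range(n_steps):
        t = i * dt
        if method == "euler":
            d = deriv_at(state, t)
            state = _advance(state, *d, dt)
        elif method == "rk4":
            d1 = deriv_at(state, t)
            s2 = _advance(state, *d1, dt / 2)
            d2 = deriv_at(s2, t + dt / 2)
            s3 = _advance(state, *d2, dt / 2)
            d3 = deriv_at(s3, t + dt / 2)
            s4 = _advance(state, *d3, dt)
            d4 = deriv_at(s4, t + dt)
            dV = (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0]) / 6
            dgate = {n: ((d1[1][n][0] + 2 * d2[1][n][0] + 2 * d3[1][n][0] + d4[1][n][0]) / 6,
                         (d1[1][n][1] + 2 * d2[1][n][1] + 2 * d3[1][n][1] + d4[1][n][1]) / 6)
                     for n in state.gating}
            dCa = (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2]) / 6
            state = _advance(state, dV, dgate, dCa, dt)
        else:
            raise ValueError(f"unknown method {method!r}")
        volts[i + 1] = state.V
    return times, volts
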