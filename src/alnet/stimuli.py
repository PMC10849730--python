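"""Odor stimulus construction.

An odor activates a subset of *percepts* — contiguous blocks of PNs (and,
mirroring the partition, unipolar LNs) standing for the AL footprint of one
pure volatile chemical.  Within its block, activation is a Gaussian of the
normalised block coordinate u in [-1, 1] centred on the block midpoint; the
odor's per-percept *width* is the Gaussian standard deviation on that
coordinate, so width 0.372 means the same thing for any block size.

Input current to a driven neuron is

    I(t) = amplitude * profile(neuron) * envelope(t) + noise(t)

with a 500 ms double-time-constant envelope (first-order rise, tau 66.7 ms,
during the pulse; first-order decay, tau 200 ms, after offset; unit peak)
and independent Gaussian current noise on every cell at all times.

Blend odors (PH/PP-style) assign each chemical component a percept whose
width equals the component's proportion of the blend.  Gas-sensor odors
instead convert per-sensor feature triples (dR, ema_max, ema_min) into pulse
parameters: tau_rise ~ 1/ema_max, tau_decay ~ 1/ema_min, amplitude ~ dR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

NOISE_HOLD_MS = 1.0   # noise current is resampled every millisecond


@dataclass(frozen=True)
class Percept:
    """One percept: a contiguous block of input-receiving neurons."""

    id: int
    block: tuple            # [start, stop) neuron index range

    @property
    def center(self) -> float:
        return (self.block[0] + self.block[1] - 1) / 2.0

    @property
    def size(self) -> int:
        return self.block[1] - self.block[0]


@dataclass(frozen=True)
class Odor:
    name: str
    active_percepts: frozenset       # percept ids
    widths: dict                     # percept id -> Gaussian sd (fraction of half-block)
    valence: str = "neutral"         # rewarded | habituated | neutral
    class_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "active_percepts", frozenset(self.active_percepts))
        if any(w <= 0 for w in self.widths.values()):
            raise ValueError("widths must be positive")
        if self.valence not in ("rewarded", "habituated", "neutral"):
            raise ValueError(f"unknown valence {self.valence!r}")

    def with_valence(self, valence: str) -> "Odor":
        return replace(self, valence=valence)


@dataclass(frozen=True)
class PulseSpec:
    tau_rise: float = 66.7      # ms
    tau_decay: float = 200.0    # ms
    duration: float = 500.0     # ms
    amplitude: float = 1.0      # peak current, uA

    def __post_init__(self):
        if min(self.tau_rise, self.tau_decay, self.duration) <= 0:
            raise ValueError("pulse parameters must be positive")


@dataclass(frozen=True)
class SensorFeatureTriple:
    """Per-sensor response features of one odor presentation."""

    dR: float          # response magnitude
    ema_max: float     # rise feature (> 0)
    ema_min: float     # decay feature (> 0)

    def __post_init__(self):
        if self.ema_max <= 0 or self.ema_min <= 0:
            raise ValueError("ema features must be positive")


@dataclass(frozen=True)
class StimulusParams:
    """Input gain and noise configuration.

    Amplitudes are peak injected currents (uA) for a neuron at a percept
    center; the defaults are calibrated so odor-driven PNs fire at a few
    tens of Hz during the pulse while spontaneous PN firing stays low.
    """

    amplitude_pn: float = 1.2e-3
    amplitude_ln: float = 2.4e-4
    multipolar_gain: float = 1.0    # multipolar LN drive relative to mean LN drive
    noise_sd_pn: float = 1.5e-4
    noise_sd_ln: float = 1.2e-5


def pulse_envelope(t, spec: PulseSpec = PulseSpec()):
    """Dimensionless input gain at ``t`` ms after odor onset (unit peak).

    Rises as 1 - exp(-t/tau_rise) during the pulse and decays with
    tau_decay after offset; normalised so the maximum over t equals 1.
    """
    t = np.asarray(t, dtype=float)
    norm = 1.0 - math.exp(-spec.duration / spec.tau_rise)
    rising = (1.0 - np.exp(-np.clip(t, 0.0, None) / spec.tau_rise)) / norm
    falling = np.exp(-(t - spec.duration) / spec.tau_decay)
    out = np.where(t < spec.duration, rising, falling)
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def percept_profile(odor: Odor, percept: Percept) -> np.ndarray:
    """Per-neuron activation of one active percept (1 at the block center).

    The Gaussian is evaluated on the normalised within-block coordinate
    u in [-1, 1] with the odor's width for this percept; neurons outside the
    block contribute nothing (the profile is truncated at the block edge).
    """
    if percept.id not in odor.active_percepts:
        raise ValueError(f"percept {percept.id} is not active in odor {odor.name}")
    width = odor.widths[percept.id]
    idx = np.arange(percept.block[0], percept.block[1])
    half = max(percept.size / 2.0, 0.5)
    u = (idx - percept.center) / half
    return np.exp(-0.5 * (u / width) ** 2)


def drive_profile(odor: Odor, percepts: list, n_neurons: int) -> np.ndarray:
    """Activation amplitude (unit peak) for a population partitioned into
    ``percepts``; inactive percepts contribute zero."""
    out = np.zeros(n_neurons)
    for p in percepts:
        if p.id in odor.active_percepts:
            out[p.block[0]:p.block[1]] = percept_profile(odor, p)
    return out


def percepts_from_blocks(blocks) -> list:
    return [Percept(i + 1, tuple(b)) for i, b in enumerate(blocks)]


def network_drive(odor: Odor, net, n_percepts: int,
                  params: StimulusParams = StimulusParams()) -> np.ndarray:
    """Peak input current (uA) per neuron of a network for one odor.

    PNs and unipolar LNs of active percepts receive the Gaussian profile
    scaled by their population amplitude; every multipolar LN receives
    ``multipolar_gain`` times the mean unipolar-LN drive (global input).
    """
    pn_percepts = percepts_from_blocks(net.pn_percept_blocks(n_percepts))
    pn_drive = drive_profile(odor, pn_percepts, net.n_pn)
    uni_blocks = net.uni_ln_percept_blocks(n_percepts)
    rel_blocks = [(a - net.n_pn, b - net.n_pn) for a, b in uni_blocks]
    uni_percepts = percepts_from_blocks(rel_blocks)
    uni_drive = drive_profile(odor, uni_percepts, net.n_uni)

    out = np.zeros(net.n_neurons)
    out[:net.n_pn] = params.amplitude_pn * pn_drive
    out[net.n_pn:net.n_pn + net.n_uni] = params.amplitude_ln * uni_drive
    if net.n_multi:
        mean_ln = params.amplitude_ln * uni_drive.mean()
        out[net.n_pn + net.n_uni:] = params.multipolar_gain * mean_ln
    return out


def noise_sd_per_neuron(net, params: StimulusParams = StimulusParams()) -> np.ndarray:
    sd = np.full(net.n_neurons, params.noise_sd_ln)
    sd[:net.n_pn] = params.noise_sd_pn
    return sd


def compose_odor_input(odor: Odor, net, pulse: PulseSpec, noise_sd,
                       seed: int, duration: float, odor_onset: float,
                       dt: float, n_percepts: int = 7,
                       params: StimulusParams = StimulusParams()) -> np.ndarray:
    """Full per-neuron current time series I_stim(neuron, t), uA.

    Deterministic given ``seed``; Gaussian noise (sd per neuron or scalar)
    is added to every neuron at all times, held constant over 1 ms blocks.
    This explicit materialisation is used for inspection and tests; the
    simulation engine reproduces the identical construction on the fly.
    """
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    profile = network_drive(odor, net, n_percepts, params)
    env = pulse_envelope(t - odor_onset, pulse) * pulse.amplitude
    out = profile[:, None] * env[None, :]
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (net.n_neurons,))
    if np.any(sd > 0):
        rng = np.random.default_rng(seed)
        hold = max(1, int(round(NOISE_HOLD_MS / dt)))
        n_blocks = -(-n_steps // hold)
        draws = rng.standard_normal((net.n_neurons, n_blocks)) * sd[:, None]
        out = out + np.repeat(draws, hold, axis=1)[:, :n_steps]
    return out


def blend_to_odor(proportions, name: str, valence: str = "neutral",
                  class_label: str = "", n_percepts: int = 7) -> Odor:
    """Odor from blend chemical proportions: component i maps to percept
    i+1 with Gaussian width equal to its proportion; the last percept stays
    inactive for all blend odors."""
    props = list(proportions)
    if len(props) > n_percepts - 1:
        raise ValueError("one percept must remain inactive for blend odors")
    if any(p < 0 or p > 1 for p in props):
        raise ValueError("proportions must lie in [0, 1]")
    active = {i + 1: p for i, p in enumerate(props) if p > 0}
    return Odor(name=name, active_percepts=frozenset(active),
                widths=active, valence=valence, class_label=class_label)


def sensor_features_to_pulse(triple: SensorFeatureTriple,
                             c_rise: float = 1.0, c_decay: float = 1.0,
                             c_amp: float = 1.0,
                             duration: float = 500.0) -> PulseSpec:
    """Pulse parameters from one sensor's feature triple:
    tau_rise = c_rise/ema_max, tau_decay = c_decay/ema_min,
    amplitude = c_amp * dR."""
    return PulseSpec(tau_rise=c_rise / triple.ema_max,
                     tau_decay=c_decay / triple.ema_min,
                     duration=duration,
                     amplitude=c_amp * triple.dR)


def make_odor_class(active_percepts, valence: str, class_label: str,
                    n_odors: int = 10, seed: int = 0,
                    width_low: float = 0.25, width_high: float = 0.45) -> list:
    """A class of odors sharing one active-percept set, individual odors
    differing in their per-percept Gaussian widths (drawn uniformly from
    [width_low, width_high]); deterministic given ``seed``."""
    if not active_percepts:
        raise ValueError("active percept set must be non-empty")
    if n_odors < 1:
        raise ValueError("need at least one odor")
    rng = np.random.default_rng(seed)
    odors = []
    for k in range(n_odors):
        widths = {p: float(rng.uniform(width_low, width_high))
                  for p in sorted(active_percepts)}
        odors.append(Odor(name=f"{class_label}{k + 1}",
                          active_percepts=frozenset(active_percepts),
                          widths=widths, valence=valence,
                          class_label=class_label))
    return odors
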