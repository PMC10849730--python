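"""Valence-gated facilitation of inhibitory synapses.

Every inhibitory connection (LN -> PN, LN -> LN) carries a facilitation
variable F >= 1 that multiplies its maximal conductance.  During training:

* a presynaptic LN spike while a *rewarded* odor is present adds dF_pre
  (associative facilitation, the octopamine-gated pathway);
* a postsynaptic spike while a *habituated* odor is present adds dF_post
  (nonassociative facilitation);
* between spiking events F decays toward its baseline of 1 with time
  constant tau_decay: F(t) = 1 + (F_i - 1) exp(-(t - t_i)/tau_decay).

After training, weights are frozen (no updates, no decay) for testing.  When
the animal trains in a *new* environment, connections that receive no
facilitation events relax slowly toward baseline with tau_forget >>
tau_decay ("forgetting"); a facilitation event returns the connection to the
ordinary decay regime.

Excitatory PN -> LN synapses are never plastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MODES = ("both", "associative_only", "nonassociative_only", "off")
VALENCES = ("rewarded", "habituated", "neutral")


@dataclass(frozen=True)
class PlasticitySpec:
    dF_pre: float = 0.15        # presynaptic facilitation increment
    dF_post: float = 0.15       # postsynaptic facilitation increment
    tau_decay: float = 30.0     # decay time constant, seconds
    mode: str = "both"

    def __post_init__(self):
        if self.dF_pre < 0 or self.dF_post < 0:
            raise ValueError("facilitation increments must be non-negative")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def effective_dF_pre(self) -> float:
        """dF_pre after mode gating (associative pathway)."""
        return self.dF_pre if self.mode in ("both", "associative_only") else 0.0

    @property
    def effective_dF_post(self) -> float:
        """dF_post after mode gating (nonassociative pathway)."""
        return self.dF_post if self.mode in ("both", "nonassociative_only") else 0.0


@dataclass(frozen=True)
class ForgettingSpec:
    tau_forget: float = 300.0   # relaxation toward baseline, seconds
    enabled: bool = False

    def __post_init__(self):
        if self.tau_forget <= 0:
            raise ValueError("tau_forget must be positive")


def on_spike_update(F: float, event: str, valence: str, spec: PlasticitySpec,
                    connection_kind: str = "LN->PN") -> float:
    """Facilitation value after one spike event.

    Only rewarded + presynaptic and habituated + postsynaptic combinations
    facilitate, each subject to the spec's mode gating; everything else
    leaves F unchanged.  Raises for excitatory connections, whose weights are
    never plastic.
    """
    if connection_kind not in ("LN->PN", "LN->LN"):
        raise ValueError(f"plasticity applies only to inhibitory connections, "
                         f"not {connection_kind!r}")
    if event not in ("presynaptic_spike", "postsynaptic_spike"):
        raise ValueError(f"unknown event {event!r}")
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    if F < 1.0:
        raise ValueError("F must be >= 1")
    if valence == "rewarded" and event == "presynaptic_spike":
        return F + spec.effective_dF_pre
    if valence == "habituated" and event == "postsynaptic_spike":
        return F + spec.effective_dF_post
    return F


def decay_facilitation(F_at_last_spike: float, dt_since_spike_ms: float,
                       spec: PlasticitySpec) -> float:
    """F after ``dt_since_spike_ms`` ms without events:
    1 + (F - 1) * exp(-dt / tau_decay)."""
    if dt_since_spike_ms < 0:
        raise ValueError("dt must be non-negative")
    if F_at_last_spike < 1.0:
        raise ValueError("F must be >= 1")
    tau_ms = spec.tau_decay * 1000.0
    return 1.0 + (F_at_last_spike - 1.0) * math.exp(-dt_since_spike_ms / tau_ms)


def relax_toward_baseline(F: float, dt_unreinforced_s: float,
                          spec: ForgettingSpec) -> float:
    """Slow forgetting: F relaxes toward 1 with tau_forget (seconds)."""
    if not spec.enabled:
        raise ValueError("forgetting is disabled in this spec")
    if dt_unreinforced_s < 0:
        raise ValueError("dt must be non-negative")
    return 1.0 + (F - 1.0) * math.exp(-dt_unreinforced_s / spec.tau_forget)


def facilitation_event_log(history, spec: PlasticitySpec = PlasticitySpec()):
    """Tidy log of facilitation-triggering spike events from a training
    history (list of (odor, trial_start_ms, SpikeRaster) as returned by the
    trainer with ``return_history=True``).

    Each row is one gated spike: (time_ms, neuron_id, event_type, valence,
    dF).  Presynaptic events are LN spikes during rewarded odors (every
    plastic synapse *from* that LN gained dF_pre); postsynaptic events are
    spikes of any neuron during habituated odors (every plastic synapse
    *onto* it gained dF_post).  The per-connection updates follow from the
    network's adjacency, keeping the log compact.
    """
    import pandas as pd

    rows = []
    for odor, t0, raster in history:
        if odor.valence == "rewarded" and spec.effective_dF_pre > 0:
            sel = raster.neuron_ids >= raster.n_pn      # LN spikes
            for nid, t in zip(raster.neuron_ids[sel], raster.times[sel]):
                rows.append((t0 + t, int(nid), "presynaptic_spike",
                             odor.valence, spec.effective_dF_pre))
        if odor.valence == "habituated" and spec.effective_dF_post > 0:
            for nid, t in zip(raster.neuron_ids, raster.times):
                rows.append((t0 + t, int(nid), "postsynaptic_spike",
                             odor.valence, spec.effective_dF_post))
    return pd.DataFrame(rows, columns=["time_ms", "neuron_id", "event_type",
                                       "valence", "dF"])


def freeze_weights(network):
    """Freeze the trained facilitation values of a network for testing.

    After freezing, every connection's effective conductance is fixed at
    gmax * F(end of training); trials run on a frozen network perform no
    facilitation updates and no decay.
    """
    network.freeze()
    return network
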