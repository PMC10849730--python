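"""Trial, training, testing and multi-environment protocols.

The coupled neuron/synapse system is integrated with a fixed-step classical
RK4 method (default dt = 0.04 ms).  A trial presents one odor as a 500 ms
current pulse inside a longer window (default 2 s, odor onset at 500 ms so
the first 200 ms settle-in transient is well clear of the analysis window).
Training presents a randomized sequence of rewarded/habituated odors as one
continuous simulation with plasticity on and freezes the facilitation values
at the end; testing runs probe trials on the frozen network from re-settled
initial conditions with plasticity off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .network import Network
from .plasticity import ForgettingSpec, PlasticitySpec, freeze_weights
from .raster import SpikeRaster
from .stimuli import Odor, PulseSpec, StimulusParams, network_drive, noise_sd_per_neuron

DEFAULT_DT = 0.04          # ms
SETTLE_MS = 200.0          # discarded before analysis

VALENCE_CODE = {"rewarded": 1, "habituated": -1, "neutral": 0}


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrialSpec:
    odor: Odor
    duration: float = 2000.0
    odor_onset: float = 500.0
    pulse: PulseSpec = PulseSpec()
    n_percepts: int = 7
    stim: StimulusParams = StimulusParams()
    record_lfp: bool = True

    def __post_init__(self):
        if self.odor_onset + self.pulse.duration > self.duration:
            raise ValueError("odor pulse must end within the trial")

    @property
    def odor_window(self) -> tuple:
        """The odor-stimulation analysis interval (ms)."""
        return (self.odor_onset, self.odor_onset + self.pulse.duration)


@dataclass(frozen=True)
class TrainingSchedule:
    odors: tuple                    # Odor objects with valences set
    n_presentations: int = 30
    order_seed: int = 0
    trial: TrialSpec = None         # template; its odor field is ignored

    def __post_init__(self):
        if self.trial is None:
            object.__setattr__(self, "trial", TrialSpec(odor=self.odors[0]))

    @property
    def total_time(self) -> float:
        return self.n_presentations * self.trial.duration

    def presentation_order(self) -> list:
        """Seeded randomized order in which each odor appears either
        floor or ceil of n_presentations/len(odors) times."""
        odors = list(self.odors)
        rng = np.random.default_rng(self.order_seed)
        reps, rem = divmod(self.n_presentations, len(odors))
        seq = odors * reps + [odors[i] for i in rng.choice(len(odors), rem,
                                                           replace=False)]
        return [seq[i] for i in rng.permutation(len(seq))]


@dataclass
class TrialResult:
    raster: SpikeRaster
    lfp: np.ndarray | None
    lfp_dt: float
    v_traces: np.ndarray | None = None
    v_ids: tuple = ()
    dt: float = DEFAULT_DT

    def voltage_table(self):
        """Recorded voltages as a tidy (time_ms, neuron_id, V_mV) table."""
        import pandas as pd

        if self.v_traces is None:
            raise ValueError("no voltages were recorded for this trial")
        n_ids, n_t = self.v_traces.shape
        t = np.tile(np.arange(n_t) * self.dt, n_ids)
        ids = np.repeat(np.asarray(self.v_ids, dtype=np.int64), n_t)
        return pd.DataFrame({"time_ms": t, "neuron_id": ids,
                             "V_mV": self.v_traces.reshape(-1)})


@dataclass(frozen=True)
class EnvironmentProtocol:
    env1_rewarded: tuple
    env1_habituated: tuple
    env2_rewarded: tuple
    env2_habituated: tuple
    forgetting: ForgettingSpec = ForgettingSpec(enabled=True)
    plasticity: PlasticitySpec = PlasticitySpec()
    n_presentations: int = 30
    trial: TrialSpec = None

    def __post_init__(self):
        if self.trial is None:
            object.__setattr__(self, "trial",
                               TrialSpec(odor=self.env1_rewarded[0]))


def _run_window(net: Network, trial: TrialSpec, seed: int, t0: float,
                plasticity: PlasticitySpec | None,
                forgetting: ForgettingSpec | None,
                valence: str, dt: float, record_v_ids=()):
    """Low-level wrapper around the numba kernel for one trial window."""
    n_steps = int(round(trial.duration / dt))
    profile = network_drive(trial.odor, net, trial.n_percepts, trial.stim)
    noise_sd = noise_sd_per_neuron(net, trial.stim)
    plast_on = (plasticity is not None and plasticity.mode != "off"
                and not net.frozen)
    dFpre = plasticity.effective_dF_pre if plast_on else 0.0
    dFpost = plasticity.effective_dF_post if plast_on else 0.0
    decay_fast = np.exp(-dt / (plasticity.tau_decay * 1000.0)) if plast_on else 1.0
    forgetting_on = bool(forgetting is not None and forgetting.enabled
                         and plast_on)
    decay_slow = (np.exp(-dt / (forgetting.tau_forget * 1000.0))
                  if forgetting_on else decay_fast)
    pre_ptr, pre_idx, post_ptr, post_idx = net.adjacency_csr()

    cap = int(net.n_neurons * max(64, trial.duration))  # generous: <=1 kHz
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_time = np.empty(cap)
    lfp_every = max(1, int(round(1.0 / dt)))
    n_lfp = (n_steps // lfp_every) + 1 if trial.record_lfp else 0
    lfp = np.empty(n_lfp)
    rec_ids = np.asarray(record_v_ids, dtype=np.int64)
    v_rec = np.empty((len(rec_ids), n_steps + 1))

    n_gaba = net.sl_ln_ln.stop            # fast GABA_A entries come first
    n_ach = net.sl_pn_ln.stop - net.sl_pn_ln.start
    n_spk = _engine.run_window(
        net.V, net.gate, net.ca, net.O_gaba, net.O_ach, net.R_slow,
        net.G_slow, net.last_spike, net.above,
        net.is_pn, net.n_pn, net.cm, net.gl, net.gkl, net.gch, net.area,
        net.pre, net.post, net.g, net.F, net.plastic,
        net.env_reinforced, n_gaba, n_ach,
        pre_ptr, pre_idx, post_ptr, post_idx,
        profile, t0 + trial.odor_onset, trial.pulse.duration,
        trial.pulse.tau_rise, trial.pulse.tau_decay, trial.pulse.amplitude,
        noise_sd, int(seed) % (2 ** 31), t0, n_steps, dt,
        plast_on, VALENCE_CODE[valence], dFpre, dFpost,
        decay_fast, decay_slow, forgetting_on,
        _engine.KINETICS_TABLE, spike_neuron, spike_time, lfp, lfp_every,
        rec_ids, v_rec)
    if n_spk < 0:
        raise IntegrationError(
            f"non-finite state in neuron {-(n_spk + 1)} during trial of "
            f"odor {trial.odor.name!r} starting at t={t0} ms")
    raster = SpikeRaster(spike_neuron[:n_spk].copy(),
                         spike_time[:n_spk] - t0,
                         net.n_neurons, net.n_pn, trial.duration,
                         odor=trial.odor.name, seed=seed)
    return TrialResult(raster, lfp if trial.record_lfp else None,
                       lfp_every * dt,
                       v_rec if len(rec_ids) else None,
                       tuple(int(i) for i in rec_ids), dt)


def rk4_step(net: Network, i_stim=None, t: float = 0.0,
             dt: float = DEFAULT_DT) -> list:
    """Advance the whole coupled system by one RK4 step.

    ``i_stim`` is the per-neuron injected current (uA) held over the step
    (default zero).  Spike events detected on the updated voltages are
    returned as a list of neuron indices; the network state is mutated in
    place.  This is the primitive the trial runners are built on — use
    :func:`run_trial` for anything longer than a few steps.
    """
    profile = np.zeros(net.n_neurons) if i_stim is None \
        else np.asarray(i_stim, dtype=float)
    pre_ptr, pre_idx, post_ptr, post_idx = net.adjacency_csr()
    n_gaba = net.sl_ln_ln.stop
    n_ach = net.sl_pn_ln.stop - net.sl_pn_ln.start
    spike_neuron = np.empty(net.n_neurons, dtype=np.int64)
    spike_time = np.empty(net.n_neurons)
    n_spk = _engine.run_window(
        net.V, net.gate, net.ca, net.O_gaba, net.O_ach, net.R_slow,
        net.G_slow, net.last_spike, net.above,
        net.is_pn, net.n_pn, net.cm, net.gl, net.gkl, net.gch, net.area,
        net.pre, net.post, net.g, net.F, net.plastic, net.env_reinforced,
        n_gaba, n_ach, pre_ptr, pre_idx, post_ptr, post_idx,
        # constant unit envelope: onset far in the past, instant rise,
        # effectively infinite pulse, so i_stim is held over the step
        profile, -1e9, 1e18, 1e-9, 1.0, 1.0,
        np.zeros(net.n_neurons), 0, t, 1, dt,
        False, 0, 0.0, 0.0, 1.0, 1.0, False,
        _engine.KINETICS_TABLE, spike_neuron, spike_time,
        np.empty(0), 1, np.empty(0, dtype=np.int64), np.empty((0, 2)))
    if n_spk < 0:
        raise IntegrationError(
            f"non-finite state in neuron {-(n_spk + 1)} at t={t} ms")
    return list(spike_neuron[:n_spk])


def run_trial(net: Network, trial: TrialSpec, seed: int,
              plasticity: PlasticitySpec | None = None,
              forgetting: ForgettingSpec | None = None,
              dt: float = DEFAULT_DT, reset: bool = True, t0: float = 0.0,
              record_v_ids=()) -> TrialResult:
    """Run one trial.  With ``reset`` the network starts from re-settled
    initial conditions (testing convention); training protocols pass
    ``reset=False`` to carry state across presentations.  Plasticity is
    applied per the odor's valence when a spec is given and the network is
    not frozen."""
    if reset:
        net.reset_state()
    return _run_window(net, trial, seed, t0, plasticity, forgetting,
                       trial.odor.valence, dt, record_v_ids)


def run_training(net: Network, schedule: TrainingSchedule, seed: int,
                 plasticity: PlasticitySpec = PlasticitySpec(),
                 forgetting: ForgettingSpec | None = None,
                 dt: float = DEFAULT_DT, freeze: bool = True,
                 new_environment: bool = False,
                 return_history: bool = False):
    """Train a network on one odor sequence as a continuous simulation.

    Presents the schedule's odors in seeded random order with plasticity on,
    then (by default) freezes the facilitation values for testing.  With
    ``new_environment`` the per-connection reinforcement flags are cleared
    first, so that connections receiving no facilitation events relax with
    the slow forgetting time constant instead of the ordinary decay.
    """
    if net.frozen:
        net.frozen = False          # resume plasticity (e.g. Env2 training)
    if new_environment:
        net.reset_environment_flags()
    net.reset_state()
    order = schedule.presentation_order()
    t0 = 0.0
    history = []
    for k, odor in enumerate(order):
        trial = replace(schedule.trial, odor=odor)
        res = _run_window(net, trial, seed + 1000 * k, t0, plasticity,
                          forgetting, odor.valence, dt)
        if return_history:
            history.append((odor, t0, res.raster))
        t0 += trial.duration
    if freeze:
        freeze_weights(net)
    if return_history:
        return net, history
    return net


def run_probes(net: Network, odors, trial_template: TrialSpec, seed: int,
               n_trials: int = 1, dt: float = DEFAULT_DT,
               probe_duration: float | None = None) -> dict:
    """Plasticity-off test trials: ``n_trials`` per odor from re-settled
    initial conditions; returns {odor name: [SpikeRaster, ...]}.

    ``probe_duration`` optionally shortens probe trials relative to the
    training template (the analysis window only spans the odor pulse)."""
    out = {}
    for oi, odor in enumerate(odors):
        trial = replace(trial_template, odor=odor.with_valence("neutral"))
        if probe_duration is not None:
            trial = replace(trial, duration=probe_duration)
        rasters = []
        for k in range(n_trials):
            res = run_trial(net, trial, seed + 7919 * oi + 104729 * k, dt=dt)
            r = res.raster
            r.odor = odor.name
            rasters.append(r)
        out[odor.name] = rasters
    return out


CONDITIONS = ("naive", "absolute", "differential", "associative_only",
              "nonassociative_only")


def run_condition_suite(naive: Network, rewarded, habituated,
                        conditions=CONDITIONS, n_presentations: int = 30,
                        n_trials: int = 1, seed: int = 0,
                        trial: TrialSpec | None = None,
                        probe_odors=None, dt: float = DEFAULT_DT,
                        probe_duration: float | None = None) -> dict:
    """Train fresh copies of one naive network under each conditioning
    condition and probe them with plasticity off (paired design: every
    condition starts from the identical naive network).

    * naive — no training;
    * absolute — rewarded odors only, both plasticity pathways on;
    * differential — rewarded + habituated odors, both pathways on;
    * associative_only / nonassociative_only — rewarded + habituated odors
      with only the presynaptic / postsynaptic pathway enabled.
    """
    if trial is None:
        trial = TrialSpec(odor=rewarded[0])
    if probe_odors is None:
        probe_odors = list(rewarded) + list(habituated)
    results = {}
    for cond in conditions:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        net = naive.clone()
        if cond != "naive":
            odors = list(rewarded) if cond == "absolute" \
                else list(rewarded) + list(habituated)
            mode = {"absolute": "both", "differential": "both",
                    "associative_only": "associative_only",
                    "nonassociative_only": "nonassociative_only"}[cond]
            schedule = TrainingSchedule(tuple(odors), n_presentations,
                                        order_seed=seed, trial=trial)
            run_training(net, schedule, seed,
                         PlasticitySpec(mode=mode), dt=dt)
        rasters = run_probes(net, probe_odors, trial, seed + 1, n_trials, dt,
                             probe_duration)
        for rs in rasters.values():
            for r in rs:
                r.condition = cond
        results[cond] = {"network": net, "rasters": rasters}
    return results


def run_environment_protocol(naive: Network, protocol: EnvironmentProtocol,
                             seed: int, n_trials: int = 1,
                             dt: float = DEFAULT_DT,
                             probe_duration: float | None = None,
                             probe_odors=None) -> dict:
    """Sequential training on two environments with slow forgetting.

    Probes every odor class at three stages (naive, after Env1, after Env2)
    with plasticity off; returns
    {stage: {"rasters": {odor: [...]}, "network": Network}}.
    """
    trial = protocol.trial
    if probe_odors is None:
        probe = (list(protocol.env1_rewarded) + list(protocol.env1_habituated)
                 + list(protocol.env2_rewarded)
                 + list(protocol.env2_habituated))
        # drop duplicates by name (overlapping environments may share odors)
        seen, probe_odors = set(), []
        for o in probe:
            if o.name not in seen:
                seen.add(o.name)
                probe_odors.append(o)

    out = {}
    net = naive.clone()
    out["naive"] = {"rasters": run_probes(net, probe_odors, trial, seed + 11,
                                          n_trials, dt, probe_duration),
                    "network": net.clone()}
    env1 = TrainingSchedule(
        tuple(list(protocol.env1_rewarded) + list(protocol.env1_habituated)),
        protocol.n_presentations, order_seed=seed, trial=trial)
    run_training(net, env1, seed, protocol.plasticity, protocol.forgetting,
                 dt=dt, new_environment=True)
    out["post_env1"] = {"rasters": run_probes(net, probe_odors, trial,
                                              seed + 13, n_trials, dt,
                                              probe_duration),
                        "network": net.clone()}
    env2 = TrainingSchedule(
        tuple(list(protocol.env2_rewarded) + list(protocol.env2_habituated)),
        protocol.n_presentations, order_seed=seed + 1, trial=trial)
    run_training(net, env2, seed + 2, protocol.plasticity,
                 protocol.forgetting, dt=dt, new_environment=True)
    out["post_env2"] = {"rasters": run_probes(net, probe_odors, trial,
                                              seed + 17, n_trials, dt,
                                              probe_duration),
                        "network": net.clone()}
    return out
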