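"""Sequential learning in two odor environments with slow forgetting.

Case 1 layout: environment 1 holds classes P (rewarded) and Q (habituated);
environment 2 holds classes S/T built on entirely different percepts.
The P/Q representation correlation is probed naive, after training on Env1,
and after training on Env2.  Facilitated connections that receive no
reinforcement in the new environment relax slowly toward baseline.
"""

from alnet import analysis, network, simulator, synthetic
from alnet.plasticity import ForgettingSpec

net = network.build_reduced_network(seed=0, n_glomeruli=4)
env1, env2, _ = synthetic.generate_environment_suite(case=1,
                                                     valence_variant="consistent",
                                                     seed=0, n_odors=5)
trial = simulator.TrialSpec(odor=env1["P"][0], duration=1500.0,
                            odor_onset=300.0, n_percepts=8)
proto = simulator.EnvironmentProtocol(
    env1_rewarded=tuple(env1["P"]), env1_habituated=tuple(env1["Q"]),
    env2_rewarded=tuple(env2["S"]), env2_habituated=tuple(env2["T"]),
    forgetting=ForgettingSpec(tau_forget=75.0, enabled=True),
    n_presentations=10, trial=trial)

res = simulator.run_environment_protocol(
    net, proto, seed=0, n_trials=2, probe_duration=1000.0,
    probe_odors=list(env1["P"][:2]) + list(env1["Q"][:2]))

pn = [o.name for o in env1["P"][:2]]
qn = [o.name for o in env1["Q"][:2]]
for stage in ("naive", "post_env1", "post_env2"):
    c = analysis.class_correlation(res[stage]["rasters"], pn, qn,
                                   trial.odor_window)
    print(f"corr(P, Q) {stage:>10}: {c:+.3f}")

# Training on Env1 separates P from Q (the correlation drops); what happens
# after Env2 depends on how much of the Env1 structure is left untouched
# versus re-reinforced by the new odors.
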