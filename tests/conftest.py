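"""Shared fixtures.

Heavy spiking-network experiments are computed once per session and shared
across tests.  All simulation-based checks run on a reduced
4-glomerulus network (20 PNs / 56 LNs) with shortened trials (1.5 s
training trials, 1 s probes, odor onset 300 ms) and 10-presentation
training; these problem sizes keep the whole suite within a desktop time
budget while preserving the protocols' structure.
"""

import numpy as np
import pytest

from alnet import analysis, network, simulator, synthetic
from alnet.plasticity import ForgettingSpec
from alnet.simulator import TrialSpec

MICRO_GLOM = 4
N_ODORS = 5
N_PRES = 10
PROBE_TRIALS = 2
PROBE_DURATION = 1000.0
TRIAL_KW = dict(duration=1500.0, odor_onset=300.0)


def micro_network(seed, **kw):
    return network.build_reduced_network(seed, n_glomeruli=MICRO_GLOM, **kw)


def single_neuron_network(role="PN"):
    """A degenerate 'network' holding one isolated neuron, for validating
    the vectorized engine against the reference integrator."""
    net = network.Network(variant="single", seed=0,
                          n_pn=1 if role == "PN" else 0,
                          n_uni=0 if role == "PN" else 1, n_multi=0)
    (net.is_pn, net.cm, net.gl, net.gkl, net.gch, net.area) = \
        network._neuron_arrays(net.n_pn, net.n_ln)
    return network._finalize(net, [], [], [],
                             dict(gaba_ln_ln=0, gaba_ln_pn=0, ach_pn_ln=0,
                                  slow_ln_pn=0))


def run_conditioning(seed, conditions, n_trials=PROBE_TRIALS):
    """One full conditioning experiment on the micro network: train fresh
    copies of one naive network per condition and probe 3 odors per class."""
    net = micro_network(seed)
    rew, hab, truth = synthetic.generate_minimal_classes(seed, n_odors=N_ODORS)
    trial = TrialSpec(odor=rew[0], **TRIAL_KW)
    win = trial.odor_window
    probe_rew, probe_hab = rew[:3], hab[:3]
    res = simulator.run_condition_suite(
        net, rew, hab, conditions=conditions, n_presentations=N_PRES,
        n_trials=n_trials, seed=seed * 100, trial=trial,
        probe_odors=probe_rew + probe_hab, probe_duration=PROBE_DURATION)
    rew_names = [o.name for o in probe_rew]
    hab_names = [o.name for o in probe_hab]
    blocks = net.pn_percept_blocks(7)

    out = {"net": net, "odors": (rew, hab), "window": win, "truth": truth,
           "results": res, "corr": {}, "acts": {}}
    for cond, r in res.items():
        out["corr"][cond] = analysis.class_correlation(
            r["rasters"], rew_names, hab_names, win)
        act_rew = np.mean([analysis.unit_activity(r["rasters"][n], blocks, win)
                           for n in rew_names], axis=0)
        act_hab = np.mean([analysis.unit_activity(r["rasters"][n], blocks, win)
                           for n in hab_names], axis=0)
        out["acts"][cond] = (act_rew, act_hab)
    return out


@pytest.fixture(scope="session")
def conditioning_suite():
    """Seeds 0-4, all four conditions; shared by several acceptance tests."""
    conds = ("naive", "differential", "associative_only",
             "nonassociative_only")
    return {seed: run_conditioning(seed, conds) for seed in range(5)}


@pytest.fixture(scope="session")
def shuffle_suite(conditioning_suite):
    """Paired structured-vs-shuffled decorrelation over 10 seeds (the first
    five reuse the conditioning suite's differential networks)."""
    pairs = []
    for seed in range(10):
        if seed < 5:
            data = conditioning_suite[seed]
        else:
            data = run_conditioning(seed, ("differential",))
        rew, hab = data["odors"]
        win = data["window"]
        trial = TrialSpec(odor=rew[0], **TRIAL_KW)
        rew_names = [o.name for o in rew[:3]]
        hab_names = [o.name for o in hab[:3]]
        trained = data["results"]["differential"]["network"]
        shuffled = network.shuffle_inhibitory_weights(trained, seed + 991)
        rasters = simulator.run_probes(shuffled, rew[:3] + hab[:3], trial,
                                       seed * 100 + 1, PROBE_TRIALS,
                                       probe_duration=PROBE_DURATION)
        corr_sh = analysis.class_correlation(rasters, rew_names, hab_names,
                                             win)
        pairs.append((data["corr"]["differential"], corr_sh))
    return pairs


@pytest.fixture(scope="session")
def environment_suite():
    """Sequential-environment runs for the overlap cases checked in the
    suite: case 1 (no overlap) and case 2 (full overlap) with both valence
    assignments; 2 seeds each."""
    out = {}
    for case, variant in ((1, "consistent"), (2, "consistent"),
                          (2, "reversed")):
        runs = []
        for seed in (0, 1):
            net = micro_network(seed)
            env1, env2, _ = synthetic.generate_environment_suite(
                case, variant, seed * 10, n_odors=N_ODORS)
            trial = TrialSpec(odor=env1["P"][0], n_percepts=8, **TRIAL_KW)
            e2 = list(env2.values())
            proto = simulator.EnvironmentProtocol(
                env1_rewarded=tuple(env1["P"]),
                env1_habituated=tuple(env1["Q"]),
                env2_rewarded=tuple(c for c in e2
                                    if c[0].valence == "rewarded")[0],
                env2_habituated=tuple(c for c in e2
                                      if c[0].valence == "habituated")[0],
                forgetting=ForgettingSpec(tau_forget=75.0, enabled=True),
                n_presentations=N_PRES, trial=trial)
            probe = list(env1["P"][:2]) + list(env1["Q"][:2])
            for cls in env2.values():
                probe += [o for o in cls[:2]
                          if o.name not in {p.name for p in probe}]
            res = simulator.run_environment_protocol(
                net, proto, seed=seed * 100, n_trials=PROBE_TRIALS,
                probe_duration=PROBE_DURATION, probe_odors=probe)
            win = trial.odor_window
            pn = [o.name for o in env1["P"][:2]]
            qn = [o.name for o in env1["Q"][:2]]
            runs.append({stage: analysis.class_correlation(
                res[stage]["rasters"], pn, qn, win)
                for stage in ("naive", "post_env1", "post_env2")})
        out[(case, variant)] = runs
    return out


@pytest.fixture(scope="session")
def blend_suite():
    """Differential conditioning on blend-proportion (flower-variety-like)
    odor classes, with the per-percept contrast-enhancement fit."""
    ph_means = [0.372, 0.25, 0.15, 0.10, 0.08, 0.048]
    pp_means = [0.05, 0.10, 0.20, 0.30, 0.25, 0.10]
    out = []
    for seed in (0,):
        net = micro_network(seed)
        ph, pp, _ = synthetic.generate_blend_classes(
            [ph_means, pp_means], seed, n_odors_per_class=N_ODORS)
        trial = TrialSpec(odor=ph[0], **TRIAL_KW)
        win = trial.odor_window
        res = simulator.run_condition_suite(
            net, ph, pp, conditions=("naive", "differential"),
            n_presentations=N_PRES, n_trials=PROBE_TRIALS, seed=seed * 100,
            trial=trial, probe_odors=ph[:3] + pp[:3],
            probe_duration=PROBE_DURATION)
        blocks = net.pn_percept_blocks(7)
        phn = [o.name for o in ph[:3]]
        ppn = [o.name for o in pp[:3]]

        def act(cond, names):
            return np.mean([analysis.unit_activity(
                res[cond]["rasters"][n], blocks, win) for n in names], axis=0)

        recs = analysis.percept_uniqueness_records(
            act("naive", phn), act("naive", ppn), act("differential", phn))
        out.append({
            "corr_naive": analysis.class_correlation(res["naive"]["rasters"],
                                                     phn, ppn, win),
            "corr_diff": analysis.class_correlation(
                res["differential"]["rasters"], phn, ppn, win),
            "fit": analysis.contrast_enhancement_fit(recs)
            if len(recs) >= 3 else None,
        })
    return out


@pytest.fixture(scope="session")
def gcn_suite():
    """Trained GCN on the surrogate sensor dataset plus its baselines."""
    from alnet import gcn

    df, truth = synthetic.generate_sensor_dataset(seed=5)
    model, res = gcn.train(df, gcn.GCNSpec(), seed=5)
    _, res_ablated = gcn.train(df, gcn.GCNSpec(reward_edges_enabled=False),
                               seed=5)
    labels = (df["valence"] == "habituated").to_numpy().astype(int)
    majority = max(np.mean(labels[res["test_idx"]]),
                   1 - np.mean(labels[res["test_idx"]]))
    records, fit = gcn.layer_uniqueness_analysis(model, df)
    return {"df": df, "model": model, "result": res,
            "ablated": res_ablated, "majority": majority,
            "records": records, "fit": fit}
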