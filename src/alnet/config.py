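"""Structured configuration files (YAML) for network, stimulus, plasticity
and odor definitions, plus tabular export helpers.

A config file has one section per concern::

    neurons:
      PN: {Cm: 2.9e-4, gL: 0.01, gKL: 0.012, EL: -70, EKL: -95, area: 2.9e-4,
           channels: {Na: 90.0, K: 10.0, A: 10.0, T: 2.0, h: 0.02}}
      LN: {...}
    synapses: {gaba_ln_ln: 0.02, gaba_ln_pn: 0.015, ach_pn_ln: 0.3,
               slow_ln_pn: 0.02}
    stimulus: {amplitude_pn: ..., amplitude_ln: ..., multipolar_gain: ...,
               noise_sd_pn: ..., noise_sd_ln: ...}
    plasticity: {dF_pre: 0.15, dF_post: 0.15, tau_decay: 30.0, mode: both}
    forgetting: {tau_forget: 300.0, enabled: false}
    odors:
      - {name: A1, class: A, valence: rewarded, percepts: [1, 2, 3],
         widths: {1: 0.3, 2: 0.35, 3: 0.4}}

Every section is optional; omitted values fall back to the package defaults.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from . import neurons
from .plasticity import ForgettingSpec, PlasticitySpec
from .stimuli import Odor, StimulusParams
from .synapses import SMALL_NET_CONDUCTANCES


def default_config() -> dict:
    cfg = {"neurons": {}, "synapses": dict(SMALL_NET_CONDUCTANCES)}
    for role in ("PN", "LN"):
        p = neurons.passive_for_role(role)
        cfg["neurons"][role] = {
            "Cm": p.Cm, "gL": p.gL, "gKL": p.gKL, "EL": p.EL, "EKL": p.EKL,
            "area": p.area,
            "channels": {c.name: c.gmax for c in neurons.channels_for_role(role)},
        }
    cfg["stimulus"] = asdict(StimulusParams())
    cfg["plasticity"] = asdict(PlasticitySpec())
    cfg["forgetting"] = asdict(ForgettingSpec())
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, values in user.items():
        if section == "odors":
            cfg["odors"] = values
        elif section in cfg and isinstance(values, dict):
            for k, v in values.items():
                if isinstance(v, dict) and isinstance(cfg[section].get(k), dict):
                    cfg[section][k].update(v)
                else:
                    cfg[section][k] = v
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def stimulus_from_config(cfg: dict) -> StimulusParams:
    return StimulusParams(**cfg.get("stimulus", {}))


def plasticity_from_config(cfg: dict) -> PlasticitySpec:
    return PlasticitySpec(**cfg.get("plasticity", {}))


def forgetting_from_config(cfg: dict) -> ForgettingSpec:
    return ForgettingSpec(**cfg.get("forgetting", {}))


def passive_from_config(cfg: dict, role: str) -> neurons.PassiveParams:
    sec = cfg["neurons"][role]
    return neurons.PassiveParams(Cm=sec["Cm"], gL=sec["gL"], gKL=sec["gKL"],
                                 EL=sec["EL"], EKL=sec["EKL"],
                                 area=sec["area"])


def odors_to_config(odors) -> list:
    return [{"name": o.name, "class": o.class_label, "valence": o.valence,
             "percepts": sorted(o.active_percepts),
             "widths": {int(k): float(v) for k, v in o.widths.items()}}
            for o in odors]


def odors_from_config(entries) -> list:
    out = []
    for e in entries:
        widths = {int(k): float(v) for k, v in e["widths"].items()}
        out.append(Odor(name=e["name"], active_percepts=frozenset(e["percepts"]),
                        widths=widths, valence=e.get("valence", "neutral"),
                        class_label=e.get("class", "")))
    return out
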