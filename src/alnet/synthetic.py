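"""Seed-deterministic generators for every input class the pipeline needs.

* minimal two-class odor layout (class A on percepts {1,2,3} rewarded,
  class B on {2,3,4} habituated, 10 odors per class differing in percept
  widths);
* blend-proportion classes emulating two flower varieties sharing the same
  six volatile components at different ratios;
* the four environment-overlap layouts used for sequential-learning
  experiments;
* a surrogate gas-sensor feature table (6 odor classes x 16 sensors x 8
  features with class-dependent means, including the (dR, ema_max, ema_min)
  pulse-feature triple);
* calcium-imaging-like 24-glomerulus response matrices with a planted
  uniqueness-index/activity-change relationship for recovery tests.

Each generator returns data plus a ground-truth sidecar dict so downstream
recovery tests are self-contained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimuli import Odor, make_odor_class

# ---------------------------------------------------------------------------
# odor classes


def generate_minimal_classes(seed: int, n_odors: int = 10,
                             n_trailing_inactive: int = 3):
    """The minimal differential-conditioning layout: rewarded class A on
    percepts {1,2,3}, habituated class B on {2,3,4} (overlap {2,3})."""
    a = make_odor_class({1, 2, 3}, "rewarded", "A", n_odors, seed=seed)
    b = make_odor_class({2, 3, 4}, "habituated", "B", n_odors, seed=seed + 1)
    truth = {"overlap": {2, 3}, "unique_rewarded": {1},
             "unique_habituated": {4},
             "inactive": set(range(5, 5 + n_trailing_inactive))}
    return a, b, truth


def generate_blend_classes(class_means, seed: int, n_odors_per_class: int = 10,
                           dispersion: float = 200.0, names=("PH", "PP"),
                           valences=("rewarded", "habituated")):
    """Blend-proportion odor classes: same components, different ratios.

    ``class_means``: (n_classes, n_components) mean proportions, each row on
    the simplex.  Per-odor proportions are Dirichlet draws concentrated
    around the class mean (concentration = dispersion * mean); component i
    maps to percept i+1 with Gaussian width equal to its proportion, and the
    last percept stays inactive.  dispersion -> infinity recovers the class
    means exactly.
    """
    means = np.asarray(class_means, dtype=float)
    if np.any(means < 0) or not np.allclose(means.sum(axis=1), 1.0):
        raise ValueError("class means must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    classes = []
    for c, mean in enumerate(means):
        odors = []
        for k in range(n_odors_per_class):
            if np.isfinite(dispersion):
                props = rng.dirichlet(dispersion * mean)
            else:
                props = mean.copy()
            widths = {i + 1: float(p) for i, p in enumerate(props) if p > 0}
            odors.append(Odor(name=f"{names[c]}{k + 1}",
                              active_percepts=frozenset(widths),
                              widths=widths, valence=valences[c],
                              class_label=names[c]))
        classes.append(odors)
    truth = {"class_means": means, "dispersion": dispersion}
    return (*classes, truth)


ENVIRONMENT_CASES = {
    # percept sets (rewarded-in-Env1 P, habituated-in-Env1 Q, Env2 pair)
    1: {"P": {1, 2, 3}, "Q": {2, 3, 4}, "E2a": {5, 6, 7}, "E2b": {6, 7, 8},
        "E2_names": ("S", "T")},
    2: {"P": {1, 2, 3}, "Q": {2, 3, 4}, "E2a": {1, 2, 3}, "E2b": {2, 3, 4},
        "E2_names": ("M", "N")},
    3: {"P": {1, 2, 3}, "Q": {2, 3, 4}, "E2a": {1, 2, 3}, "E2b": {5, 6, 7},
        "E2_names": ("M", "S")},
    4: {"P": {1, 2, 3}, "Q": {2, 3, 4}, "E2a": {2, 3, 4}, "E2b": {5, 6, 7},
        "E2_names": ("N", "S")},
}
N_PERCEPTS_ENVIRONMENT = 8


def generate_environment_suite(case: int, valence_variant: str, seed: int,
                               n_odors: int = 10):
    """Env1 + Env2 odor classes for one of the four overlap cases.

    Env1 is always P+ (rewarded) / Q- (habituated).  ``valence_variant``:
    "consistent" rewards the Env2 class aligned with P (first of the pair),
    "reversed" swaps the Env2 valences.  Case layouts: 1 - no overlap
    (S, T fresh percepts); 2 - full overlap (M ~ P, N ~ Q); 3 - M ~ P plus
    fresh S; 4 - N ~ Q plus fresh S.
    """
    if case not in ENVIRONMENT_CASES:
        raise ValueError("case must be 1..4")
    if valence_variant not in ("consistent", "reversed"):
        raise ValueError("valence_variant must be consistent|reversed")
    lay = ENVIRONMENT_CASES[case]
    val_a, val_b = (("rewarded", "habituated")
                    if valence_variant == "consistent"
                    else ("habituated", "rewarded"))
    name_a, name_b = lay["E2_names"]
    env1 = {
        "P": make_odor_class(lay["P"], "rewarded", "P", n_odors, seed=seed),
        "Q": make_odor_class(lay["Q"], "habituated", "Q", n_odors,
                             seed=seed + 1),
    }
    env2 = {
        name_a: make_odor_class(lay["E2a"], val_a, name_a, n_odors,
                                seed=seed + 2),
        name_b: make_odor_class(lay["E2b"], val_b, name_b, n_odors,
                                seed=seed + 3),
    }
    truth = {"case": case, "variant": valence_variant,
             "percepts": {**{k: lay[k] for k in ("P", "Q")},
                          name_a: lay["E2a"], name_b: lay["E2b"]}}
    return env1, env2, truth


# ---------------------------------------------------------------------------
# surrogate gas-sensor dataset

N_SENSORS = 16
N_FEATURES = 8
FEATURE_NAMES = ("dR", "ema_max", "ema_min", "f3", "f4", "f5", "f6", "f7")


def generate_sensor_dataset(seed: int, n_classes: int = 6,
                            n_samples_per_class: int = 60,
                            within_class_sd: float = 0.08,
                            drift_sd: float = 0.03) -> tuple:
    """Surrogate for a gas-sensor-array recording session.

    Returns (DataFrame, truth).  Each sample row carries 16 sensors x 8
    features plus a class label and a valence (the first 3 classes rewarded,
    the last 3 habituated).  Class-conditional feature means differ by
    construction; ema features stay positive (they become reciprocal time
    constants downstream); a drift-like additive noise term is shared by all
    features of a sample.
    """
    rng = np.random.default_rng(seed)
    # class-mean tensor (classes, sensors, features)
    base = rng.uniform(0.5, 1.5, size=(1, N_SENSORS, N_FEATURES))
    sep = rng.normal(0.0, 0.35, size=(n_classes, N_SENSORS, N_FEATURES))
    means = base + sep
    # keep pulse-feature scales realistic: dR ~ O(1), ema ~ 5e-3..2e-2
    means[:, :, 0] = np.abs(means[:, :, 0])
    means[:, :, 1] = 0.015 * np.abs(means[:, :, 1])
    means[:, :, 2] = 0.005 * np.abs(means[:, :, 2])

    rows = []
    for c in range(n_classes):
        for k in range(n_samples_per_class):
            drift = rng.normal(0.0, drift_sd)
            feats = means[c] * (1.0 + rng.normal(0.0, within_class_sd,
                                                 size=(N_SENSORS, N_FEATURES))
                                + drift)
            feats[:, 1:3] = np.abs(feats[:, 1:3]) + 1e-6
            row = {"sample": c * n_samples_per_class + k, "odor_class": c,
                   "valence": "rewarded" if c < n_classes // 2 else "habituated"}
            for s in range(N_SENSORS):
                for f, name in enumerate(FEATURE_NAMES):
                    row[f"s{s:02d}_{name}"] = feats[s, f]
            rows.append(row)
    df = pd.DataFrame(rows)
    truth = {"class_means": means, "within_class_sd": within_class_sd,
             "drift_sd": drift_sd}
    return df, truth


def sensor_feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n_samples, 16, 8) feature tensor from the dataset table."""
    cols = [f"s{s:02d}_{n}" for s in range(N_SENSORS) for n in FEATURE_NAMES]
    return df[cols].to_numpy(dtype=float).reshape(len(df), N_SENSORS,
                                                  N_FEATURES)


# ---------------------------------------------------------------------------
# calcium-imaging-like glomerular patterns


def generate_glomerular_patterns(seed: int, n_glomeruli: int = 24,
                                 slope: float = 0.5, noise_sd: float = 0.0):
    """Reference/differential glomerular response vectors with a planted
    contrast-enhancement relationship.

    Reference activities of each glomerulus for rewarded and habituated
    odors are positive draws; after "differential conditioning" the rewarded
    response changes by exactly ``slope`` * UI (plus optional noise), so the
    change-vs-UI regression recovers the planted slope (exactly at zero
    noise).  Returns (DataFrame, truth).
    """
    if slope <= 0 or slope >= 1:
        raise ValueError("planted slope must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    act_rew = rng.uniform(0.5, 2.0, n_glomeruli)
    act_hab = rng.uniform(0.5, 2.0, n_glomeruli)
    ui = (act_rew - act_hab) / act_hab
    change = slope * ui + rng.normal(0.0, noise_sd, n_glomeruli)
    act_rew_post = act_rew * (1.0 + change)
    df = pd.DataFrame({"glomerulus": np.arange(n_glomeruli),
                       "act_rew_ref": act_rew, "act_hab_ref": act_hab,
                       "act_rew_diff": act_rew_post})
    truth = {"slope": slope, "noise_sd": noise_sd, "UI": ui}
    return df, truth
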