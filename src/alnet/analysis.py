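"""Representation statistics for odor responses.

The central quantity is the similarity of two odor representations:
population vectors of normalized binned PN spike counts (100 ms bins over
the 500 ms stimulation window) are compared bin by bin with Pearson
correlation and averaged over bins and trial pairs.  Decorrelation of
rewarded vs. habituated representations after differential conditioning is
the model's signature of learning.

Also here: PCA response trajectories (40 ms bins), the per-unit uniqueness
index UI = (act_rew - act_hab)/act_hab and activity change
(act_post - act_ref)/act_ref, the contrast-enhancement regression of change
vs. UI, and plain two-sample condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

CORR_BIN_MS = 100.0
PCA_BIN_MS = 40.0


@dataclass
class UniquenessRecord:
    """Per-unit (percept/glomerulus/sensor-node) contrast-enhancement entry."""

    unit_id: int
    act_rew_ref: float
    act_hab_ref: float
    act_rew_post: float
    UI: float
    change: float


def _normalize_unit_max(mats):
    """Divide each neuron's counts by its maximum across all matrices of the
    comparison; neurons silent everywhere are dropped from all matrices."""
    stack = np.concatenate(mats, axis=1)
    peak = stack.max(axis=1)
    keep = peak > 0
    return [m[keep] / peak[keep, None] for m in mats], keep


def _binned(rasters, bin_ms, window, population="PN"):
    return [r.binned_counts(window, bin_ms, population) for r in rasters]


def representation_correlation(rasters_A, rasters_B, window,
                               bin_ms: float = CORR_BIN_MS,
                               normalize: str = "unit_max") -> float:
    """Mean Pearson correlation between two sets of odor representations.

    For every trial pair (a from A, b from B) and every time bin, the two
    normalized PN count vectors are correlated; the result is averaged over
    bins, then over pairs.  Identical rasters give 1.  Bins in which either
    vector has zero variance are skipped.  When A and B are the same list,
    only distinct unordered pairs are used.

    ``normalize``: "unit_max" (each PN divided by its peak count across the
    comparison), "zscore", or "none".
    """
    mats_A = _binned(rasters_A, bin_ms, window)
    mats_B = _binned(rasters_B, bin_ms, window)
    same = rasters_A is rasters_B or (
        len(rasters_A) == len(rasters_B)
        and all(a is b for a, b in zip(rasters_A, rasters_B)))
    mats = mats_A + ([] if same else mats_B)
    if normalize == "unit_max":
        mats, _ = _normalize_unit_max(mats)
    elif normalize == "zscore":
        stack = np.concatenate(mats, axis=1)
        mu, sd = stack.mean(axis=1), stack.std(axis=1)
        keep = sd > 0
        mats = [(m[keep] - mu[keep, None]) / sd[keep, None] for m in mats]
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    mats_A = mats[:len(rasters_A)]
    mats_B = mats_A if same else mats[len(rasters_A):]

    pair_means = []
    for ia, a in enumerate(mats_A):
        for ib, b in enumerate(mats_B):
            if same and ib <= ia:
                continue
            vals = []
            for k in range(a.shape[1]):
                x, y = a[:, k], b[:, k]
                if x.std() == 0 or y.std() == 0:
                    continue
                vals.append(np.corrcoef(x, y)[0, 1])
            if vals:
                pair_means.append(np.mean(vals))
    if not pair_means:
        raise ValueError("no valid (pair, bin) combinations")
    return float(np.mean(pair_means))


def class_correlation(rasters_by_odor: dict, names_A, names_B, window,
                      bin_ms: float = CORR_BIN_MS) -> float:
    """Average representation correlation over all cross pairs of odors in
    class A vs class B (or within-class pairs when the name lists match)."""
    within = list(names_A) == list(names_B)
    vals = []
    for i, na in enumerate(names_A):
        for j, nb in enumerate(names_B):
            if within and j <= i:
                continue
            vals.append(representation_correlation(
                rasters_by_odor[na], rasters_by_odor[nb], window, bin_ms))
    return float(np.mean(vals))


def pca_trajectory(rasters_by_label: dict, window, bin_ms: float = PCA_BIN_MS,
                   n_components: int = 2) -> dict:
    """Low-dimensional response trajectories with shared axes.

    PCA is fitted on the pooled bin vectors of every compared condition
    jointly so the trajectories live in one coding space; returns
    {label: (n_bins, n_components) trajectory} plus the fitted model under
    key "_pca".
    """
    mats = {k: np.mean([r.binned_counts(window, bin_ms) for r in v], axis=0)
            for k, v in rasters_by_label.items()}
    pooled = np.concatenate([m.T for m in mats.values()], axis=0)
    if pooled.shape[0] < n_components:
        raise ValueError("not enough bins to fit the requested components")
    pca = PCA(n_components=n_components)
    pca.fit(pooled)
    out = {k: pca.transform(m.T) for k, m in mats.items()}
    out["_pca"] = pca
    return out


def uniqueness_index(act_rew_ref: float, act_hab_ref: float) -> float:
    """UI = (act_rew - act_hab) / act_hab in the reference condition."""
    if act_hab_ref <= 0:
        raise ValueError("undefined uniqueness index: zero reference activity")
    return (act_rew_ref - act_hab_ref) / act_hab_ref


def activity_change(act_post: float, act_ref: float,
                    normalized: bool = True) -> float:
    """(act_post - act_ref)/act_ref; unnormalized difference when
    ``normalized`` is False (the GCN layer-difference variant)."""
    if not normalized:
        return act_post - act_ref
    if act_ref <= 0:
        raise ValueError("undefined activity change: zero reference activity")
    return (act_post - act_ref) / act_ref


def unit_activity(rasters, blocks, window) -> np.ndarray:
    """Mean spike count per unit (percept block of PNs) over the odor
    window, averaged over trials and neurons of the block."""
    counts = np.mean([r.binned_counts(window, window[1] - window[0])[:, 0]
                      for r in rasters], axis=0)
    return np.array([counts[a:b].mean() for a, b in blocks])


def percept_uniqueness_records(act_rew_ref, act_hab_ref, act_rew_post,
                               min_act: float = 0.0) -> list:
    """UniquenessRecords for units with defined (positive) reference
    activities; undefined units are excluded."""
    records = []
    for u, (r0, h0, r1) in enumerate(zip(act_rew_ref, act_hab_ref,
                                         act_rew_post)):
        if h0 <= min_act or r0 <= min_act:
            continue
        records.append(UniquenessRecord(u, r0, h0, r1,
                                        uniqueness_index(r0, h0),
                                        activity_change(r1, r0)))
    return records


def contrast_enhancement_fit(records) -> dict:
    """OLS fit of activity change vs uniqueness index.

    Returns slope, intercept, r2 and the standard F-test p-value; a positive
    slope is the contrast-enhancement signature (units unique to rewarded
    odors gain activity, shared units lose it).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 defined records")
    ui = np.array([r.UI for r in records])
    ch = np.array([r.change for r in records])
    fit = stats.linregress(ui, ch)
    return {"slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.rvalue ** 2, "p": fit.pvalue, "n": len(records)}


def compare_conditions(samples_A, samples_B, test: str = "t_test"):
    """Two-sided comparison of two groups of correlation values."""
    a = np.asarray(samples_A, dtype=float)
    b = np.asarray(samples_B, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if test == "t_test":
        res = stats.ttest_ind(a, b)
    elif test == "wilcoxon":
        res = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def sign_test_decrease(before, after) -> float:
    """One-sided sign test p-value that ``after`` < ``before`` across
    paired samples (ties dropped)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    diff = before - after
    n = int((diff != 0).sum())
    k = int((diff > 0).sum())
    if n == 0:
        return 1.0
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
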