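"""Representation statistics: binned-count correlation, PCA trajectories,
uniqueness index, activity change, contrast-enhancement fit, comparisons."""

import numpy as np
import pytest

from alnet.analysis import (activity_change, compare_conditions,
                            contrast_enhancement_fit, pca_trajectory,
                            percept_uniqueness_records,
                            representation_correlation, sign_test_decrease,
                            uniqueness_index, unit_activity, UniquenessRecord)
from alnet.raster import SpikeRaster

WINDOW = (0.0, 500.0)


def raster_from_counts(counts, bin_ms=100.0, seed=0):
    """Build a SpikeRaster whose binned counts equal ``counts``."""
    counts = np.asarray(counts)
    ids, times = [], []
    rng = np.random.default_rng(seed)
    for i in range(counts.shape[0]):
        for b in range(counts.shape[1]):
            for k in range(int(counts[i, b])):
                ids.append(i)
                times.append(b * bin_ms + (k + 0.5) * bin_ms / (counts[i, b] + 1))
    return SpikeRaster(np.array(ids, dtype=np.int64), np.array(times),
                       counts.shape[0], counts.shape[0],
                       counts.shape[1] * bin_ms)


def test_binned_counts_round_trip():
    counts = np.array([[3, 0, 1], [0, 2, 2], [5, 5, 0]])
    r = raster_from_counts(counts)
    assert np.array_equal(r.binned_counts((0, 300.0), 100.0), counts)
    with pytest.raises(ValueError):
        r.binned_counts((0, 250.0), 100.0)     # bins must tile the window


def test_identical_rasters_correlate_perfectly():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 6, size=(30, 5))
    r = raster_from_counts(counts)
    assert representation_correlation([r], [raster_from_counts(counts)],
                                      (0, 500.0)) == pytest.approx(1.0)


def test_disjoint_activation_matches_closed_form():
    """Complementary indicator vectors x and 1-x have Pearson correlation
    exactly -1; two rasters activating disjoint PN halves with equal
    counts hit that closed form."""
    n = 20
    a = np.zeros((n, 1))
    b = np.zeros((n, 1))
    a[:10] = 4
    b[10:] = 4
    corr = representation_correlation([raster_from_counts(a)],
                                      [raster_from_counts(b)], (0, 100.0),
                                      normalize="none")
    assert corr == pytest.approx(-1.0)


def test_correlation_is_symmetric_and_scale_invariant():
    rng = np.random.default_rng(2)
    A = [raster_from_counts(rng.integers(0, 5, (15, 5))) for _ in range(2)]
    B = [raster_from_counts(rng.integers(0, 5, (15, 5))) for _ in range(2)]
    ab = representation_correlation(A, B, WINDOW)
    ba = representation_correlation(B, A, WINDOW)
    assert ab == pytest.approx(ba)
    # common positive rescaling of all counts leaves unit-max result alone
    A3 = [raster_from_counts(3 * r.binned_counts(WINDOW, 100.0)) for r in A]
    B3 = [raster_from_counts(3 * r.binned_counts(WINDOW, 100.0)) for r in B]
    assert representation_correlation(A3, B3, WINDOW) == pytest.approx(ab)


def test_within_class_correlation_skips_self_pairs():
    counts = np.random.default_rng(3).integers(0, 5, (10, 5))
    r = [raster_from_counts(counts), raster_from_counts(counts + 1)]
    val = representation_correlation(r, r, WINDOW)
    assert val < 1.0 + 1e-9                     # not the self-pair value


def test_pca_trajectory_properties():
    rng = np.random.default_rng(4)
    groups = {f"odor{k}": [raster_from_counts(rng.integers(0, 8, (25, 12)),
                                              bin_ms=40.0)]
              for k in range(3)}
    out = pca_trajectory(groups, (0, 480.0), n_components=2)
    pca = out.pop("_pca")
    assert all(v.shape == (12, 2) for v in out.values())
    evr = pca.explained_variance_
    assert np.all(np.diff(evr) <= 1e-12)       # ordered components
    # duplicated rasters give overlapping trajectories
    dup = {"a": groups["odor0"], "b": groups["odor0"]}
    out2 = pca_trajectory(dup, (0, 480.0), n_components=2)
    assert np.allclose(out2["a"], out2["b"])
    # reconstruction from all feature components returns the data
    full = pca_trajectory(groups, (0, 480.0), n_components=25)
    p = full["_pca"]
    X = groups["odor0"][0].binned_counts((0, 480.0), 40.0).T
    assert np.allclose(p.inverse_transform(p.transform(X)), X, atol=1e-8)


def test_uniqueness_index_and_activity_change_values():
    assert uniqueness_index(1.0, 1.0) == 0.0
    assert uniqueness_index(2.0, 1.0) == 1.0
    assert uniqueness_index(0.0, 1.0) == -1.0
    with pytest.raises(ValueError):
        uniqueness_index(1.0, 0.0)
    assert activity_change(1.0, 1.0) == 0.0
    assert activity_change(1.5, 1.0) == 0.5
    assert activity_change(2.0, 2.0, normalized=False) == 0.0
    # scale invariance of the normalized forms
    assert uniqueness_index(4.0, 2.0) == uniqueness_index(2.0, 1.0)
    assert activity_change(3.0, 2.0) == activity_change(1.5, 1.0)


def test_unit_activity_averages_blocks_and_trials():
    counts = np.array([[2, 2], [4, 4], [0, 0], [6, 6]], dtype=float)
    r = raster_from_counts(counts, bin_ms=100.0)
    act = unit_activity([r, r], [(0, 2), (2, 4)], (0, 200.0))
    assert act == pytest.approx([6.0, 6.0])    # window-total counts


def test_contrast_fit_exact_line_and_permutation_null():
    rng = np.random.default_rng(5)
    ui = rng.normal(0, 1, 24)
    records = [UniquenessRecord(i, 1 + u, 1.0, 0.0, u, 0.7 * u - 0.1)
               for i, u in enumerate(ui)]
    fit = contrast_enhancement_fit(records)
    assert fit["slope"] == pytest.approx(0.7)
    assert fit["r2"] == pytest.approx(1.0)
    # permuted pairing destroys the relation: r2 near the permutation null
    perm = rng.permutation(len(records))
    shuffled = [UniquenessRecord(i, 0, 0, 0, records[i].UI,
                                 records[perm[i]].change)
                for i in range(len(records))]
    null_r2 = []
    for _ in range(200):
        p = rng.permutation(len(records))
        x = np.array([r.UI for r in records])
        y = np.array([records[j].change for j in p])
        c = np.corrcoef(x, y)[0, 1] ** 2
        null_r2.append(c)
    assert contrast_enhancement_fit(shuffled)["r2"] <= np.quantile(null_r2,
                                                                   0.99)
    with pytest.raises(ValueError):
        contrast_enhancement_fit(records[:2])


def test_percept_records_exclude_undefined_units():
    recs = percept_uniqueness_records([1.0, 2.0, 0.0], [1.0, 0.0, 1.0],
                                      [1.5, 1.0, 1.0])
    assert [r.unit_id for r in recs] == [0]
    assert recs[0].UI == 0.0 and recs[0].change == pytest.approx(0.5)


def test_compare_conditions_and_sign_test():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, 10)
    t, p = compare_conditions(a, a)
    assert p == pytest.approx(1.0)
    b = rng.normal(5, 1, 10)
    t1, p1 = compare_conditions(a, b)
    t2, p2 = compare_conditions(b, a)
    assert p1 < 1e-3 and t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)
    # one-sided sign test: 5/5 decreases is significant, 3/5 is not
    assert sign_test_decrease([1] * 5, [0] * 5) < 0.05
    assert sign_test_decrease([1, 1, 1, 0, 0], [0, 0, 0, 1, 1]) > 0.05
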