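"""RDM construction, distance metrics, block algebra, intra-RDM geometry."""

import numpy as np
import pytest

import mooneyrsa as m
from mooneyrsa.containers import CONDITIONS, RDMSeries
from mooneyrsa.rdm import (
    average_presentations,
    average_rdm_series,
    block_view,
    default_folds,
    intra_rdm_correlation,
    pattern_distance,
    rdm_series,
    subject_rdm_series,
    within_condition_dissimilarity_timecourse,
)


def test_hand_computed_distances():
    """x=(1,0,2), y=(0,1,2): 1 - r and squared Euclidean from the expanded
    formulas."""
    x, y = np.array([1.0, 0.0, 2.0]), np.array([0.0, 1.0, 2.0])
    # centered: (0,-1,1) and (-1,0,1); r = 1/2
    assert pattern_distance(x, y, "one_minus_r") == pytest.approx(0.5, abs=1e-12)
    assert pattern_distance(x, y, "euclidean") == pytest.approx(2.0, abs=1e-12)


def test_identical_inputs_give_zero_distance():
    x = np.array([0.3, -1.2, 0.7, 2.0])
    assert pattern_distance(x, x, "one_minus_r") == pytest.approx(0.0, abs=1e-12)
    assert pattern_distance(x, x, "euclidean") == 0.0
    trials = np.tile(x, (6, 1))
    assert pattern_distance(trials, trials, "cv_euclidean") == pytest.approx(0.0, abs=1e-12)


def test_cv_euclidean_equals_plain_when_folds_identical():
    """Noise-free trials: every partition average is the same vector, so the
    cross-validated distance collapses to the plain squared distance."""
    x = np.tile([1.0, 2.0, -1.0], (6, 1))
    y = np.tile([0.0, 1.0, 1.0], (6, 1))
    plain = pattern_distance(x[0], y[0], "euclidean")
    assert pattern_distance(x, y, "cv_euclidean") == pytest.approx(plain, abs=1e-12)


def test_cv_euclidean_matches_explicit_formula():
    """2-trial folds with fold-specific offsets: equals the partition-product
    formula evaluated by hand."""
    rng = np.random.default_rng(3)
    base_x, base_y = rng.standard_normal(4), rng.standard_normal(4)
    x = np.stack([base_x + 0.1 * i for i in range(6)])
    y = np.stack([base_y - 0.2 * i for i in range(6)])
    folds = default_folds(6)
    expected = 0.0
    for f in folds:
        comp = np.setdiff1d(np.arange(6), f)
        dA = x[f].mean(0) - y[f].mean(0)
        dB = x[comp].mean(0) - y[comp].mean(0)
        expected += dA @ dB
    expected /= 3
    assert pattern_distance(x, y, "cv_euclidean") == pytest.approx(expected, abs=1e-12)


def test_cv_euclidean_cancels_noise():
    """Same true pattern, independent noise: cross-validated distance
    averages ~0 while the plain squared distance stays strictly positive."""
    rng = np.random.default_rng(4)
    truth = rng.standard_normal(12)
    cv_vals, plain_vals = [], []
    for _ in range(500):
        x = truth + rng.standard_normal((6, 12))
        y = truth + rng.standard_normal((6, 12))
        cv_vals.append(pattern_distance(x, y, "cv_euclidean"))
        plain_vals.append(pattern_distance(x.mean(0), y.mean(0), "euclidean"))
    se = np.std(cv_vals, ddof=1) / np.sqrt(len(cv_vals))
    assert abs(np.mean(cv_vals)) < 3 * se
    assert np.mean(plain_vals) > 10 * se


def test_distance_errors():
    with pytest.raises(ValueError):
        pattern_distance(np.ones(3), np.array([1.0, 2.0, 3.0]), "one_minus_r")
    with pytest.raises(ValueError):
        pattern_distance(np.ones(3), np.ones(3), "mahalanobis")
    with pytest.raises(ValueError):
        default_folds(2, 3)


def _random_patterns(n_img, n_sensors, n_times, seed):
    rng = np.random.default_rng(seed)
    return {
        c: rng.standard_normal((n_img, n_sensors, n_times)) for c in CONDITIONS
    }


def test_rdm_series_is_99_by_99_for_33_sets():
    pats = _random_patterns(33, 8, 2, 0)
    series = rdm_series(pats, "one_minus_r")
    assert series.values.shape == (2, 99, 99)
    assert np.all(np.isnan(np.diagonal(series.values, axis1=1, axis2=2)))


def test_rdm_entries_match_pairwise_oracle():
    pats = _random_patterns(5, 7, 3, 1)
    for metric in ("one_minus_r", "euclidean"):
        series = rdm_series(pats, metric)
        stacked = np.concatenate([pats[c] for c in CONDITIONS], axis=0)
        rng = np.random.default_rng(2)
        for t in range(3):
            for _ in range(5):
                i, j = rng.integers(0, 15, 2)
                if i == j:
                    continue
                expected = pattern_distance(stacked[i, :, t], stacked[j, :, t], metric)
                assert series.values[t, i, j] == pytest.approx(expected, abs=1e-10)


def test_rdm_symmetry_and_conjugation():
    pats = _random_patterns(4, 6, 2, 3)
    series = rdm_series(pats, "one_minus_r")
    np.testing.assert_allclose(series.values, np.swapaxes(series.values, 1, 2))
    # permuting image order inside each condition conjugates the matrix
    perm = np.array([2, 0, 3, 1])
    pats_p = {c: pats[c][perm] for c in CONDITIONS}
    series_p = rdm_series(pats_p, "one_minus_r")
    idx = np.concatenate([perm, 4 + perm, 8 + perm])
    np.testing.assert_allclose(
        series_p.values, series.values[:, idx][:, :, idx], atol=1e-12
    )


def test_one_minus_r_affine_invariance():
    pats = _random_patterns(3, 9, 2, 5)
    series = rdm_series(pats, "one_minus_r")
    scaled = {c: 3.0 * pats[c] - 1.2 for c in CONDITIONS}
    series2 = rdm_series(scaled, "one_minus_r")
    np.testing.assert_allclose(series.values, series2.values, atol=1e-10)


def test_block_view_addressing():
    pats = _random_patterns(4, 6, 1, 6)
    series = rdm_series(pats, "one_minus_r")
    pp = block_view(series, "pre", "pre")
    np.testing.assert_allclose(pp, np.swapaxes(pp, 1, 2))
    pg = block_view(series, "pre", "gray")
    gp = block_view(series, "gray", "pre")
    np.testing.assert_allclose(pg, np.swapaxes(gp, 1, 2))
    # Post-Gray diagonal addresses matching image pairs via the label map
    labels = series.labels()
    n = series.n_images
    for i in range(n):
        row = labels.index(("post", series.image_ids[i]))
        col = labels.index(("gray", series.image_ids[i]))
        assert block_view(series, "post", "gray")[0, i, i] == series.values[0, row, col]
    with pytest.raises(ValueError):
        block_view(series, "pre", "sepia")


def test_within_condition_summary():
    # all-equal patterns: zero euclidean dissimilarity everywhere
    pats = {c: np.tile(np.arange(6.0)[None, :, None], (3, 1, 2)) for c in CONDITIONS}
    series = rdm_series(pats, "euclidean")
    np.testing.assert_allclose(
        within_condition_dissimilarity_timecourse(series, "pre"), 0.0, atol=1e-12
    )
    # hand-filled 3-image block: mean of the three upper-triangle entries
    vals = np.full((1, 9, 9), np.nan)
    block = np.array([[np.nan, 1.0, 2.0], [1.0, np.nan, 3.0], [2.0, 3.0, np.nan]])
    vals[0, :3, :3] = block
    series = RDMSeries(np.array([0.0]), vals, "euclidean", np.arange(3))
    assert within_condition_dissimilarity_timecourse(series, "pre")[0] == pytest.approx(2.0)


def test_average_presentations(small_epochs):
    ev = small_epochs.subject_events(0)
    img = int(ev[ev["set_type"] == "real"]["image_id"].iloc[0])
    imgs = np.array([img])
    # k=1: first presentation unchanged
    first = average_presentations(small_epochs, "pre", k=1, images=imgs)
    idx = ev[
        (ev["stage"] == "pre") & (ev["image_id"] == img) & (ev["presentation"] == 1)
    ]["trial"].iloc[0]
    np.testing.assert_array_equal(first[0], small_epochs.values[0, idx])
    # k=3: explicit three-term mean
    mean3 = average_presentations(small_epochs, "pre", k=3, images=imgs)
    rows = ev[(ev["stage"] == "pre") & (ev["image_id"] == img)].sort_values("presentation")
    expected = small_epochs.values[0, rows["trial"].to_numpy()[:3]].mean(axis=0)
    np.testing.assert_allclose(mean3[0], expected, atol=1e-12)
    with pytest.raises(ValueError, match="presentations"):
        average_presentations(small_epochs, "gray", k=5, images=imgs)


def test_subject_series_and_group_average(small_epochs):
    series = subject_rdm_series(small_epochs)
    assert len(series) == small_epochs.n_subjects
    group = average_rdm_series(series)
    n = series[0].n_images
    assert group.values.shape == (small_epochs.n_times, 3 * n, 3 * n)
    cell = np.mean([s.values[5, 0, 1] for s in series])
    assert group.values[5, 0, 1] == pytest.approx(cell, abs=1e-12)


def test_intra_rdm_correlation_properties():
    rng = np.random.default_rng(8)
    pats = _random_patterns(6, 10, 4, 9)
    series = rdm_series(pats, "one_minus_r")
    # same block against itself: r = 1, clipped before the final transform
    z_self = intra_rdm_correlation(series, ("pre", "pre"), ("pre", "pre"))
    assert np.all(z_self > 10)
    # independent random geometries: correlation near zero
    vals = []
    for s in range(40):
        p = _random_patterns(8, 10, 1, 100 + s)
        ser = rdm_series(p, "one_minus_r")
        vals.append(intra_rdm_correlation(ser, ("pre", "pre"), ("post", "post"))[0])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals)) < 3 * se
    with pytest.raises(ValueError):
        intra_rdm_correlation(series, ("pre", "post"), ("gray", "gray"))


def test_cv_euclidean_series_from_epochs(small_epochs):
    series = subject_rdm_series(small_epochs, metric="cv_euclidean")
    s0 = series[0]
    np.testing.assert_allclose(
        s0.values, np.swapaxes(s0.values, 1, 2), atol=1e-10
    )
    assert s0.metric == "cv_euclidean"
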