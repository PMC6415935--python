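"""Planted component structure of the synthetic sensor and ROI generators."""

import numpy as np
import pytest

import mooneyrsa as m
from mooneyrsa.fusion import roi_rdm
from mooneyrsa.rdm import pattern_distance


def _noise_free_epochs(design, seed=21, **amps):
    gt = m.make_ground_truth(design.n_sets, n_sensors=24, seed=seed,
                             noise_scale=0.0, **amps)
    ep = m.simulate_sensor_epochs(design, gt, n_subjects=1, sampling_rate=20.0, seed=5)
    return gt, ep


def test_zero_noise_repeats_are_identical(tiny_design):
    """Without noise, two post trials of the same image are the same array."""
    _, ep = _noise_free_epochs(tiny_design)
    ev = ep.subject_events(0)
    post = ev[(ev["stage"] == "post") & (ev["image_id"] == ev["image_id"].iloc[-1])]
    img = post["image_id"].iloc[0]
    sel = ev[(ev["stage"] == "post") & (ev["image_id"] == img)]["trial"].to_numpy()
    assert len(sel) == 6
    for k in sel[1:]:
        np.testing.assert_array_equal(ep.values[0, sel[0]], ep.values[0, k])


def test_zero_noise_post_equals_matching_gray_late(tiny_design):
    """Late in the epoch (stimulus envelope ~0, recognition ramp saturated)
    a real post-Mooney pattern equals its matching grayscale pattern."""
    gt, ep = _noise_free_epochs(tiny_design)
    ev = ep.subject_events(0)
    t_idx = np.argmin(np.abs(ep.time - 2.6))
    assert gt.envelopes.stimulus(ep.time[t_idx : t_idx + 1])[0] < 1e-6
    img = int(tiny_design.real_image_ids[0])
    post = ev[(ev["stage"] == "post") & (ev["image_id"] == img)]["trial"].iloc[0]
    gray = ev[(ev["stage"] == "gray") & (ev["image_id"] == img)]["trial"].iloc[0]
    np.testing.assert_allclose(
        ep.values[0, post, :, t_idx], ep.values[0, gray, :, t_idx], atol=1e-8
    )
    # ... while a *different* image's grayscale differs (distinct recognition content)
    other = int(tiny_design.real_image_ids[1])
    gray2 = ev[(ev["stage"] == "gray") & (ev["image_id"] == other)]["trial"].iloc[0]
    assert not np.allclose(ep.values[0, post, :, t_idx], ep.values[0, gray2, :, t_idx])


def test_catch_post_lacks_recognition_component(tiny_design):
    """A catch Mooney image gains no recognition/attention components post."""
    _, ep = _noise_free_epochs(tiny_design)
    ev = ep.subject_events(0)
    img = int(tiny_design.catch_image_ids[0])
    pre = ev[(ev["stage"] == "pre") & (ev["image_id"] == img)]["trial"].iloc[0]
    post = ev[(ev["stage"] == "post") & (ev["image_id"] == img)]["trial"].iloc[0]
    np.testing.assert_allclose(ep.values[0, pre], ep.values[0, post], atol=1e-10)


def test_early_correlation_matches_closed_form(tiny_design):
    """Sensor-space correlation between pre and post trials of one image at
    the early stimulus peak: the same-image excess over different images
    matches the closed-form expectation from the generative model."""
    gt = m.make_ground_truth(tiny_design.n_sets, n_sensors=24, seed=21)
    ep = m.simulate_sensor_epochs(
        tiny_design, gt, n_subjects=8, sampling_rate=20.0, seed=50
    )
    t_idx = int(np.argmin(np.abs(ep.time - gt.envelopes.stim_peak)))
    tval = ep.time[t_idx : t_idx + 1]

    # closed-form: signal vectors at this time point per trial type
    def signal(img, stage):
        e = gt.amp_evoked * gt.envelopes.evoked(tval)[0] * gt.evoked_pattern
        s = gt.envelopes.stimulus(tval)[0] * (
            gt.amp_stim * gt.stim_patterns[img] + gt.amp_class * gt.class_patterns[0]
        )
        return e + s

    def expected_r(a, b):
        # Pearson across sensors of a + noise vs b + noise
        ac, bc = a - a.mean(), b - b.mean()
        S = len(a)
        var_n = gt.noise_scale**2 * (S - 1) / S  # sensor-axis variance of noise
        cov = ac @ bc / S
        return cov / np.sqrt((ac @ ac / S + var_n) * (bc @ bc / S + var_n))

    img_a, img_b = 0, 1
    exp_same = expected_r(signal(img_a, "pre"), signal(img_a, "post"))
    exp_diff = expected_r(signal(img_a, "pre"), signal(img_b, "post"))
    assert exp_same - exp_diff > 0.05  # the planted excess is real

    got_same, got_diff = [], []
    for s in range(ep.n_subjects):
        ev = ep.subject_events(s)

        def trials(img, stage):
            idx = ev[(ev["stage"] == stage) & (ev["image_id"] == img)]["trial"]
            return ep.values[s, idx.to_numpy(), :, t_idx]

        for x in trials(img_a, "pre"):
            for y in trials(img_a, "post"):
                got_same.append(np.corrcoef(x, y)[0, 1])
            for y in trials(img_b, "post"):
                got_diff.append(np.corrcoef(x, y)[0, 1])
    assert np.mean(got_same) == pytest.approx(exp_same, abs=0.05)
    assert np.mean(got_diff) == pytest.approx(exp_diff, abs=0.05)


def test_generator_reproducible(tiny_design, small_ground_truth):
    a = m.simulate_sensor_epochs(tiny_design, small_ground_truth, 2, 20.0, seed=9)
    b = m.simulate_sensor_epochs(tiny_design, small_ground_truth, 2, 20.0, seed=9)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.events.equals(b.events)


def test_roi_stimulus_only_profile(small_ground_truth):
    """A stimulus-only ROI shows identical Pre-Pre and Post-Post RDM blocks."""
    rois = m.simulate_roi_patterns(
        small_ground_truth, {"S": (1.0, 0.0, 0.0)}, seed=1, noise=0.0
    )
    rdm = roi_rdm(rois)["S"]
    n = rois.n_images
    np.testing.assert_allclose(rdm[:n, :n], rdm[n : 2 * n, n : 2 * n], atol=1e-10)


def test_roi_recognition_only_profile(small_ground_truth):
    """A recognition-only ROI has a zero Post-Gray diagonal (matching pairs
    share the full pattern)."""
    rois = m.simulate_roi_patterns(
        small_ground_truth, {"R": (0.0, 1.0, 0.0)}, seed=2, noise=0.0
    )
    rdm = roi_rdm(rois)["R"]
    n = rois.n_images
    post_gray = rdm[n : 2 * n, 2 * n :]
    np.testing.assert_allclose(np.diag(post_gray), 0.0, atol=1e-10)
    off = post_gray[~np.eye(n, dtype=bool)]
    assert np.all(off > 0.05)


def test_roi_rdm_equals_brute_force(small_ground_truth):
    """Mixed-profile ROI RDM equals direct pairwise 1 - r over the vectors."""
    rois = m.simulate_roi_patterns(
        small_ground_truth, {"M": (0.7, 0.5, 0.3)}, seed=3
    )
    pats = rois.patterns["M"]
    rdm = roi_rdm(rois)["M"]
    rng = np.random.default_rng(0)
    for _ in range(10):
        i, j = rng.integers(0, len(pats), 2)
        if i == j:
            continue
        assert rdm[i, j] == pytest.approx(
            pattern_distance(pats[i], pats[j], "one_minus_r"), abs=1e-10
        )


def test_component_patterns_near_orthogonal(small_ground_truth):
    gt = small_ground_truth
    dots = [
        abs(gt.stim_patterns[0] @ gt.rec_patterns[0]),
        abs(gt.stim_patterns[0] @ gt.attention_pattern),
        abs(gt.rec_patterns[1] @ gt.evoked_pattern),
    ]
    assert max(dots) < 0.6  # unit vectors in 24 dims: far from collinear


def test_sensor_count_validation(tiny_design):
    with pytest.raises(ValueError):
        m.make_ground_truth(tiny_design.n_sets, n_sensors=3)
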