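"""Synthetic sensor epochs and ROI patterns with planted component structure.

Each trial is a sum of sensor-space components, every one the outer product
of a spatial pattern and a non-negative temporal envelope, plus white noise:

* *evoked*: one pattern shared by every trial, with an onset bump and a
  sustained plateau while the image is on screen — the gross visual-evoked
  response that makes all images look alike early on;
* *stimulus*: an image-specific pattern shared by a Mooney image across its
  pre and post stages (a grayscale image has its own, different stimulus
  pattern), active early with an optional small late re-activation; a
  class-level pattern shared by all Mooney images (and a different one by
  all grayscale images) rides on the same envelope and stands in for gross
  image statistics (two-tone vs. grayscale);
* *recognition*: an image-specific pattern shared between a
  post-disambiguation Mooney image and its matching grayscale image (catch
  Mooney images get none — their assigned grayscale does not match), rising
  as a late logistic ramp;
* *attention*: a single condition-level pattern carried by all recognized
  conditions (post-disambiguation Mooney and grayscale trials of real
  sets, and grayscale trials of catch sets), with an intermediate transient.

Spatial patterns are independent unit-norm Gaussian vectors, hence
near-orthogonal in expectation for realistic sensor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SensorEpochs
from .design import Design, build_design


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _logistic(t: np.ndarray, mu: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - mu) / width))


@dataclass
class EnvelopeSpec:
    """Temporal envelopes of the planted components (times in seconds)."""

    stim_peak: float = 0.2
    stim_sigma: float = 0.08
    stim_second_peak: float | None = 1.35
    stim_second_sigma: float = 0.12
    stim_second_amp: float = 0.35
    rec_midpoint: float = 0.6
    rec_width: float = 0.1
    att_peak: float = 0.5
    att_sigma: float = 0.1
    evoked_peak: float = 0.15
    evoked_sigma: float = 0.05
    evoked_plateau: float = 0.6
    image_offset: float = 2.0

    def stimulus(self, t: np.ndarray) -> np.ndarray:
        env = _gauss(t, self.stim_peak, self.stim_sigma)
        if self.stim_second_peak is not None:
            env = env + self.stim_second_amp * _gauss(
                t, self.stim_second_peak, self.stim_second_sigma
            )
        return env

    def recognition(self, t: np.ndarray) -> np.ndarray:
        return _logistic(t, self.rec_midpoint, self.rec_width) * (t > 0)

    def attention(self, t: np.ndarray) -> np.ndarray:
        return _gauss(t, self.att_peak, self.att_sigma)

    def evoked(self, t: np.ndarray) -> np.ndarray:
        onset = _gauss(t, self.evoked_peak, self.evoked_sigma)
        plateau = self.evoked_plateau * (
            _logistic(t, 0.1, 0.03) - _logistic(t, self.image_offset + 0.3, 0.1)
        )
        return onset + np.clip(plateau, 0.0, None)


@dataclass
class GroundTruth:
    """Planted spatial patterns, envelopes, amplitudes, and noise scale."""

    stim_patterns: np.ndarray      # n_sets x n_sensors, Mooney stimulus features
    gray_patterns: np.ndarray      # n_sets x n_sensors, grayscale stimulus features
    rec_patterns: np.ndarray       # n_sets x n_sensors, recognition content
    class_patterns: np.ndarray     # 2 x n_sensors: Mooney-class, grayscale-class
    attention_pattern: np.ndarray  # n_sensors
    evoked_pattern: np.ndarray     # n_sensors
    envelopes: EnvelopeSpec = field(default_factory=EnvelopeSpec)
    amp_stim: float = 6.0
    amp_class: float = 4.0
    amp_rec: float = 6.0
    amp_att: float = 4.0
    amp_evoked: float = 8.0
    noise_scale: float = 1.0
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.stim_patterns.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.stim_patterns.shape[1]


def _unit_rows(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    x = rng.standard_normal((n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def make_ground_truth(
    n_sets: int = 39,
    n_sensors: int = 64,
    seed: int | None = None,
    envelopes: EnvelopeSpec | None = None,
    **amplitudes: float,
) -> GroundTruth:
    """Draw unit-norm component patterns; ``amplitudes`` overrides defaults
    (``amp_stim``, ``amp_rec``, ``amp_att``, ``amp_evoked``, ``noise_scale``)."""
    if n_sensors < 4:
        raise ValueError("need at least component count + 1 sensors")
    rng = np.random.default_rng(seed)
    gt = GroundTruth(
        stim_patterns=_unit_rows(rng, n_sets, n_sensors),
        gray_patterns=_unit_rows(rng, n_sets, n_sensors),
        rec_patterns=_unit_rows(rng, n_sets, n_sensors),
        class_patterns=_unit_rows(rng, 2, n_sensors),
        attention_pattern=_unit_rows(rng, 1, n_sensors)[0],
        evoked_pattern=_unit_rows(rng, 1, n_sensors)[0],
        envelopes=envelopes or EnvelopeSpec(),
        seed=seed,
    )
    for key, val in amplitudes.items():
        if not hasattr(gt, key):
            raise TypeError(f"unknown amplitude parameter {key!r}")
        setattr(gt, key, float(val))
    return gt


def _trial_components(
    gt: GroundTruth, image_id: int, image_type: str, stage: str, set_type: str,
    envs: dict[str, np.ndarray],
) -> np.ndarray:
    """Noise-free sensors x time signal of one trial."""
    sig = gt.amp_evoked * np.outer(gt.evoked_pattern, envs["evoked"])
    if image_type == "grayscale":
        stim_pat = gt.gray_patterns[image_id]
        class_pat = gt.class_patterns[1]
    else:
        stim_pat = gt.stim_patterns[image_id]
        class_pat = gt.class_patterns[0]
    sig = sig + gt.amp_stim * np.outer(stim_pat, envs["stim"])
    sig = sig + gt.amp_class * np.outer(class_pat, envs["stim"])
    recognized = (image_type == "grayscale") or (stage == "post" and set_type == "real")
    if recognized:
        sig = sig + gt.amp_rec * np.outer(gt.rec_patterns[image_id], envs["rec"])
        sig = sig + gt.amp_att * np.outer(gt.attention_pattern, envs["att"])
    return sig


def simulate_sensor_epochs(
    design: Design,
    ground_truth: GroundTruth,
    n_subjects: int = 18,
    sampling_rate: float = 100.0,
    seed: int | None = None,
    epoch_window: tuple[float, float] = (-0.5, 3.0),
    band: str = "synthetic",
) -> SensorEpochs:
    """Generate epoched sensor data for ``n_subjects`` sessions.

    Each subject receives an independently re-randomized schedule with the
    same design parameters (same image sets, fresh trial order) and
    independent sensor noise; all randomness descends from ``seed`` via
    per-subject child seeds.
    """
    if ground_truth.n_sets != design.n_sets:
        raise ValueError("ground truth and design disagree on the number of sets")
    rng = np.random.default_rng(seed)
    t0, t1 = epoch_window
    n_time = int(round((t1 - t0) * sampling_rate)) + 1
    time = t0 + np.arange(n_time) / sampling_rate
    envs = {
        "stim": ground_truth.envelopes.stimulus(time),
        "rec": ground_truth.envelopes.recognition(time),
        "att": ground_truth.envelopes.attention(time),
        "evoked": ground_truth.envelopes.evoked(time),
    }

    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    n_trials = len(design.trials)
    values = np.empty((n_subjects, n_trials, ground_truth.n_sensors, n_time))
    event_frames = []
    for s in range(n_subjects):
        srng = np.random.default_rng(subject_seeds[s])
        subj_design = build_design(
            design.n_real_sets,
            design.n_catch_sets,
            design.n_runs,
            seed=int(srng.integers(0, 2**31 - 1)),
        )
        ev = subj_design.trials.copy()
        ev.insert(0, "subject", s)
        event_frames.append(ev)
        for k, row in enumerate(subj_design.trials.itertuples(index=False)):
            sig = _trial_components(
                ground_truth, row.image_id, row.image_type, row.stage, row.set_type, envs
            )
            noise = ground_truth.noise_scale * srng.standard_normal(sig.shape)
            values[s, k] = sig + noise

    events = pd.concat(event_frames, ignore_index=True)
    return SensorEpochs(values=values, time=time, sfreq=sampling_rate, events=events, band=band)


@dataclass
class ROIPatterns:
    """Per-ROI activation patterns for every (condition, image) of the real sets.

    ``patterns[name]`` is a ``3n x d`` array in the fixed condition-block
    order (pre, post, gray) over the ``n`` real image sets; ``weights[name]``
    holds the (stimulus, recognition, attention) mixing weights.
    """

    patterns: dict[str, np.ndarray]
    weights: dict[str, tuple[float, float, float]]
    n_images: int

    @property
    def roi_names(self) -> list[str]:
        return list(self.patterns)


#: Default ROI mixing profiles: (stimulus, recognition, attention) weights.
#: Recognition-dominant ROIs keep the attention weight modest — a strong
#: shared attention component makes recognized conditions similar to each
#: other and works *against* the image-specific recognition geometry.
DEFAULT_ROI_PROFILES: dict[str, tuple[float, float, float]] = {
    "V1": (1.0, 0.1, 0.05),
    "LOC": (0.7, 0.5, 0.2),
    "Frontal": (0.15, 1.0, 0.3),
    "Parietal": (0.1, 0.3, 1.0),
}


def simulate_roi_patterns(
    ground_truth: GroundTruth,
    roi_profiles: dict[str, tuple[float, float, float]] | None = None,
    seed: int | None = None,
    n_features: int = 60,
    noise: float = 0.05,
    common_scale: float = 0.5,
    n_real_sets: int | None = None,
) -> ROIPatterns:
    """Synthesize ROI feature vectors sharing the ground truth's identity
    structure (which image pairs share which components) in a fresh feature
    space per ROI.

    Every pattern also receives an ROI-wide common component
    (``common_scale``), the mean task activation shared by every image and
    condition; it keeps correlation distances defined for single-component
    profiles and gives unrecognized conditions the baseline similarity seen
    in group-level ROI RDMs.  ``noise`` is per-feature and deliberately
    small: the patterns stand in for group-averaged activation estimates.
    """
    profiles = roi_profiles or DEFAULT_ROI_PROFILES
    for name, w in profiles.items():
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError(f"profile {name!r} must give 3 non-negative weights")
    if n_features < 2:
        raise ValueError("each ROI needs feature dimension >= 2")
    n = n_real_sets if n_real_sets is not None else ground_truth.n_sets
    rng = np.random.default_rng(seed)
    patterns: dict[str, np.ndarray] = {}
    for name, (w_s, w_r, w_a) in profiles.items():
        rroi = np.random.default_rng(rng.integers(0, 2**31 - 1))
        stim = _unit_rows(rroi, n, n_features)
        gray = _unit_rows(rroi, n, n_features)
        rec = _unit_rows(rroi, n, n_features)
        cls = _unit_rows(rroi, 2, n_features)  # Mooney-class, grayscale-class
        att = _unit_rows(rroi, 1, n_features)[0]
        common = _unit_rows(rroi, 1, n_features)[0]
        cls_ratio = ground_truth.amp_class / max(ground_truth.amp_stim, 1e-12)
        rows = np.empty((3 * n, n_features))
        for i in range(n):
            rows[i] = w_s * (stim[i] + cls_ratio * cls[0])            # pre
            rows[n + i] = (
                w_s * (stim[i] + cls_ratio * cls[0]) + w_r * rec[i] + w_a * att
            )                                                          # post
            rows[2 * n + i] = (
                w_s * (gray[i] + cls_ratio * cls[1]) + w_r * rec[i] + w_a * att
            )                                                          # gray
        rows = rows + common_scale * common
        rows = rows + noise * rroi.standard_normal(rows.shape)
        patterns[name] = rows
    return ROIPatterns(patterns=patterns, weights=dict(profiles), n_images=n)
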