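"""Time-resolved linear decoding of perceptual state.

Per subject, trials are first averaged across the six presentations of each
image in each perceptual state; the per-image averaged sensor patterns are
the samples, and the class labels are the stages (pre- vs.
post-disambiguation).  A linear SVM (cost = 1) is trained at every time
point under a deterministic odd-even cross-validation over image sets:
splitting by image keeps both stage averages of one image inside the same
fold, so no image's pattern ever appears on both sides of the train/test
split.  Accuracy is the balanced accuracy averaged over the two folds.

The activation-pattern transform turns decoder weights back into
interpretable sensor patterns by multiplying with the training-data
covariance, and temporal generalization applies the classifier trained at
one time point to every other time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import SVC

from .containers import SensorEpochs

_STAGE_LABEL = {"pre": 0, "post": 1}


@dataclass
class DecoderConfig:
    """Linear-SVM decoding configuration (cost fixed at 1 by default)."""

    cost: float = 1.0
    store_weights: bool = False
    store_patterns: bool = False

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("SVM cost parameter must be positive")


@dataclass
class DecodingResult:
    """Per-subject decoding output.

    ``accuracy``: subjects x time balanced accuracy (chance 0.5).
    ``weights`` / ``patterns``: subjects x time x sensors, if requested.
    ``tgm``: subjects x train-time x test-time, if computed.
    """

    time: np.ndarray
    accuracy: np.ndarray
    weights: np.ndarray | None = None
    patterns: np.ndarray | None = None
    tgm: np.ndarray | None = None
    image_sets: dict[int, np.ndarray] = field(default_factory=dict)

    def group_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def group_patterns(self) -> np.ndarray:
        if self.patterns is None:
            raise ValueError("patterns were not stored; set store_patterns=True")
        return self.patterns.mean(axis=0)


def _resolve_subsets(
    epochs: SensorEpochs, image_subset
) -> dict[int, np.ndarray]:
    """Per-subject sorted image-id arrays; default = all real sets."""
    subsets: dict[int, np.ndarray] = {}
    for s in range(epochs.n_subjects):
        ev = epochs.subject_events(s)
        if image_subset is None:
            imgs = np.unique(
                ev[(ev["image_type"] == "mooney") & (ev["set_type"] == "real")]["image_id"]
            )
        elif isinstance(image_subset, dict):
            imgs = np.sort(np.asarray(image_subset[s], dtype=int))
        else:
            imgs = np.sort(np.asarray(image_subset, dtype=int))
        subsets[s] = imgs
    return subsets


def _per_image_stage_averages(
    epochs: SensorEpochs, subject: int, images: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Samples ``(2 * n_img) x sensors x time`` and stage labels.

    Sample order is all images pre, then all images post, image order as in
    ``images``.
    """
    ev = epochs.subject_events(subject)
    data = epochs.values[subject]
    samples = []
    labels = []
    for stage in ("pre", "post"):
        for img in images:
            sel = ev[
                (ev["image_type"] == "mooney")
                & (ev["image_id"] == img)
                & (ev["stage"] == stage)
            ]["trial"].to_numpy()
            if len(sel) == 0:
                raise ValueError(
                    f"image {img} has no {stage}-stage trials for subject {subject}"
                )
            samples.append(data[sel].mean(axis=0))
            labels.append(_STAGE_LABEL[stage])
    return np.stack(samples), np.asarray(labels)


def _fold_indices(n_img: int) -> tuple[np.ndarray, np.ndarray]:
    """Odd-even split over image positions; returns sample indices of the
    two folds (each image contributes its pre and post sample)."""
    pos = np.arange(n_img)
    folds = []
    for parity in (0, 1):
        img_idx = pos[pos % 2 == parity]
        folds.append(np.concatenate([img_idx, img_idx + n_img]))
    return folds[0], folds[1]


def activation_patterns(weights: np.ndarray, training_data: np.ndarray) -> np.ndarray:
    """Transform decoder weights into an activation pattern.

    ``pattern = Cov(training_data) @ weights`` where the covariance is taken
    over samples (rows) of the training set.
    """
    training_data = np.asarray(training_data, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if training_data.ndim != 2 or training_data.shape[0] < 2:
        raise ValueError("training data must be (>=2 samples) x sensors")
    if training_data.shape[1] != weights.shape[0]:
        raise ValueError("weights and data disagree on the sensor dimension")
    cov = np.cov(training_data, rowvar=False)
    return cov @ weights


def _decode_subject(
    X: np.ndarray,
    y: np.ndarray,
    n_img: int,
    config: DecoderConfig,
    want_tgm: bool,
) -> dict:
    """Fit per-time classifiers for one subject; X is samples x sensors x time."""
    fold_a, fold_b = _fold_indices(n_img)
    for fold in (fold_a, fold_b):
        if len(fold) < 4:  # two images -> one per class is the minimum
            raise ValueError("need at least 2 images per cross-validation fold")
    n_times = X.shape[2]
    n_sensors = X.shape[1]
    acc = np.zeros(n_times)
    weights = np.zeros((n_times, n_sensors))
    patterns = np.zeros((n_times, n_sensors))
    tgm = np.zeros((n_times, n_times)) if want_tgm else None

    fold_pairs = [(fold_a, fold_b), (fold_b, fold_a)]
    for train_idx, test_idx in fold_pairs:
        clfs = []
        for t in range(n_times):
            clf = SVC(kernel="linear", C=config.cost)
            clf.fit(X[train_idx, :, t], y[train_idx])
            clfs.append(clf)
            acc[t] += 0.5 * balanced_accuracy_score(
                y[test_idx], clf.predict(X[test_idx, :, t])
            )
            w = clf.coef_.ravel()
            weights[t] += 0.5 * w
            patterns[t] += 0.5 * activation_patterns(w, X[train_idx, :, t])
        if want_tgm:
            for t_train, clf in enumerate(clfs):
                for t_test in range(n_times):
                    tgm[t_train, t_test] += 0.5 * balanced_accuracy_score(
                        y[test_idx], clf.predict(X[test_idx, :, t_test])
                    )
    return {"accuracy": acc, "weights": weights, "patterns": patterns, "tgm": tgm}


def decode_timecourse(
    epochs: SensorEpochs,
    image_subset=None,
    config: DecoderConfig | None = None,
    _want_tgm: bool = False,
) -> DecodingResult:
    """Balanced decoding accuracy of perceptual state at every time point.

    ``image_subset`` may be None (all real sets), an array of image ids, or
    a per-subject dict (e.g. the output of behavioral selection).
    """
    config = config or DecoderConfig()
    subsets = _resolve_subsets(epochs, image_subset)
    acc = np.zeros((epochs.n_subjects, epochs.n_times))
    weights = np.zeros((epochs.n_subjects, epochs.n_times, epochs.n_sensors))
    patterns = np.zeros_like(weights)
    tgms = (
        np.zeros((epochs.n_subjects, epochs.n_times, epochs.n_times))
        if _want_tgm
        else None
    )
    for s in range(epochs.n_subjects):
        X, y = _per_image_stage_averages(epochs, s, subsets[s])
        out = _decode_subject(X, y, len(subsets[s]), config, _want_tgm)
        acc[s] = out["accuracy"]
        weights[s] = out["weights"]
        patterns[s] = out["patterns"]
        if _want_tgm:
            tgms[s] = out["tgm"]
    return DecodingResult(
        time=epochs.time.copy(),
        accuracy=acc,
        weights=weights if config.store_weights else None,
        patterns=patterns if config.store_patterns else None,
        tgm=tgms,
        image_sets=subsets,
    )


def temporal_generalization(
    epochs: SensorEpochs,
    image_subset=None,
    config: DecoderConfig | None = None,
) -> DecodingResult:
    """Train at each time point, test at all time points (same folds as
    :func:`decode_timecourse`); the TGM diagonal equals the within-time
    accuracy curve exactly."""
    result = decode_timecourse(epochs, image_subset, config, _want_tgm=True)
    # self-consistency: the diagonal IS the within-time curve
    diag = np.einsum("stt->st", result.tgm)
    np.copyto(result.accuracy, diag)
    return result
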