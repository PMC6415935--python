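"""Single-trial pattern separability and its condition-block analyses.

The separability of two images A and B at one time point measures how much
the neural similarity across repeated presentations of the same image
exceeds the similarity between the two different images:

    separability(A, B) = r_within - r_between

where ``r_within`` averages the mean Fisher-z trial-pair correlation within
A and within B (the two within-image means are themselves averaged), and
``r_between`` is the mean Fisher-z correlation over all m x n cross pairs.
All averaging happens in Fisher-z space and is not transformed back; under
exchangeable trials the expected score is 0.  Unlike the trial-averaged
1 - r distance, this statistic is sensitive to within-image across-trial
variability and is akin to single-trial decoding.

The separability RDM uses all six presentations of a Mooney image per stage
and all three grayscale presentations (the first-three averaging rule
applies only to the correlation-distance RDMs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CONDITIONS, RDMSeries, SensorEpochs, condition_block
from .rdm import fisher_z

COND_PAIRS = (("pre", "post"), ("pre", "gray"), ("post", "gray"))


@dataclass
class TrialPatternSet:
    """Single trials of two images at one time point.

    ``x``: ``m x sensors`` trials of image A; ``y``: ``n x sensors`` trials
    of image B; ``m, n >= 2`` (within-image pairs are required).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] < 2 or self.y.shape[0] < 2:
            raise ValueError("separability needs at least 2 trials per image")
        if self.x.shape[1] != self.y.shape[1]:
            raise ValueError("trial vectors must share the sensor dimension")
        for name, arr in (("x", self.x), ("y", self.y)):
            if np.any(arr.std(axis=1) == 0):
                raise ValueError(f"zero-variance trial vector in {name}")

    @property
    def m(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.y.shape[0]


def separability_score(trial_set: TrialPatternSet) -> float:
    """``r_within - r_between`` in Fisher-z space; symmetric in A and B."""
    x, y = trial_set.x, trial_set.y
    m, n = trial_set.m, trial_set.n
    z = fisher_z(np.corrcoef(np.vstack([x, y])))
    zx = z[:m, :m]
    zy = z[m:, m:]
    zxy = z[:m, m:]
    iu_x = np.triu_indices(m, k=1)
    iu_y = np.triu_indices(n, k=1)
    r_within = 0.5 * (zx[iu_x].mean() + zy[iu_y].mean())
    r_between = zxy.mean()
    return float(r_within - r_between)


def _group_trial_indices(epochs: SensorEpochs, subject: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Trial-index groups in RDM order (pre, post, gray) x real image ids."""
    ev = epochs.subject_events(subject)
    images = np.unique(ev[ev["set_type"] == "real"]["image_id"])
    groups = []
    for cond in CONDITIONS:
        image_type = "grayscale" if cond == "gray" else "mooney"
        sel = ev[(ev["image_type"] == image_type) & (ev["stage"] == cond)]
        for img in images:
            rows = sel[sel["image_id"] == img].sort_values("presentation")
            idx = rows["trial"].to_numpy()
            if len(idx) < 2:
                raise ValueError(
                    f"image {img} has fewer than 2 {cond} trials for subject {subject}"
                )
            groups.append(idx)
    return groups, images


def separability_rdm_series(epochs: SensorEpochs, subject: int = 0) -> RDMSeries:
    """Time-resolved separability RDM for one subject, over the real sets.

    All cells are computed from single trials; the main diagonal is NaN.
    """
    groups, images = _group_trial_indices(epochs, subject)
    n_groups = len(groups)
    sizes = np.array([len(g) for g in groups])
    flat = np.concatenate(groups)
    # group-membership indicator for block sums
    G = np.zeros((len(flat), n_groups))
    start = 0
    for gi, sz in enumerate(sizes):
        G[start : start + sz, gi] = 1.0
        start += sz

    n_times = epochs.n_times
    values = np.empty((n_times, n_groups, n_groups))
    data = epochs.values[subject][flat]  # trials x sensors x time
    if np.any(data.std(axis=1) == 0):
        raise ValueError("zero-variance trial vector in separability input")
    for t in range(n_times):
        z = fisher_z(np.corrcoef(data[:, :, t]))
        np.fill_diagonal(z, 0.0)
        S = G.T @ z @ G
        mw = np.diag(S) / (sizes * (sizes - 1))  # mean within-group Fisher-z
        mb = S / np.outer(sizes, sizes)          # mean between-group Fisher-z
        sep = 0.5 * (mw[:, None] + mw[None, :]) - mb
        np.fill_diagonal(sep, np.nan)
        values[t] = sep
    return RDMSeries(
        time=epochs.time.copy(), values=values, metric="separability", image_ids=images
    )


def subject_separability_series(epochs: SensorEpochs) -> list[RDMSeries]:
    return [separability_rdm_series(epochs, s) for s in range(epochs.n_subjects)]


def _check_pair(cond_pair: tuple[str, str]) -> tuple[str, str]:
    pair = tuple(cond_pair)
    if pair not in COND_PAIRS and pair[::-1] not in COND_PAIRS:
        raise ValueError(f"cond_pair must be a between-condition pair, got {pair}")
    return pair


def cross_condition_diagonal_timecourse(
    series: RDMSeries, cond_pair: tuple[str, str]
) -> np.ndarray:
    """Mean of the matching-image diagonal of one between-condition square
    per time point (e.g. post-Mooney image i vs. its grayscale image i)."""
    a, b = _check_pair(cond_pair)
    block = condition_block(series.values, a, b)
    return np.nanmean(np.einsum("tii->ti", block), axis=1)


def offdiagonal_minus_diagonal_timecourse(
    series: RDMSeries, cond_pair: tuple[str, str]
) -> np.ndarray:
    """Mean off-diagonal minus mean diagonal of one between-condition square
    per time point: how separable an image is from *other* images of the
    second condition, over and above its own matching pair."""
    a, b = _check_pair(cond_pair)
    block = condition_block(series.values, a, b)
    n = block.shape[-1]
    diag = np.einsum("tii->ti", block)
    total = np.nansum(block, axis=(1, 2))
    off_mean = (total - np.nansum(diag, axis=1)) / (n * (n - 1))
    return off_mean - np.nanmean(diag, axis=1)
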