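"""Time-resolved representational dissimilarity matrices and their algebra.

For ``n`` real image sets the RDM at each time point is ``3n x 3n`` over the
(condition, image) grid with blocks ordered pre, post, gray.  Three distance
metrics are implemented on sensor vectors ``x`` and ``y``:

* ``one_minus_r`` — ``1 - Pearson r`` across sensors;
* ``euclidean`` — the squared Euclidean distance ``(x - y)(x - y)^T``;
* ``cv_euclidean`` — the cross-validated squared distance
  ``(x - y)_A (x - y)_B^T`` where A and B are the two data partitions of a
  cross-validation fold (fold vs. its complement), averaged over a
  three-fold scheme.  Because independent noise in the two partitions is
  uncorrelated, its contribution cancels in expectation and only the signal
  consistent across partitions survives — unlike the plain squared distance,
  which is inflated by noise.

Distances are raw sums over sensors (no normalization by sensor count).
Main-diagonal cells (an image against itself within a condition) are stored
as NaN and excluded from every summary.
"""

from __future__ import annotations

import numpy as np

from .containers import CONDITIONS, RDMSeries, SensorEpochs, condition_block

_Z_CLIP = 1.0 - 1e-10

METRICS = ("one_minus_r", "euclidean", "cv_euclidean")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform with clipping at +/-(1 - 1e-10) so degenerate,
    noise-free fixtures (r = +/-1) stay finite."""
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def average_presentations(
    epochs: SensorEpochs,
    condition: str,
    k: int = 3,
    subject: int = 0,
    images: np.ndarray | None = None,
) -> np.ndarray:
    """Per-image mean of the first ``k`` presentations in one condition.

    Presentations are taken in presentation order (the ``presentation``
    column).  Returns ``n_images x sensors x time``; ``images`` defaults to
    the real image sets.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    ev = epochs.subject_events(subject)
    if images is None:
        images = np.unique(ev[ev["set_type"] == "real"]["image_id"])
    image_type = "grayscale" if condition == "gray" else "mooney"
    sel_cond = ev[(ev["image_type"] == image_type) & (ev["stage"] == condition)]
    out = np.empty((len(images), epochs.n_sensors, epochs.n_times))
    for i, img in enumerate(images):
        rows = sel_cond[sel_cond["image_id"] == img].sort_values("presentation")
        if len(rows) < k:
            raise ValueError(
                f"image {img} has only {len(rows)} {condition} presentations, need {k}"
            )
        idx = rows["trial"].to_numpy()[:k]
        out[i] = epochs.values[subject, idx].mean(axis=0)
    return out


def condition_trials(
    epochs: SensorEpochs,
    condition: str,
    subject: int = 0,
    images: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Single-trial arrays (``m_i x sensors x time``) per image in one
    condition, in presentation order."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    ev = epochs.subject_events(subject)
    if images is None:
        images = np.unique(ev[ev["set_type"] == "real"]["image_id"])
    image_type = "grayscale" if condition == "gray" else "mooney"
    sel_cond = ev[(ev["image_type"] == image_type) & (ev["stage"] == condition)]
    out = []
    for img in images:
        rows = sel_cond[sel_cond["image_id"] == img].sort_values("presentation")
        out.append(epochs.values[subject, rows["trial"].to_numpy()])
    return out


def default_folds(n_trials: int, n_folds: int = 3) -> list[np.ndarray]:
    """Contiguous presentation-order fold assignment (6 trials -> 3 folds of
    2; 3 trials -> 3 folds of 1)."""
    if n_trials < n_folds:
        raise ValueError(f"cannot split {n_trials} trials into {n_folds} folds")
    return [np.asarray(f) for f in np.array_split(np.arange(n_trials), n_folds)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance vector in correlation distance")
    return float(xc @ yc / (nx * ny))


def pattern_distance(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "one_minus_r",
    partitions: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
) -> float:
    """Dissimilarity between two sensor patterns (or trial sets).

    For ``one_minus_r`` and ``euclidean``, ``x`` and ``y`` are 1-D sensor
    vectors.  For ``cv_euclidean`` they are ``trials x sensors`` matrices
    and ``partitions`` gives the fold index arrays for each (defaulting to
    the presentation-order three-fold split); within fold ``j`` partition A
    is the fold itself and partition B its complement, and the fold
    distances are averaged.
    """
    if metric == "one_minus_r":
        return 1.0 - _pearson(np.asarray(x, float).ravel(), np.asarray(y, float).ravel())
    if metric == "euclidean":
        d = np.asarray(x, float).ravel() - np.asarray(y, float).ravel()
        return float(d @ d)
    if metric == "cv_euclidean":
        x = np.atleast_2d(np.asarray(x, float))
        y = np.atleast_2d(np.asarray(y, float))
        if partitions is None:
            partitions = (default_folds(len(x)), default_folds(len(y)))
        folds_x, folds_y = partitions
        if len(folds_x) != len(folds_y):
            raise ValueError("x and y need the same number of folds")
        _check_partition(folds_x, len(x))
        _check_partition(folds_y, len(y))
        total = 0.0
        for fx, fy in zip(folds_x, folds_y):
            cx = np.setdiff1d(np.arange(len(x)), fx)
            cy = np.setdiff1d(np.arange(len(y)), fy)
            dA = x[fx].mean(axis=0) - y[fy].mean(axis=0)
            dB = x[cx].mean(axis=0) - y[cy].mean(axis=0)
            total += float(dA @ dB)
        return total / len(folds_x)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _check_partition(folds: list[np.ndarray], n: int) -> None:
    allidx = np.concatenate([np.asarray(f) for f in folds])
    if sorted(allidx.tolist()) != list(range(n)):
        raise ValueError("fold partitions must be disjoint and exhaustive")


def _one_minus_r_matrix(patterns: np.ndarray) -> np.ndarray:
    """1 - correlation over rows of an ``N x sensors`` matrix."""
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance pattern in correlation RDM")
    return 1.0 - np.corrcoef(patterns)


def _euclidean_matrix(patterns: np.ndarray) -> np.ndarray:
    sq = np.einsum("is,is->i", patterns, patterns)
    g = patterns @ patterns.T
    d = sq[:, None] + sq[None, :] - 2 * g
    return np.clip(d, 0.0, None)


def _cv_euclidean_matrix(trials: list[np.ndarray], t: int, n_folds: int = 3) -> np.ndarray:
    """Cross-validated squared distances between all entities at one time
    index; ``trials[i]`` is ``m_i x sensors x time``."""
    n = len(trials)
    n_sensors = trials[0].shape[1]
    A = np.empty((n_folds, n, n_sensors))
    B = np.empty((n_folds, n, n_sensors))
    for i, tr in enumerate(trials):
        folds = default_folds(len(tr), n_folds)
        allidx = np.arange(len(tr))
        for j, f in enumerate(folds):
            comp = np.setdiff1d(allidx, f)
            A[j, i] = tr[f, :, t].mean(axis=0)
            B[j, i] = tr[comp, :, t].mean(axis=0)
    out = np.zeros((n, n))
    for j in range(n_folds):
        P = A[j] @ B[j].T
        dg = np.diag(P)
        out += dg[:, None] + dg[None, :] - P - P.T
    return out / n_folds


def rdm_series(
    per_image_patterns: dict[str, np.ndarray] | None = None,
    metric: str = "one_minus_r",
    time: np.ndarray | None = None,
    image_ids: np.ndarray | None = None,
    trials: dict[str, list[np.ndarray]] | None = None,
) -> RDMSeries:
    """Assemble the time-resolved ``3n x 3n`` RDM for one subject.

    ``per_image_patterns`` maps each condition to an ``n x sensors x time``
    array of (presentation-averaged) patterns — required for
    ``one_minus_r`` and ``euclidean``.  For ``cv_euclidean`` pass ``trials``
    instead: per condition a list of ``m_i x sensors x time`` single-trial
    arrays.  Main-diagonal cells are NaN.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    source = trials if metric == "cv_euclidean" else per_image_patterns
    if source is None:
        raise ValueError(
            "cv_euclidean needs single-trial data; other metrics need averaged patterns"
        )
    missing = [c for c in CONDITIONS if c not in source]
    if missing:
        raise ValueError(f"missing condition(s) {missing} in the input patterns")
    if metric == "cv_euclidean":
        n = len(trials["pre"])
        n_times = trials["pre"][0].shape[2]
        stacked = [arr for cond in CONDITIONS for arr in trials[cond]]
    else:
        n = per_image_patterns["pre"].shape[0]
        n_times = per_image_patterns["pre"].shape[2]
        stacked = np.concatenate([per_image_patterns[c] for c in CONDITIONS], axis=0)
    if time is None:
        time = np.arange(n_times, dtype=float)
    if image_ids is None:
        image_ids = np.arange(n)

    values = np.empty((n_times, 3 * n, 3 * n))
    for t in range(n_times):
        if metric == "one_minus_r":
            values[t] = _one_minus_r_matrix(stacked[:, :, t])
        elif metric == "euclidean":
            values[t] = _euclidean_matrix(stacked[:, :, t])
        else:
            values[t] = _cv_euclidean_matrix(stacked, t)
        np.fill_diagonal(values[t], np.nan)
    return RDMSeries(time=np.asarray(time, float), values=values, metric=metric, image_ids=image_ids)


def subject_rdm_series(
    epochs: SensorEpochs, metric: str = "one_minus_r", k_mooney: int = 3
) -> list[RDMSeries]:
    """Per-subject RDM series from epochs (first-``k`` averaging for Mooney
    conditions and all grayscale presentations, per the analysis recipe)."""
    out = []
    for s in range(epochs.n_subjects):
        if metric == "cv_euclidean":
            trials = {c: condition_trials(epochs, c, subject=s) for c in CONDITIONS}
            out.append(rdm_series(metric=metric, time=epochs.time, trials=trials))
        else:
            pats = {
                c: average_presentations(
                    epochs, c, k=(3 if c == "gray" else k_mooney), subject=s
                )
                for c in CONDITIONS
            }
            out.append(rdm_series(pats, metric=metric, time=epochs.time))
    return out


def average_rdm_series(series: list[RDMSeries]) -> RDMSeries:
    """Cell-wise group average of per-subject RDM series."""
    if not series:
        raise ValueError("no series to average")
    values = np.mean([s.values for s in series], axis=0)
    first = series[0]
    return RDMSeries(first.time.copy(), values, first.metric, first.image_ids.copy())


def block_view(rdm, cond_a: str, cond_b: str) -> np.ndarray:
    """The ``cond_a`` x ``cond_b`` square of an RDM (matrix, stack, or
    :class:`RDMSeries`)."""
    matrix = rdm.values if isinstance(rdm, RDMSeries) else np.asarray(rdm)
    return condition_block(matrix, cond_a, cond_b)


def _upper_triangle(block: np.ndarray) -> np.ndarray:
    """Upper-triangle (off-diagonal) vector(s) of a ``... x n x n`` block."""
    n = block.shape[-1]
    iu = np.triu_indices(n, k=1)
    return block[..., iu[0], iu[1]]


def within_condition_dissimilarity_timecourse(series: RDMSeries, cond: str) -> np.ndarray:
    """Mean across-image dissimilarity inside one condition over time
    (mean of the off-diagonal upper triangle of the cond-cond square)."""
    if series.metric not in ("one_minus_r", "euclidean", "cv_euclidean"):
        raise ValueError(f"metric {series.metric!r} not supported for this summary")
    tri = _upper_triangle(series.block(cond, cond))
    return np.nanmean(tri, axis=-1)


def intra_rdm_correlation(
    series: RDMSeries,
    block_a: tuple[str, str] = ("pre", "pre"),
    block_b: tuple[str, str] = ("post", "post"),
) -> np.ndarray:
    """Representational-geometry correlation between two within-condition
    squares over time.

    Both squares are converted to similarity (1 - RDM), the upper-triangle
    values are Fisher-z transformed, correlated (Pearson) per time point,
    and the resulting r is Fisher-z transformed.  Returns a Fisher-z time
    course; undefined values (zero-variance triangles) propagate as NaN.
    """
    for pair in (block_a, block_b):
        if pair[0] != pair[1]:
            raise ValueError("intra-RDM analysis uses within-condition squares")
    za = fisher_z(1.0 - _upper_triangle(series.block(*block_a)))
    zb = fisher_z(1.0 - _upper_triangle(series.block(*block_b)))
    out = np.full(len(series.time), np.nan)
    for t in range(len(series.time)):
        a, b = za[t], zb[t]
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            continue
        r = np.corrcoef(a, b)[0, 1]
        out[t] = fisher_z(r)
    return out
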