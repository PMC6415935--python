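"""Group-level inference: cluster-based permutation tests and FDR.

Time-course and TGM significance use a one-tailed one-sample Wilcoxon
signed-rank test at every sample, clusters of contiguous below-threshold
samples (4-neighbour contiguity in 2-D), the summed signed-rank statistic W
as the cluster summary, and a max-cluster null built by randomly
sign-flipping each subject's deviation from chance.  For one-sample group
tests, per-subject sign flips are the exchangeability-preserving analogue
of shuffling class labels.

Model-RSA and fusion statistics use an RDM-order permutation null: each
permutation shuffles the (condition, image) entry order of the data RDM
identically along rows, columns and all time points, the cluster-forming
threshold is the
per-time 95th percentile of the null statistic, and cluster significance is
assessed against the 95th percentile of the null's maximum cluster size.

The signed-rank machinery is vectorized across samples and permutations
(ranks of |deviation| are invariant under sign flips, so they are computed
once per data set); it reproduces ``scipy.stats.wilcoxon`` exactly on
tie-free data and is validated against it in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import ClusterResult, RDMSeries

_EXACT_N_MAX = 25


@lru_cache(maxsize=64)
def _exact_sf(n: int) -> np.ndarray:
    """Survival function P(W+ >= w) of the signed-rank statistic under H0
    for sample size ``n`` (no ties, no zeros), w = 0 .. n(n+1)/2."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):  # polynomial product of (1 + x^r)
        counts[r:] += counts[:-r].copy()
    pmf = counts / counts.sum()
    sf = np.cumsum(pmf[::-1])[::-1]
    return sf


def signed_rank_test(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-tailed (greater) one-sample signed-rank test.

    ``diffs`` is ``subjects x samples``; zero differences are dropped
    (Wilcoxon convention) and ties in |diff| receive average ranks with a
    normal approximation, otherwise the exact null distribution is used.
    Returns ``(W, p)`` per sample.
    """
    diffs = np.asarray(diffs, dtype=float)
    n_subj, n_samp = diffs.shape
    absd = np.abs(diffs)
    nonzero = absd > 0
    n_eff = nonzero.sum(axis=0)
    # rank |diffs| per column, zeros pushed out of the ranking
    ranks = np.zeros_like(absd)
    has_tie = np.zeros(n_samp, dtype=bool)
    for j in range(n_samp):
        a = absd[nonzero[:, j], j]
        r = rankdata(a)
        ranks[nonzero[:, j], j] = r
        has_tie[j] = len(np.unique(a)) < len(a)
    W = np.sum(ranks * (diffs > 0), axis=0)

    p = np.ones(n_samp)
    for j in range(n_samp):
        n = int(n_eff[j])
        if n == 0:
            continue
        if n <= _EXACT_N_MAX and not has_tie[j]:
            p[j] = _exact_sf(n)[int(round(W[j]))]
        else:
            mu = n * (n + 1) / 4
            a = absd[nonzero[:, j], j]
            r = rankdata(a)
            var = np.sum(r**2) / 4  # tie-corrected variance of W+
            zval = (W[j] - mu - 0.5) / np.sqrt(var)
            from scipy.stats import norm

            p[j] = norm.sf(zval)
    return W, p


def _perm_W(ranks: np.ndarray, diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Signed-rank statistics for all sign-flip permutations at once.

    ``ranks``/``diffs``: subjects x samples, ``signs``: perms x subjects
    (+/-1).  |diffs| (hence ranks) are flip-invariant, so W+ under a flip
    only re-selects which ranks count as positive.
    """
    pos = ranks * (diffs > 0)
    neg = ranks * (diffs < 0)
    keep = signs > 0
    return np.einsum("ps,sj->pj", keep, pos) + np.einsum("ps,sj->pj", ~keep, neg)


def _p_from_W(W: np.ndarray, n_eff: int) -> np.ndarray:
    """Exact one-tailed p for tie-free data, vectorized over W."""
    sf = _exact_sf(n_eff)
    return sf[np.rint(W).astype(int)]


def _runs(mask: np.ndarray) -> list[np.ndarray]:
    """Index arrays of contiguous True runs in a 1-D mask."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def cluster_permutation_timecourse(
    values_per_subject: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 500,
    seed: int | None = None,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster-corrected one-sample test of a time course against chance.

    ``values_per_subject`` is ``subjects x time``.  Clusters are contiguous
    time points with one-tailed Wilcoxon p < ``cluster_alpha``; a cluster's
    summary is its summed W statistic, compared against the null of maximum
    cluster summaries over ``n_perm`` per-subject sign flips.
    """
    values = np.asarray(values_per_subject, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a subjects x time array with >= 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable null tail", stacklevel=2)
    diffs = values - chance
    W, p = signed_rank_test(diffs)
    clusters = _runs(p < cluster_alpha)
    summaries = np.array([W[c].sum() for c in clusters])

    rng = np.random.default_rng(seed)
    n_subj, n_time = diffs.shape
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    absd = np.abs(diffs)
    ranks = rankdata(absd, axis=0)
    ranks[absd == 0] = 0.0
    n_eff = int((absd > 0).sum(axis=0).min())
    tie_free = all(
        len(np.unique(absd[absd[:, j] > 0, j])) == (absd[:, j] > 0).sum()
        for j in range(n_time)
    )
    W_perm = _perm_W(ranks, diffs, signs)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        if tie_free and n_eff == n_subj and n_eff <= _EXACT_N_MAX:
            W_i = W_perm[i]
            p_i = _p_from_W(W_i, n_eff)
        else:
            W_i, p_i = signed_rank_test(diffs * signs[i][:, None])
        runs = _runs(p_i < cluster_alpha)
        null[i] = max((W_i[c].sum() for c in runs), default=0.0)

    pvals = np.array(
        [(1 + np.sum(null >= s)) / (n_perm + 1) for s in summaries]
    )
    mask = np.zeros(n_time, dtype=bool)
    for c, pv in zip(clusters, pvals):
        if pv < alpha:
            mask[c] = True
    return ClusterResult(clusters, summaries, pvals, mask, null=null, alpha=alpha)


def cluster_permutation_tgm(
    tgm_per_subject: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 500,
    seed: int | None = None,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
) -> ClusterResult:
    """2-D analogue of :func:`cluster_permutation_timecourse` for temporal
    generalization matrices (``subjects x train-time x test-time``), with
    4-neighbour contiguity in the train/test plane."""
    tgm = np.asarray(tgm_per_subject, dtype=float)
    if tgm.ndim != 3 or tgm.shape[0] < 2:
        raise ValueError("need subjects x train-time x test-time with >= 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable null tail", stacklevel=2)
    n_subj, t1, t2 = tgm.shape
    diffs = (tgm - chance).reshape(n_subj, t1 * t2)
    W, p = signed_rank_test(diffs)
    Wg, pg = W.reshape(t1, t2), p.reshape(t1, t2)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    def _clusters_2d(pgrid: np.ndarray, Wgrid: np.ndarray):
        lab, n_lab = ndimage.label(pgrid < cluster_alpha, structure=structure)
        cl, s = [], []
        for k in range(1, n_lab + 1):
            cells = np.argwhere(lab == k)
            cl.append(cells)
            s.append(Wgrid[lab == k].sum())
        return cl, np.asarray(s)

    clusters, summaries = _clusters_2d(pg, Wg)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    absd = np.abs(diffs)
    ranks = rankdata(absd, axis=0)
    ranks[absd == 0] = 0.0
    n_eff = int((absd > 0).sum(axis=0).min())
    tie_free = all(
        len(np.unique(absd[absd[:, j] > 0, j])) == (absd[:, j] > 0).sum()
        for j in range(diffs.shape[1])
    )
    W_perm = _perm_W(ranks, diffs, signs)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        if tie_free and n_eff == n_subj and n_eff <= _EXACT_N_MAX:
            W_i = W_perm[i]
            p_i = _p_from_W(W_i, n_eff)
        else:
            W_i, p_i = signed_rank_test(diffs * signs[i][:, None])
        _, s_i = _clusters_2d(p_i.reshape(t1, t2), W_i.reshape(t1, t2))
        null[i] = s_i.max() if len(s_i) else 0.0

    pvals = np.array([(1 + np.sum(null >= s)) / (n_perm + 1) for s in summaries])
    mask = np.zeros((t1, t2), dtype=bool)
    for cells, pv in zip(clusters, pvals):
        if pv < alpha:
            mask[cells[:, 0], cells[:, 1]] = True
    return ClusterResult(clusters, summaries, pvals, mask, null=null, alpha=alpha)


@dataclass
class OrderPermutationResult:
    """Image-order permutation null for an RDM-series statistic."""

    observed: np.ndarray
    null: np.ndarray          # perms x time
    threshold: np.ndarray     # per-time cluster-forming threshold
    clusters: ClusterResult


def permute_rdm_series(series: RDMSeries, order: np.ndarray) -> RDMSeries:
    """Apply one label-order shuffle identically to rows, columns, and all
    time points of an RDM series.

    ``order`` is a permutation of all ``3n`` (condition, image) entries.
    Shuffling whole entries — rather than conjugating by the same
    33-image permutation inside every condition block — is essential:
    a block-consistent image shuffle maps every model-RDM level class
    (block membership and diagonal-ness) onto itself, leaving the
    correlation with any block-structured model exactly unchanged and the
    null degenerate.
    """
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(series.side)):
        raise ValueError("order must be a permutation of all RDM entries")
    values = series.values[:, order][:, :, order]
    return RDMSeries(series.time, values, series.metric, series.image_ids)


def rdm_order_permutation_null(
    series: RDMSeries,
    statistic_fn,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> OrderPermutationResult:
    """Cluster inference for a statistic of an RDM series under image-order
    permutation.

    ``statistic_fn`` maps an :class:`RDMSeries` to a per-time statistic.
    Clusters form where the observed statistic exceeds the per-time 95th
    percentile of the null; a cluster is significant when its size exceeds
    the 95th percentile of the null's maximum cluster size.
    """
    observed = np.asarray(statistic_fn(series), dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(observed)))
    for i in range(n_perm):
        order = rng.permutation(series.side)
        null[i] = statistic_fn(permute_rdm_series(series, order))
    threshold = np.nanpercentile(null, 100 * (1 - alpha), axis=0)

    clusters = _runs(observed > threshold)
    sizes = np.array([len(c) for c in clusters], dtype=float)
    null_max_size = np.zeros(n_perm)
    for i in range(n_perm):
        runs = _runs(null[i] > threshold)
        null_max_size[i] = max((len(r) for r in runs), default=0)
    size_cut = np.percentile(null_max_size, 100 * (1 - alpha))
    pvals = np.array(
        [(1 + np.sum(null_max_size >= s)) / (n_perm + 1) for s in sizes]
    )
    mask = np.zeros(len(observed), dtype=bool)
    for c, s in zip(clusters, sizes):
        if s > size_cut:
            mask[c] = True
    result = ClusterResult(clusters, sizes, pvals, mask, null=null_max_size, alpha=alpha)
    return OrderPermutationResult(observed, null, threshold, result)


def fdr_mask(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask at level ``q`` (True = significant)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
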