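"""Model-based RSA time courses and MEG-fMRI fusion via commonality analysis.

The fusion asks, for every (ROI, time point) cell, how much of the variance
shared between the sensor-level RDM at that time and the ROI's activation
RDM is accounted for by a theoretical model.  With R² denoting the
coefficient of determination of the MEG RDM vector regressed on a predictor
set, the *shared* commonality of model M1 is

    C = R²(MEG ~ fMRI) + R²(MEG ~ M1) - R²(MEG ~ {fMRI, M1})

and the commonality of M1 *unique* with respect to a second model M2 is

    C = R²(MEG ~ {fMRI, M2}) + R²(MEG ~ {M1, M2})
        - R²(MEG ~ M2) - R²(MEG ~ {fMRI, M1, M2}).

All RDM and model vectors are rank-transformed (average ranks for ties)
before the ordinary least-squares fits, so a single-predictor R² equals the
squared Spearman rho; cells missing in any vector of an equation are
excluded listwise.  Negative commonalities (suppression) are reported, not
clipped.  The squared Spearman correlation between MEG and ROI RDMs bounds
the commonality any model can reach at that cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from .containers import ModelRDM, RDMSeries
from .simulate import ROIPatterns
from .stats import _runs


def _upper_indices(side: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(side, k=1)


def roi_rdm(roi_patterns: ROIPatterns | np.ndarray) -> dict[str, np.ndarray] | np.ndarray:
    """1 - Pearson correlation RDM(s) from ROI activation patterns.

    Accepts a :class:`ROIPatterns` bundle (returns a dict of matrices) or a
    single ``N x features`` array.  The main diagonal is NaN.
    """
    if isinstance(roi_patterns, ROIPatterns):
        return {k: roi_rdm(v) for k, v in roi_patterns.patterns.items()}
    pats = np.asarray(roi_patterns, dtype=float)
    if np.any(pats.std(axis=1) == 0):
        raise ValueError("zero-variance activation pattern in ROI RDM")
    out = 1.0 - np.corrcoef(pats)
    np.fill_diagonal(out, np.nan)
    return out


def _triangle(matrix: np.ndarray) -> np.ndarray:
    iu = _upper_indices(matrix.shape[-1])
    return matrix[..., iu[0], iu[1]]


def model_rsa_timecourse(series: RDMSeries, model: ModelRDM) -> np.ndarray:
    """Spearman rho between the model and the (group-averaged) RDM at every
    time point, over the non-missing upper-triangle cells."""
    mvec = _triangle(model.masked())
    dvec = _triangle(series.values)
    ok = np.isfinite(mvec)
    out = np.empty(len(series.time))
    for t in range(len(series.time)):
        use = ok & np.isfinite(dvec[t])
        if use.sum() < 3:
            raise ValueError("fewer than 3 usable cells for the model correlation")
        out[t] = spearmanr(mvec[use], dvec[t][use]).statistic
    return out


@dataclass
class CommonalityTerms:
    """R² terms and the resulting commonality of one equation."""

    r2: dict[str, float]
    commonality: float
    m1: str = ""
    m2: str | None = None
    roi: str | None = None
    time: float | None = None


def _rank_center(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    return r - r.mean()


def _r2_subset(c: np.ndarray, G: np.ndarray, yss: float, idx: list[int]) -> float:
    """R² of y on predictor subset ``idx`` from precomputed cross-products
    (c = X'y, G = X'X, yss = y'y), via pseudoinverse when rank-deficient."""
    if not idx or yss == 0:
        return 0.0
    Gs = G[np.ix_(idx, idx)]
    cs = c[idx]
    try:
        beta = np.linalg.solve(Gs, cs)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient predictor set; using pseudoinverse", stacklevel=2)
        beta = np.linalg.pinv(Gs) @ cs
    return float(np.clip(cs @ beta / yss, 0.0, 1.0))


def _prepare_vectors(*vecs: np.ndarray) -> list[np.ndarray]:
    """Listwise-exclude cells missing in any vector, then rank-center."""
    ok = np.ones(len(vecs[0]), dtype=bool)
    for v in vecs:
        ok &= np.isfinite(v)
    if ok.sum() < 4:
        raise ValueError("fewer than 4 shared non-missing cells")
    return [_rank_center(v[ok]) for v in vecs]


def commonality_shared(
    meg_rdm: np.ndarray, fmri_rdm: np.ndarray, model: ModelRDM
) -> CommonalityTerms:
    """Shared variance between the MEG RDM, the fMRI RDM, and one model."""
    y, f, m1 = _prepare_vectors(
        _triangle(np.asarray(meg_rdm)),
        _triangle(np.asarray(fmri_rdm)),
        _triangle(model.masked()),
    )
    X = np.column_stack([f, m1])
    G, c, yss = X.T @ X, X.T @ y, float(y @ y)
    r2 = {
        "MEG.fMRI": _r2_subset(c, G, yss, [0]),
        "MEG.M1": _r2_subset(c, G, yss, [1]),
        "MEG.fMRI,M1": _r2_subset(c, G, yss, [0, 1]),
    }
    C = r2["MEG.fMRI"] + r2["MEG.M1"] - r2["MEG.fMRI,M1"]
    return CommonalityTerms(r2=r2, commonality=C, m1=model.kind)


def commonality_unique(
    meg_rdm: np.ndarray, fmri_rdm: np.ndarray, m1: ModelRDM, m2: ModelRDM
) -> CommonalityTerms:
    """Variance shared between MEG, fMRI, and model ``m1`` that is not
    explained by model ``m2``."""
    y, f, v1, v2 = _prepare_vectors(
        _triangle(np.asarray(meg_rdm)),
        _triangle(np.asarray(fmri_rdm)),
        _triangle(m1.masked()),
        _triangle(m2.masked()),
    )
    X = np.column_stack([f, v1, v2])
    G, c, yss = X.T @ X, X.T @ y, float(y @ y)
    r2 = {
        "MEG.fMRI,M2": _r2_subset(c, G, yss, [0, 2]),
        "MEG.M1,M2": _r2_subset(c, G, yss, [1, 2]),
        "MEG.M2": _r2_subset(c, G, yss, [2]),
        "MEG.fMRI,M1,M2": _r2_subset(c, G, yss, [0, 1, 2]),
    }
    C = r2["MEG.fMRI,M2"] + r2["MEG.M1,M2"] - r2["MEG.M2"] - r2["MEG.fMRI,M1,M2"]
    return CommonalityTerms(r2=r2, commonality=C, m1=m1.kind, m2=m2.kind)


def fusion_upper_bound(series: RDMSeries, fmri_rdm: np.ndarray) -> np.ndarray:
    """Squared Spearman rho between MEG and ROI RDM upper triangles per
    time point — the ceiling on model-explained shared variance."""
    fvec = _triangle(np.asarray(fmri_rdm))
    dvec = _triangle(series.values)
    ok_f = np.isfinite(fvec)
    out = np.empty(len(series.time))
    for t in range(len(series.time)):
        use = ok_f & np.isfinite(dvec[t])
        out[t] = spearmanr(fvec[use], dvec[t][use]).statistic ** 2
    return out


@dataclass
class FusionMap:
    """ROI x time commonality values, significance masks, and upper bounds."""

    time: np.ndarray
    rois: list[str]
    commonality: dict[str, np.ndarray]          # model kind -> ROI x time
    mask: dict[str, np.ndarray]                 # model kind -> ROI x time bool
    upper_bound: dict[str, np.ndarray] = field(default_factory=dict)  # roi -> time
    onsets: dict[str, dict[str, float]] = field(default_factory=dict)

    def onset(self, kind: str, roi: str) -> float:
        """Earliest significant time for one model in one ROI (NaN if none)."""
        i = self.rois.index(roi)
        sig = np.flatnonzero(self.mask[kind][i])
        return float(self.time[sig[0]]) if sig.size else float("nan")


def _commonality_stat(
    y_ranked: np.ndarray, preds: dict[str, np.ndarray], kind: str
) -> float:
    """One commonality value from pre-ranked vectors on a shared support."""
    if kind == "attention":
        X = np.column_stack([preds["fmri"], preds["attention"]])
        G, c = X.T @ X, X.T @ y_ranked
        yss = float(y_ranked @ y_ranked)
        return (
            _r2_subset(c, G, yss, [0])
            + _r2_subset(c, G, yss, [1])
            - _r2_subset(c, G, yss, [0, 1])
        )
    other = "recognition" if kind == "stimulus" else "stimulus"
    X = np.column_stack([preds["fmri"], preds[kind], preds[other]])
    G, c = X.T @ X, X.T @ y_ranked
    yss = float(y_ranked @ y_ranked)
    return (
        _r2_subset(c, G, yss, [0, 2])
        + _r2_subset(c, G, yss, [1, 2])
        - _r2_subset(c, G, yss, [2])
        - _r2_subset(c, G, yss, [0, 1, 2])
    )


def fusion_map(
    meg_series: RDMSeries,
    roi_rdms: dict[str, np.ndarray],
    models: dict[str, ModelRDM],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> FusionMap:
    """Model-driven MEG-fMRI fusion over all ROIs and time points.

    For the stimulus and recognition models the commonality is the variance
    unique with respect to the other model; for the attention model it is
    the plain shared commonality.  Significance per (ROI, model) is a
    cluster test over time against an image-order permutation null, further
    masked to cells where both the MEG-model and the fMRI-model
    correlations are themselves significant under the same kind of null.
    All permutations share one image-order sequence per iteration.
    """
    from .stats import permute_rdm_series  # local import to avoid cycles

    kinds = list(models)
    rois = list(roi_rdms)
    side = meg_series.side
    n_time = len(meg_series.time)
    rng = np.random.default_rng(seed)
    orders = [rng.permutation(side) for _ in range(n_perm)]

    # supports (upper-triangle masks) per model equation
    tri_models = {k: _triangle(m.masked()) for k, m in models.items()}
    tri_meg = _triangle(meg_series.values)  # time x cells
    tri_fmri = {r: _triangle(np.asarray(m)) for r, m in roi_rdms.items()}

    def support(kind: str) -> np.ndarray:
        ok = np.isfinite(tri_models[kind])
        if kind in ("stimulus", "recognition"):
            other = "recognition" if kind == "stimulus" else "stimulus"
            ok = ok & np.isfinite(tri_models[other])
        for r in rois:
            ok = ok & np.isfinite(tri_fmri[r])
        return ok

    supports = {k: support(k) for k in kinds}

    def commonality_grid(series: RDMSeries) -> dict[str, np.ndarray]:
        # cells missing in the data (the permuted diagonal) are excluded
        # listwise per equation, per series
        tri = _triangle(series.values)
        data_ok = np.all(np.isfinite(tri), axis=0)
        out = {k: np.empty((len(rois), n_time)) for k in kinds}
        for k in kinds:
            sup = supports[k] & data_ok
            preds_base = {kk: _rank_center(tri_models[kk][sup]) for kk in kinds}
            y_ranked = np.empty((n_time, int(sup.sum())))
            for t in range(n_time):
                y_ranked[t] = _rank_center(tri[t][sup])
            for ri, r in enumerate(rois):
                preds = dict(preds_base)
                preds["fmri"] = _rank_center(tri_fmri[r][sup])
                for t in range(n_time):
                    out[k][ri, t] = _commonality_stat(y_ranked[t], preds, k)
        return out

    observed = commonality_grid(meg_series)
    null = {k: np.empty((n_perm, len(rois), n_time)) for k in kinds}
    # MEG-model correlation nulls share the same orders
    meg_model_obs = {k: model_rsa_timecourse(meg_series, models[k]) for k in kinds}
    meg_model_null = {k: np.empty((n_perm, n_time)) for k in kinds}
    for i, order in enumerate(orders):
        perm = permute_rdm_series(meg_series, order)
        grid = commonality_grid(perm)
        for k in kinds:
            null[k][i] = grid[k]
            meg_model_null[k][i] = model_rsa_timecourse(perm, models[k])

    # fMRI-model correlations: permutation p per (ROI, model)
    fmri_model_sig = {k: {} for k in kinds}
    for k in kinds:
        sup = np.isfinite(tri_models[k])
        for r in rois:
            use = sup & np.isfinite(tri_fmri[r])
            obs = spearmanr(tri_models[k][use], tri_fmri[r][use]).statistic
            iu = _upper_indices(side)
            fmat = np.asarray(roi_rdms[r])
            nulls = np.empty(n_perm)
            for i, order in enumerate(orders):
                fperm = fmat[order][:, order]
                fvec = fperm[iu[0], iu[1]]
                u2 = sup & np.isfinite(fvec)
                nulls[i] = spearmanr(tri_models[k][u2], fvec[u2]).statistic
            fmri_model_sig[k][r] = obs > np.percentile(nulls, 100 * (1 - alpha))

    commonality = {k: observed[k] for k in kinds}
    mask = {}
    for k in kinds:
        m = np.zeros((len(rois), n_time), dtype=bool)
        thr_meg = np.percentile(meg_model_null[k], 100 * (1 - alpha), axis=0)
        meg_sig = meg_model_obs[k] > thr_meg
        for ri, r in enumerate(rois):
            thr = np.percentile(null[k][:, ri, :], 100 * (1 - alpha), axis=0)
            clusters = _runs(observed[k][ri] > thr)
            null_max = np.zeros(n_perm)
            for i in range(n_perm):
                runs = _runs(null[k][i, ri] > thr)
                null_max[i] = max((len(rr) for rr in runs), default=0)
            cut = np.percentile(null_max, 100 * (1 - alpha))
            for c in clusters:
                if len(c) > cut:
                    m[ri, c] = True
            if not fmri_model_sig[k][r]:
                m[ri] = False
        mask[k] = m & meg_sig[np.newaxis, :]

    upper = {r: fusion_upper_bound(meg_series, roi_rdms[r]) for r in rois}
    result = FusionMap(
        time=meg_series.time.copy(),
        rois=rois,
        commonality=commonality,
        mask=mask,
        upper_bound=upper,
    )
    result.onsets = {k: {r: result.onset(k, r) for r in rois} for k in kinds}
    return result
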