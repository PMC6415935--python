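"""Commonality analysis, model RSA, ROI RDMs, fusion bounds."""

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

import mooneyrsa as m
from mooneyrsa.containers import RDMSeries
from mooneyrsa.fusion import (
    commonality_shared,
    commonality_unique,
    fusion_upper_bound,
    model_rsa_timecourse,
    roi_rdm,
)
from mooneyrsa.models import build_model_rdm


def _vec_to_rdm(vec, n):
    """Place an upper-triangle vector into a symmetric matrix (NaN diag)."""
    out = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def _model_from_matrix(matrix, kind="stimulus"):
    from mooneyrsa.containers import ModelRDM

    missing = ~np.isfinite(matrix)
    vals = np.where(missing, 0.0, matrix)
    return ModelRDM(vals, missing, kind, np.arange(matrix.shape[0] // 3 or 1))


def _r2_lstsq(y, X):
    """Independent R² oracle: explicit least squares on centered ranks."""
    yc = rankdata(y) - np.mean(rankdata(y))
    Xc = np.column_stack([rankdata(x) - np.mean(rankdata(x)) for x in X])
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return 1 - resid @ resid / (yc @ yc)


def test_roi_rdm_duplicate_and_hand_computed():
    pats = np.array([[1.0, 0.0, 2.0], [1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
    rdm = roi_rdm(pats)
    assert rdm[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert rdm[0, 2] == pytest.approx(0.5, abs=1e-12)  # hand-computed 1 - r
    assert np.isnan(rdm[1, 1])
    with pytest.raises(ValueError):
        roi_rdm(np.array([[1.0, 1.0], [0.0, 1.0]]))


def test_model_as_data_has_rho_one():
    mdl = build_model_rdm("recognition", 6)
    series = RDMSeries(
        np.array([0.0]), mdl.masked()[np.newaxis], "one_minus_r", np.arange(6)
    )
    rho = model_rsa_timecourse(series, mdl)
    assert rho[0] == pytest.approx(1.0, abs=1e-12)


def test_random_rdm_has_rho_near_zero():
    rng = np.random.default_rng(0)
    mdl = build_model_rdm("stimulus", 8)
    vals = []
    for _ in range(50):
        mat = _vec_to_rdm(rng.standard_normal(24 * 23 // 2), 24)
        series = RDMSeries(np.array([0.0]), mat[np.newaxis], "one_minus_r", np.arange(8))
        vals.append(model_rsa_timecourse(series, mdl)[0])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals)) < 3 * se


def test_commonality_shared_duplicate_predictor():
    """Model identical to the fMRI RDM: C equals R²(MEG ~ fMRI) exactly."""
    rng = np.random.default_rng(1)
    n = 9
    f = _vec_to_rdm(rng.standard_normal(n * (n - 1) // 2), n)
    meg = _vec_to_rdm(rng.standard_normal(n * (n - 1) // 2), n)
    terms = commonality_shared(meg, f, _model_from_matrix(f))
    assert terms.commonality == pytest.approx(terms.r2["MEG.fMRI"], abs=1e-10)


def test_commonality_shared_matches_regression_oracle():
    """6-cell vectors: equals the three explicit regressions."""
    rng = np.random.default_rng(2)
    n = 4  # 4x... use a 4-entity grid -> 6 upper cells
    yv, fv, mv = rng.standard_normal((3, 6))
    meg, f = _vec_to_rdm(yv, n), _vec_to_rdm(fv, n)
    mdl = _model_from_matrix(_vec_to_rdm(mv, n))
    terms = commonality_shared(meg, f, mdl)
    r2_f = _r2_lstsq(yv, [fv])
    r2_m = _r2_lstsq(yv, [mv])
    r2_fm = _r2_lstsq(yv, [fv, mv])
    assert terms.commonality == pytest.approx(r2_f + r2_m - r2_fm, abs=1e-10)
    assert terms.r2["MEG.fMRI"] == pytest.approx(r2_f, abs=1e-10)


def test_commonality_unique_matches_regression_oracle():
    """8-cell vectors: equals the brute-force four-regression evaluation;
    negative values (suppression) are preserved."""
    rng = np.random.default_rng(3)
    sims = []
    for trial in range(30):
        vecs = rng.standard_normal((4, 10))
        n = 5  # 5 entities -> 10 upper cells
        meg, f = _vec_to_rdm(vecs[0], n), _vec_to_rdm(vecs[1], n)
        m1 = _model_from_matrix(_vec_to_rdm(vecs[2], n))
        m2 = _model_from_matrix(_vec_to_rdm(vecs[3], n))
        terms = commonality_unique(meg, f, m1, m2)
        expected = (
            _r2_lstsq(vecs[0], [vecs[1], vecs[3]])
            + _r2_lstsq(vecs[0], [vecs[2], vecs[3]])
            - _r2_lstsq(vecs[0], [vecs[3]])
            - _r2_lstsq(vecs[0], [vecs[1], vecs[2], vecs[3]])
        )
        assert terms.commonality == pytest.approx(expected, abs=1e-10)
        sims.append(terms.commonality)
    assert min(sims) < 0  # suppression occurs and is not clipped


def test_commonality_unique_degenerate_cases():
    rng = np.random.default_rng(4)
    n = 9
    yv = rng.standard_normal(n * (n - 1) // 2)
    fv = rng.standard_normal(len(yv))
    mv = rng.standard_normal(len(yv))
    meg, f = _vec_to_rdm(yv, n), _vec_to_rdm(fv, n)
    m1 = _model_from_matrix(_vec_to_rdm(mv, n))
    # m1 == m2: no unique variance at all
    with pytest.warns(UserWarning, match="rank-deficient"):
        terms = commonality_unique(meg, f, m1, m1)
    assert terms.commonality == pytest.approx(0.0, abs=1e-8)


def test_r2_monotone_in_predictor_set():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 8
        yv = rng.standard_normal(n * (n - 1) // 2)
        fv, m1v, m2v = rng.standard_normal((3, len(yv)))
        terms = commonality_unique(
            _vec_to_rdm(yv, n),
            _vec_to_rdm(fv, n),
            _model_from_matrix(_vec_to_rdm(m1v, n)),
            _model_from_matrix(_vec_to_rdm(m2v, n)),
        )
        assert 0.0 <= terms.r2["MEG.M2"] <= terms.r2["MEG.fMRI,M2"] + 1e-12
        assert terms.r2["MEG.M1,M2"] <= terms.r2["MEG.fMRI,M1,M2"] + 1e-12
        assert all(0.0 <= v <= 1.0 for v in terms.r2.values())


def test_variance_partition_closure():
    """unique(fMRI) + unique(M1) + common == R²(full) on random instances."""
    rng = np.random.default_rng(6)
    for _ in range(20):
        n = 7
        yv = rng.standard_normal(n * (n - 1) // 2)
        fv, mv = rng.standard_normal((2, len(yv)))
        meg, f = _vec_to_rdm(yv, n), _vec_to_rdm(fv, n)
        terms = commonality_shared(meg, f, _model_from_matrix(_vec_to_rdm(mv, n)))
        r2_full = terms.r2["MEG.fMRI,M1"]
        unique_f = r2_full - terms.r2["MEG.M1"]
        unique_m = r2_full - terms.r2["MEG.fMRI"]
        assert unique_f + unique_m + terms.commonality == pytest.approx(
            r2_full, abs=1e-10
        )


def test_fusion_upper_bound_limits():
    rng = np.random.default_rng(7)
    n = 9
    mat = _vec_to_rdm(rng.standard_normal(n * (n - 1) // 2), n)
    series = RDMSeries(np.array([0.0]), mat[np.newaxis], "one_minus_r", np.arange(3))
    assert fusion_upper_bound(series, mat)[0] == pytest.approx(1.0, abs=1e-12)
    other = _vec_to_rdm(rng.standard_normal(n * (n - 1) // 2), n)
    assert fusion_upper_bound(series, other)[0] < 0.3


def test_commonality_never_exceeds_upper_bound():
    """Model-explained shared variance stays below the squared MEG-fMRI
    Spearman correlation (the variance-partition ceiling)."""
    rng = np.random.default_rng(8)
    n = 12
    for _ in range(20):
        yv = rng.standard_normal(n * (n - 1) // 2)
        fv = yv * 0.5 + rng.standard_normal(len(yv))
        mv = yv * 0.3 + rng.standard_normal(len(yv))
        meg, f = _vec_to_rdm(yv, n), _vec_to_rdm(fv, n)
        terms = commonality_shared(meg, f, _model_from_matrix(_vec_to_rdm(mv, n)))
        bound = spearmanr(yv, fv).statistic ** 2
        assert terms.commonality <= bound + 1e-10


def test_too_few_cells_error():
    mdl = build_model_rdm("stimulus", 2)
    series = RDMSeries(
        np.array([0.0]), np.full((1, 6, 6), np.nan), "one_minus_r", np.arange(2)
    )
    with pytest.raises(ValueError):
        model_rsa_timecourse(series, mdl)
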