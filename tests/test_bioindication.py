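"""Transfer-function unit tests: WA oracle, filtering, recalibration, errors."""

import numpy as np
import pytest

from climdebt import bioindication as bio
from conftest import toy_matrix


# -- matrix building and filtering ----------------------------------------

def test_build_matrix_pivots_presences(small_system):
    _, surveys, _ = small_system
    import pandas as pd

    sub = surveys.head(20)
    resp = pd.Series(np.arange(20.0), index=sub.index)
    m = bio.build_matrix(sub, resp)
    assert m.n_surveys == 20
    assert set(np.unique(m.matrix)) <= {0.0, 1.0}
    # row sums equal richness
    assert np.array_equal(m.matrix.sum(axis=1), sub["richness"].to_numpy(float))


def test_filter_calibration_reaches_fixed_point():
    rng = np.random.default_rng(3)
    mat = (rng.random((60, 30)) < 0.15).astype(float)
    m = bio.CommunityMatrix(mat, np.arange(60), np.arange(30), rng.normal(size=60))
    f, report = bio.filter_calibration(m, min_richness=3, min_occurrences=4)
    assert (f.matrix.sum(axis=1) >= 3).all()
    assert (f.matrix.sum(axis=0) >= 4).all()
    assert report["dropped_surveys"] == m.n_surveys - f.n_surveys
    assert report["dropped_species"] == m.n_species - f.n_species


def test_filter_calibration_empty_raises():
    m = bio.CommunityMatrix(
        np.eye(4), np.arange(4), np.arange(4), np.arange(4.0)
    )
    with pytest.raises(ValueError):
        bio.filter_calibration(m, min_richness=5, min_occurrences=5)


# -- WA-PLS stage ----------------------------------------------------------

def classical_wa_oracle(Y, x):
    """Hand-computed classical weighted averaging with linear deshrinking."""
    optima = (Y.T @ x) / Y.sum(axis=0)
    site = (Y @ optima) / Y.sum(axis=1)
    design = np.column_stack([np.ones(len(x)), site])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return design @ beta


def test_one_component_wapls_equals_classical_wa():
    m, _ = toy_matrix(n_surveys=120, seed=5)
    model = bio.fit_wapls(m, 1)
    oracle = classical_wa_oracle(m.matrix, m.response)
    assert np.allclose(model.fitted, oracle, atol=1e-10)
    assert np.allclose(model.predict(m.matrix), oracle, atol=1e-10)


def test_additional_components_never_worsen_training_rmsd():
    m, _ = toy_matrix(n_surveys=150, seed=8)
    model = bio.fit_wapls(m, 4)
    assert np.all(np.diff(model.rmsd_per_component) <= 1e-9)


def test_site_scores_are_richness_weighted_orthogonal():
    m, _ = toy_matrix(n_surveys=150, seed=8)
    model = bio.fit_wapls(m, 3)
    s = model.site_scores(m.matrix)
    rows = m.matrix.sum(axis=1)
    g = s.T @ (rows[:, None] * s)
    off = g - np.diag(np.diag(g))
    assert np.max(np.abs(off)) < 1e-6 * np.max(np.abs(np.diag(g)))


def test_constant_response_raises():
    m, _ = toy_matrix(n_surveys=50)
    m.response[:] = 7.0
    with pytest.raises(ValueError):
        bio.fit_wapls(m, 1)


def test_zero_occurrence_species_raises():
    m, _ = toy_matrix(n_surveys=50)
    m.matrix[:, 0] = 0.0
    with pytest.raises(ValueError):
        bio.fit_wapls(m, 1)


def test_component_count_bounds():
    m, _ = toy_matrix(n_surveys=50)
    with pytest.raises(ValueError):
        bio.fit_wapls(m, 0)
    with pytest.raises(ValueError):
        bio.fit_wapls(m, m.n_surveys)


def test_cv_component_selection_returns_valid_count():
    m, _ = toy_matrix(n_surveys=120, seed=9)
    best, curve = bio.select_wapls_components(m, max_components=4, seed=0)
    assert 1 <= best <= 4
    assert np.isfinite(curve[best - 1])
    assert curve[best - 1] == np.min(curve[:4])


# -- hybrid model and recalibration ---------------------------------------

def test_fit_transfer_recovers_gradient():
    m, truth = toy_matrix(n_surveys=220, seed=11)
    model = bio.fit_transfer(m, n_components=2, n_trees=100, seed=0)
    pred = bio.predict_frt(model, m.matrix)
    assert np.corrcoef(pred, m.response)[0, 1] ** 2 > 0.9
    assert model.calibration_rmsd < 1.0


def test_recalibration_slope_is_below_one_and_stored():
    m, _ = toy_matrix(n_surveys=220, seed=11)
    model = bio.fit_transfer(m, n_components=2, n_trees=100, seed=0)
    meta = model.metadata["recalibration"]
    assert 0.2 < model.recal_slope < 1.0  # inverse regression attenuates
    assert meta["slope"] == model.recal_slope
    assert model.calibration_range == (m.response.min(), m.response.max())


def test_recalibration_reduces_edge_compression():
    # the residual forest overfits in-sample, so attenuation (slope < 1 of
    # prediction on observed) only shows on held-out surveys; broad niches
    # make composition weakly informative, which is what produces it
    m, _ = toy_matrix(n_surveys=440, breadth=4.0, seed=11)
    train = m.subset(row_idx=np.arange(0, 440, 2))
    occupied = np.flatnonzero(train.matrix.sum(axis=0) > 0)
    train = train.subset(col_idx=occupied)
    hold = m.subset(row_idx=np.arange(1, 440, 2)).subset(col_idx=occupied)
    plain = bio.fit_transfer(train, n_components=2, n_trees=100, seed=0,
                             recalibrate=False)
    recal = bio.fit_transfer(train, n_components=2, n_trees=100, seed=0)

    def slope(model):
        pred = bio.predict_frt(model, hold.matrix)
        return np.polyfit(hold.response, pred, 1)[0]

    s_plain, s_recal = slope(plain), slope(recal)
    assert s_plain < 1.0          # attenuation without recalibration
    assert s_recal > s_plain      # recalibration raises the slope
    assert abs(s_recal - 1.0) < 0.08  # and lands near the identity line


def test_small_calibration_skips_recalibration():
    m, _ = toy_matrix(n_surveys=30, seed=4)
    sub = m.subset(row_idx=np.arange(20))
    occupied = np.flatnonzero(sub.matrix.sum(axis=0) > 0)
    sub = sub.subset(col_idx=occupied)
    model = bio.fit_transfer(sub, n_components=1, n_trees=20, seed=0)
    assert model.recal_slope == 1.0 and model.recal_intercept == 0.0


def test_align_to_model_counts_unknown_species():
    m, _ = toy_matrix(n_surveys=60, seed=2)
    model = bio.fit_transfer(m, n_components=1, n_trees=20, seed=0, recalibrate=False)
    lists = [[int(model.species_ids[0]), 99999], [99999, 88888]]
    mat, unknown = bio.align_to_model(model, lists)
    assert unknown.tolist() == [1, 2]
    assert mat[0].sum() == 1 and mat[1].sum() == 0


def test_predict_surveys_flags_no_analogue_rows(small_system):
    import pandas as pd

    m, _ = toy_matrix(n_surveys=120, seed=5)
    model = bio.fit_transfer(m, n_components=1, n_trees=20, seed=0, recalibrate=False)
    df = pd.DataFrame(
        {
            "survey_id": [0, 1],
            "species": [[int(model.species_ids[0]), int(model.species_ids[1])], [99999]],
        }
    ).set_index("survey_id", drop=False)
    frt, unknown = bio.predict_surveys(model, df)
    assert np.isfinite(frt.iloc[0])
    assert np.isnan(frt.iloc[1])


def test_compute_debt_sign_convention():
    assert bio.compute_debt(10.0, 9.0) == pytest.approx(1.0)
    arr = bio.compute_debt(np.array([10.0, 8.0]), np.array([9.5, 8.5]))
    assert np.allclose(arr, [0.5, -0.5])
    with pytest.raises(ValueError):
        bio.compute_debt(np.nan, 1.0)


def test_validate_transfer_reports_holdout_fit():
    m, _ = toy_matrix(n_surveys=200, seed=13)
    train = m.subset(row_idx=np.arange(0, 200, 2))
    occupied = np.flatnonzero(train.matrix.sum(axis=0) > 0)
    train = train.subset(col_idx=occupied)
    hold = m.subset(row_idx=np.arange(1, 200, 2))
    model = bio.fit_transfer(train, n_components=2, n_trees=100, seed=0)
    stats = bio.validate_transfer(model, hold)
    assert stats["r2"] > 0.85
    assert stats["rmsd"] < 1.2
    assert stats["n"] == hold.n_surveys
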