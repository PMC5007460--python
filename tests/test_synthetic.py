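"""Generator invariants: determinism, planted truth, placement and round-trips."""

import numpy as np
import pandas as pd
import pytest

from climdebt.config import SimulationConfig
from climdebt.synthetic import (
    generate_infrastructure,
    generate_landscape,
    generate_species_pool,
    read_surveys_csv,
    simulate,
    write_surveys_csv,
)
from conftest import small_config


def test_same_seed_reproduces_everything(small_cfg, small_system):
    landscape, surveys, truth = small_system
    landscape2, surveys2, truth2 = simulate(small_cfg)
    assert np.allclose(
        landscape.temperature_base.values, landscape2.temperature_base.values
    )
    pd.testing.assert_frame_equal(surveys.drop(columns="species"),
                                  surveys2.drop(columns="species"))
    assert all(a == b for a, b in zip(surveys["species"], surveys2["species"]))
    pd.testing.assert_series_equal(truth.true_debt, truth2.true_debt)


def test_different_seeds_differ():
    a = simulate(small_config(seed=1))[1]
    b = simulate(small_config(seed=2))[1]
    assert not np.array_equal(a["x"].to_numpy(), b["x"].to_numpy())


def test_true_debt_is_lambda_times_warming(small_system, small_cfg):
    _, surveys, truth = small_system
    lam = small_cfg.lag_lambda
    expected = surveys["year"].map(small_cfg.warming_at) * lam
    assert np.allclose(truth.true_debt.to_numpy(), expected.to_numpy())
    base = surveys["period"] == "baseline"
    assert np.all(truth.true_debt[base] == 0.0)


def test_callable_lambda_is_evaluated_per_survey():
    cfg = small_config(lag_lambda=lambda t: np.clip((t - 5.0) / 20.0, 0, 1))
    _, surveys, truth = simulate(cfg)
    study = surveys["period"] == "study"
    assert truth.lag[study].nunique() > 1
    assert np.allclose(truth.true_debt, truth.lag * truth.delta_t)


def test_invalid_callable_lambda_raises():
    cfg = small_config(lag_lambda=lambda t: np.full_like(t, 2.0))
    with pytest.raises(ValueError):
        simulate(cfg)


def test_minimum_richness_enforced(small_system, small_cfg):
    _, surveys, _ = small_system
    assert (surveys["richness"] >= small_cfg.min_richness).all()
    assert all(len(s) == r for s, r in zip(surveys["species"], surveys["richness"]))


def test_surveys_fall_on_forest(small_system):
    landscape, surveys, _ = small_system
    for period, mask_raster in [
        ("baseline", landscape.forest_baseline),
        ("study", landscape.forest_study),
    ]:
        sub = surveys[surveys["period"] == period]
        iy, ix = mask_raster.cell_of(sub["x"].to_numpy(), sub["y"].to_numpy())
        assert np.all(mask_raster.values[iy, ix] > 0.5)


def test_study_forest_is_subset_of_baseline(small_system):
    landscape, _, _ = small_system
    base = landscape.forest_baseline.values > 0.5
    study = landscape.forest_study.values > 0.5
    assert np.all(base[study])
    assert study.sum() < base.sum()


def test_warming_raises_study_period_mean(small_system, small_cfg):
    landscape, _, _ = small_system
    diff = (
        landscape.period_mean("temperature", "study").values
        - landscape.period_mean("temperature", "baseline").values
    )
    # step profile: every study year carries the full warming
    assert diff.mean() == pytest.approx(small_cfg.warming_total, abs=0.05)


def test_species_pool_margins_and_breadths(small_cfg, small_system):
    landscape, _, truth = small_system
    pool = truth.pool
    t = landscape.temperature_base.values
    assert pool["t_opt"].min() < t.min()  # pool extends beyond the territory
    assert pool["t_opt"].max() > t.max()
    assert (pool["t_breadth"] > 0).all()
    assert pool["ellenberg_l"].between(1, 9).all()
    assert (pool["longevity"] > 0).all()


def test_forced_optima_are_pinned():
    cfg = small_config()
    pool = generate_species_pool(cfg, forced_optima={0: 42.0, 5: -3.0})
    assert pool.loc[0, "t_opt"] == 42.0
    assert pool.loc[5, "t_opt"] == -3.0


def test_fine_grid_is_nested(small_system, small_cfg):
    landscape, _, _ = small_system
    f = small_cfg.fine_subgrid
    fine = landscape.fine_temperature
    coarse = landscape.temperature_base
    assert fine.values.shape == (coarse.ny * f, coarse.nx * f)
    assert fine.cell_size * f == coarse.cell_size


def test_disturbance_flags_and_tbuf_present(small_system):
    _, surveys, _ = small_system
    for col in ("silvp", "disturb", "exot"):
        assert surveys[col].isin([0, 1]).all()
    assert surveys["tbuf"].dtype == float


def test_infrastructure_shapes(small_cfg):
    roads, population = generate_infrastructure(small_cfg)
    assert not roads.is_empty
    assert population.values.shape == (small_cfg.grid_ny, small_cfg.grid_nx)
    assert (population.values > 0).all()


def test_surveys_csv_round_trip(small_system, tmp_path):
    _, surveys, _ = small_system
    p = tmp_path / "surveys.csv"
    write_surveys_csv(surveys, p)
    back = read_surveys_csv(p)
    assert len(back) == len(surveys)
    assert list(back["species"].iloc[0]) == list(surveys["species"].iloc[0])
    assert np.array_equal(back["year"].to_numpy(), surveys["year"].to_numpy())
    assert np.allclose(back["x"].to_numpy(), surveys["x"].to_numpy())
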