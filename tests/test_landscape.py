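"""Habitat and human-pressure covariates: identities and geometry."""

import numpy as np
import pytest
from shapely.geometry import LineString, MultiLineString

from climdebt import landscape as lm
from climdebt.grids import Raster


def habitat_from(cells, cell_size=1000.0, period="baseline"):
    return lm.HabitatGrid(
        raster=Raster(np.asarray(cells, float), x0=0.0, y0=0.0, cell_size=cell_size),
        period=period,
    )


# -- aggregation index -----------------------------------------------------

def test_solid_block_is_maximally_aggregated():
    grid = np.zeros((5, 5), bool)
    grid[1:4, 1:4] = True
    assert lm.aggregation_index(grid) == pytest.approx(1.0)


def test_checkerboard_is_fully_disaggregated():
    grid = np.indices((6, 6)).sum(axis=0) % 2 == 0
    assert lm.aggregation_index(grid) == pytest.approx(0.0)


def test_single_cell_has_zero_aggregation():
    grid = np.zeros((3, 3), bool)
    grid[1, 1] = True
    assert lm.aggregation_index(grid) == 0.0


def test_empty_window_raises():
    with pytest.raises(ValueError):
        lm.aggregation_index(np.zeros((3, 3), bool))


@pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (3, 2), (4, 4), (5, 5),
                                        (6, 7), (9, 12), (12, 17)])
def test_max_shared_edges_closed_form(n, expected):
    assert lm._max_shared_edges(n) == expected


def test_aggregation_index_bounded(rng):
    for _ in range(25):
        grid = rng.random((8, 8)) < rng.uniform(0.1, 0.9)
        if not grid.any():
            continue
        ai = lm.aggregation_index(grid)
        assert 0.0 <= ai <= 1.0


# -- potential habitat and proximity ---------------------------------------

def make_temperature(ny=10, nx=10):
    vals = np.linspace(5.0, 15.0, ny)[:, None] * np.ones((1, nx))
    return Raster(vals, x0=0.0, y0=0.0, cell_size=1000.0)


def test_potential_habitat_intersects_forest_and_thermal_band():
    t = make_temperature()
    forest = Raster(np.ones((10, 10)), cell_size=1000.0)
    hab = lm.potential_habitat(8.0, 12.0, t, forest)
    assert hab.cells.any()
    assert np.all((t.values[hab.cells] >= 8.0) & (t.values[hab.cells] <= 12.0))
    forest2 = Raster(np.zeros((10, 10)), cell_size=1000.0)
    with pytest.raises(ValueError):
        lm.potential_habitat(8.0, 12.0, t, forest2)
    with pytest.raises(ValueError):
        lm.potential_habitat(12.0, 8.0, t, forest)


def test_habitat_proximity_inside_and_outside():
    cells = np.zeros((10, 10))
    cells[0, 0] = 1.0
    hab = habitat_from(cells)
    inside = lm.habitat_proximity(500.0, 500.0, hab)
    assert inside == pytest.approx(1.0 / 1000.0)  # maximal: 1 / cell_size
    away = lm.habitat_proximity(500.0 + 3000.0, 500.0, hab)
    assert away == pytest.approx(1.0 / (3000.0 + 1000.0))
    assert away < inside


def test_habitat_aggregation_change_sign_and_nan():
    past = np.zeros((9, 9))
    past[3:6, 3:6] = 1.0          # solid block: AI = 1
    current = np.zeros((9, 9))
    current[::2, ::2] = 1.0       # scattered: AI = 0
    dha = lm.habitat_aggregation_change(
        habitat_from(past), habitat_from(current), 4500.0, 4500.0, radius=20_000.0
    )
    assert dha == pytest.approx(-1.0)
    empty = np.zeros((9, 9))
    nan = lm.habitat_aggregation_change(
        habitat_from(past), habitat_from(empty), 4500.0, 4500.0, radius=20_000.0
    )
    assert np.isnan(nan)


def test_clip_to_radius_uses_cell_centres():
    cells = np.ones((5, 5))
    hab = habitat_from(cells)
    clipped = lm.clip_to_radius(hab, 2500.0, 2500.0, radius=1100.0)
    assert clipped.sum() == 5  # centre cell + 4 rook neighbours


# -- heterogeneity ---------------------------------------------------------

def test_temperature_heterogeneity_sd_of_fine_block():
    coarse = Raster(np.zeros((2, 2)), cell_size=1000.0)
    fine_vals = np.zeros((4, 4))
    fine_vals[:2, :2] = [[1.0, 2.0], [3.0, 4.0]]
    fine = Raster(fine_vals, cell_size=500.0)
    got = lm.temperature_heterogeneity(500.0, 500.0, coarse, fine)
    assert got == pytest.approx(np.std([1.0, 2.0, 3.0, 4.0], ddof=1))
    rng_stat = lm.temperature_heterogeneity(500.0, 500.0, coarse, fine, statistic="range")
    assert rng_stat == pytest.approx(3.0)
    with pytest.raises(ValueError):
        lm.temperature_heterogeneity(500.0, 500.0, coarse, fine, statistic="iqr")


def test_heterogeneity_requires_nested_grids():
    coarse = Raster(np.zeros((2, 2)), cell_size=1000.0)
    fine = Raster(np.zeros((3, 3)), cell_size=700.0)
    with pytest.raises(ValueError):
        lm.temperature_heterogeneity(500.0, 500.0, coarse, fine)


# -- human pressure --------------------------------------------------------

def test_distance_to_network():
    roads = MultiLineString([LineString([(0, 0), (10_000, 0)])])
    assert lm.distance_to_network(5_000.0, 3_000.0, roads) == pytest.approx(3_000.0)
    assert lm.distance_to_network(5_000.0, 0.0, roads) == 0.0


def test_population_within_radius_sums_disc():
    density = Raster(np.ones((10, 10)), cell_size=1000.0)
    total = lm.population_within_radius(4500.0, 4500.0, density, radius=1100.0)
    assert total == pytest.approx(5.0)  # centre + 4 rook-neighbour centres
    with pytest.raises(ValueError):
        lm.population_within_radius(5000.0, 5000.0, density, radius=10.0)


def test_extract_change_is_year_minus_baseline():
    grids = {
        2000: Raster(np.full((2, 2), 10.0), cell_size=1000.0),
        2001: Raster(np.full((2, 2), 11.0), cell_size=1000.0),
        2002: Raster(np.full((2, 2), 12.5), cell_size=1000.0),
    }
    change = lm.extract_change(500.0, 500.0, 2002, grids, [2000, 2001])
    assert change == pytest.approx(12.5 - 10.5)
    with pytest.raises(KeyError):
        lm.extract_change(500.0, 500.0, 1999, grids, [2000, 2001])
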