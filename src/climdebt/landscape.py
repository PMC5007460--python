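"""Habitat, climate-context and human-pressure covariates on grids and lines.

Everything operates in projected metres.  The per-survey covariates produced
here are: baseline climate (T, P), climate change since baseline (TC, PC),
within-cell temperature heterogeneity (THET), past-habitat proximity (HP),
temporal change in habitat aggregation (dHA), road proximity, and summed
human population density within 10 km (HPD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import Raster

__all__ = [
    "HabitatGrid",
    "extract_baseline",
    "extract_change",
    "temperature_heterogeneity",
    "potential_habitat",
    "habitat_proximity",
    "aggregation_index",
    "clip_to_radius",
    "habitat_aggregation_change",
    "distance_to_network",
    "population_within_radius",
]


@dataclass
class HabitatGrid:
    """Binary potential-habitat grid of one species for one period."""

    raster: Raster
    period: str
    species_id: int | None = None

    @property
    def cells(self) -> np.ndarray:
        return self.raster.values > 0.5


def extract_baseline(
    x: float, y: float, rasters_by_year: dict[int, Raster], years: list[int]
) -> float:
    """Multi-year mean of the baseline grids at the survey's cell."""
    vals = [rasters_by_year[yr].value_at(x, y) for yr in years]
    return float(np.mean(vals))


def extract_change(
    x: float,
    y: float,
    year: int,
    rasters_by_year: dict[int, Raster],
    baseline_years: list[int],
) -> float:
    """Survey-year value minus the baseline multi-year mean at the cell."""
    if year not in rasters_by_year:
        raise KeyError(f"no grid for year {year}")
    base = extract_baseline(x, y, rasters_by_year, baseline_years)
    return float(rasters_by_year[year].value_at(x, y)) - base


def temperature_heterogeneity(
    x: float, y: float, coarse: Raster, fine: Raster, statistic: str = "sd"
) -> float:
    """Dispersion of fine-grid temperatures inside the survey's coarse cell.

    The default statistic is the sample standard deviation; ``"range"`` is
    available as an alternative.
    """
    iy, ix = coarse.cell_of(x, y)
    ratio = coarse.cell_size / fine.cell_size
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError("fine raster is not nested in the coarse grid")
    block = fine.values[iy * f : (iy + 1) * f, ix * f : (ix + 1) * f]
    if block.size < 2:
        raise ValueError("fewer than 2 fine cells in the unit")
    if statistic == "sd":
        return float(np.std(block, ddof=1))
    if statistic == "range":
        return float(np.ptp(block))
    raise ValueError(f"unknown statistic {statistic!r}")


def potential_habitat(
    lower: float, upper: float, period_mean_temperature: Raster, forest_mask: Raster,
    period: str = "", species_id: int | None = None,
) -> HabitatGrid:
    """Habitat = forest cells whose period-mean temperature lies in the
    species' thermal tolerance interval [lower, upper]."""
    if not (np.isfinite(lower) and np.isfinite(upper)) or lower > upper:
        raise ValueError("invalid thermal limits")
    forest = forest_mask.values > 0.5
    if not forest.any():
        raise ValueError("empty forest mask")
    t = period_mean_temperature.values
    habitat = forest & (t >= lower) & (t <= upper)
    return HabitatGrid(
        raster=forest_mask.copy_with(habitat.astype(float)),
        period=period,
        species_id=species_id,
    )


def habitat_proximity(x: float, y: float, past: HabitatGrid) -> float:
    """Inverse distance HP = 1 / (d + cell_size) to the nearest past-habitat
    cell centre; the cell-size offset keeps HP finite and strictly monotone,
    with HP maximal (1/cell_size) for points inside past habitat."""
    cells = past.cells
    if not cells.any():
        raise ValueError("species has no past habitat")
    r = past.raster
    iy, ix = r.cell_of(x, y)
    if cells[iy, ix]:
        d = 0.0
    else:
        X, Y = r.cell_centers()
        tree = cKDTree(np.column_stack([X[cells], Y[cells]]))
        d, _ = tree.query([x, y])
    return 1.0 / (d + r.cell_size)


def _shared_edge_count(cells: np.ndarray) -> int:
    """Number of rook-adjacent habitat cell pairs."""
    return int(
        np.logical_and(cells[:, :-1], cells[:, 1:]).sum()
        + np.logical_and(cells[:-1, :], cells[1:, :]).sum()
    )


def _max_shared_edges(n: int) -> int:
    """Maximum rook-shared edges for n cells (largest-square packing)."""
    if n <= 1:
        return 0
    l = int(np.floor(np.sqrt(n)))
    m = n - l * l
    e = 2 * l * (l - 1)
    if m == 0:
        return e
    if m <= l:
        return e + 2 * m - 1
    return e + 2 * m - 2


def aggregation_index(cells: np.ndarray) -> float:
    """Aggregation index AI = e / e_max in [0, 1] of a binary pattern.

    ``e`` counts rook-adjacent habitat pairs; ``e_max`` is the largest count
    achievable with the same number of cells.  A single cell (e_max = 0) is
    assigned AI = 0 by convention.
    """
    cells = np.asarray(cells, dtype=bool)
    n = int(cells.sum())
    if n == 0:
        raise ValueError("no habitat cells in the window")
    emax = _max_shared_edges(n)
    if emax == 0:
        return 0.0
    return _shared_edge_count(cells) / emax


def clip_to_radius(grid: HabitatGrid, x: float, y: float, radius: float) -> np.ndarray:
    """Habitat cells whose centres lie within ``radius`` of (x, y)."""
    r = grid.raster
    X, Y = r.cell_centers()
    disc = (X - x) ** 2 + (Y - y) ** 2 <= radius**2
    return grid.cells & disc


def habitat_aggregation_change(
    past: HabitatGrid, current: HabitatGrid, x: float, y: float, radius: float = 10_000.0
) -> float:
    """dHA = AI(current) - AI(past) within a disc around the survey.

    Negative values mean the species' habitat disaggregated.  If either
    period has no habitat in the window the change is undefined (NaN).
    """
    past_cells = clip_to_radius(past, x, y, radius)
    cur_cells = clip_to_radius(current, x, y, radius)
    if not past_cells.any() or not cur_cells.any():
        return float("nan")
    return aggregation_index(cur_cells) - aggregation_index(past_cells)


def distance_to_network(x: float, y: float, network: BaseGeometry) -> float:
    """Euclidean distance from the survey to the nearest line of the network."""
    if network.is_empty:
        raise ValueError("empty road network")
    return float(network.distance(Point(x, y)))


def population_within_radius(
    x: float, y: float, density: Raster, radius: float = 10_000.0
) -> float:
    """Sum of population-density cells whose centres fall inside the disc."""
    X, Y = density.cell_centers()
    disc = (X - x) ** 2 + (Y - y) ** 2 <= radius**2
    if not disc.any():
        raise ValueError("no density cells within the radius")
    vals = density.values[disc]
    if not np.all(np.isfinite(vals)):
        raise ValueError("nodata density cells inside the radius")
    return float(vals.sum())
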