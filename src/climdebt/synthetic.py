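"""Synthetic study system: landscape, species pool and floristic surveys.

The generator plants a *known* climatic debt.  Each species has a unimodal
(Gaussian) niche along temperature, precipitation and two soil gradients.
Communities are Bernoulli samples of the pool evaluated not at the current
climate but at an *effective* temperature

    T_eff = T_baseline + (1 - lambda) * dT_planted(cell, year)

so a lag fraction ``lambda`` of the local warming is not yet expressed in
composition; the planted per-survey debt is exactly ``lambda * dT_planted``.
All randomness flows from ``config.seed`` through a splittable SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import SimulationConfig
from .grids import Raster, write_ascii_grid

__all__ = [
    "Landscape",
    "TrueState",
    "generate_landscape",
    "generate_species_pool",
    "assemble_communities",
    "simulate",
    "write_surveys_csv",
    "read_surveys_csv",
]


@dataclass
class Landscape:
    """Gridded environment for both periods."""

    temperature: dict[int, Raster]          # annual grids, all years
    precipitation: dict[int, Raster]
    temperature_base: Raster                # smooth baseline field (no noise)
    precipitation_base: Raster
    fine_temperature: Raster                # sub-grid field for heterogeneity
    ph: Raster
    cn: Raster
    forest_baseline: Raster                 # binary masks (1 = forest)
    forest_study: Raster
    config: SimulationConfig

    def period_mean(self, variable: str, period: str) -> Raster:
        years = self.config.years_in(period)
        grids = self.temperature if variable == "temperature" else self.precipitation
        stack = np.stack([grids[y].values for y in years])
        return grids[years[0]].copy_with(stack.mean(axis=0))


@dataclass
class TrueState:
    """Ground truth recorded by the generator for recovery checks."""

    true_debt: pd.Series            # degC, indexed by survey id
    lag: pd.Series                  # lambda evaluated per survey
    delta_t: pd.Series              # planted warming at the survey cell/year
    pool: pd.DataFrame              # species optima/breadths/traits
    planted_effects: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, ny: int, nx: int, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd smoothed Gaussian random field."""
    f = gaussian_filter(rng.standard_normal((ny, nx)), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def generate_landscape(config: SimulationConfig, rng: np.random.Generator | None = None) -> Landscape:
    """Build annual climate grids, static soil grids and forest masks.

    Study-period temperature grids carry a monotone warming trend that reaches
    ``config.warming_total`` in the last study year; precipitation has no
    trend.  Annual grids add iid cell noise on top of the smooth base fields.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ny, nx = config.grid_ny, config.grid_nx
    if ny < 2 or nx < 2:
        raise ValueError("grid dimensions must be >= 2")
    geo = dict(x0=0.0, y0=0.0, cell_size=config.cell_size, crs=config.crs)

    lat = np.linspace(-0.5, 0.5, ny)[:, None] * np.ones((1, nx))
    relief = _smooth_field(rng, ny, nx, sigma=4.0)
    t_base = (
        config.temperature_mean
        - config.temperature_gradient * lat
        + config.temperature_relief_sd * relief
    )
    p_relief = _smooth_field(rng, ny, nx, sigma=4.0)
    p_base = (
        config.precipitation_mean
        + config.precipitation_gradient * lat
        + config.precipitation_relief_sd * p_relief
    )
    p_base = np.maximum(p_base, 50.0)

    temperature: dict[int, Raster] = {}
    precipitation: dict[int, Raster] = {}
    for year in config.all_years:
        trend = config.warming_at(year)
        t = t_base + trend + rng.normal(0.0, config.annual_noise_sd, (ny, nx))
        p = np.maximum(p_base + rng.normal(0.0, config.precip_noise_sd, (ny, nx)), 0.0)
        temperature[year] = Raster(t, **geo)
        precipitation[year] = Raster(p, **geo)

    # fine sub-grid: baseline temperature + micro-relief, for heterogeneity
    f = config.fine_subgrid
    fine = np.kron(t_base, np.ones((f, f)))
    fine += 0.6 * _smooth_field(rng, ny * f, nx * f, sigma=1.5)
    fine_raster = Raster(fine, x0=0.0, y0=0.0, cell_size=config.cell_size / f, crs=config.crs)

    ph_lo, ph_hi = config.ph_range
    ph = ph_lo + (ph_hi - ph_lo) * _sigmoid(_smooth_field(rng, ny, nx, sigma=5.0))
    cn_lo, cn_hi = config.cn_range
    cn = cn_lo + (cn_hi - cn_lo) * _sigmoid(_smooth_field(rng, ny, nx, sigma=5.0))

    forest_field = _smooth_field(rng, ny, nx, sigma=config.forest_fragmentation)
    thr = np.quantile(forest_field, 1.0 - config.forest_cover)
    forest_base = (forest_field >= thr).astype(float)
    # lose a fraction of baseline forest cells by the study period
    idx = np.flatnonzero(forest_base.ravel() > 0)
    n_lost = int(round(config.forest_loss_study * idx.size))
    lost = rng.choice(idx, size=n_lost, replace=False) if n_lost else np.empty(0, int)
    forest_study = forest_base.copy().ravel()
    forest_study[lost] = 0.0
    forest_study = forest_study.reshape(ny, nx)

    return Landscape(
        temperature=temperature,
        precipitation=precipitation,
        temperature_base=Raster(t_base, **geo),
        precipitation_base=Raster(p_base, **geo),
        fine_temperature=fine_raster,
        ph=Raster(ph, **geo),
        cn=Raster(cn, **geo),
        forest_baseline=Raster(forest_base, **geo),
        forest_study=Raster(forest_study, **geo),
        config=config,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-1.5 * z))


def generate_species_pool(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    landscape: Landscape | None = None,
    forced_optima: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Draw a species pool with Gaussian niches and life-history traits.

    Thermal optima are spread uniformly over the landscape's baseline
    temperature range (or a default range if no landscape is given); breadths
    are normal, truncated away from zero.  ``forced_optima`` pins the thermal
    optimum of selected species (used by tests).
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    k = config.n_species
    if landscape is not None:
        tvals = landscape.temperature_base.values
        t_lo, t_hi = tvals.min(), tvals.max()
        pvals = landscape.precipitation_base.values
        p_lo, p_hi = pvals.min(), pvals.max()
    else:
        half = config.temperature_gradient / 2
        t_lo, t_hi = config.temperature_mean - half, config.temperature_mean + half
        p_lo = config.precipitation_mean - config.precipitation_gradient / 2
        p_hi = config.precipitation_mean + config.precipitation_gradient / 2
    t_lo -= config.niche_optimum_margin
    t_hi += config.niche_optimum_margin

    t_opt = rng.uniform(t_lo, t_hi, k)
    t_breadth = np.clip(
        rng.normal(config.niche_breadth_mean, config.niche_breadth_sd, k),
        0.25 * config.niche_breadth_mean,
        None,
    )
    if np.any(t_breadth <= 0):
        raise ValueError("degenerate niche breadth <= 0")
    p_opt = rng.uniform(p_lo, p_hi, k)
    p_breadth = np.clip(
        rng.normal(config.precip_breadth_mean, config.precip_breadth_sd, k),
        0.25 * config.precip_breadth_mean,
        None,
    )
    ph_opt = rng.uniform(*config.ph_range, k)
    cn_opt = rng.uniform(*config.cn_range, k)
    prevalence = rng.uniform(*config.prevalence_range, k)
    # longevity in years, log-normal, cool-adapted species slightly longer lived
    longevity = np.exp(rng.normal(np.log(12.0), 0.7, k))
    # Ellenberg L: ordinal 1..9 light requirement
    ellenberg_l = rng.integers(1, 10, k).astype(float)

    pool = pd.DataFrame(
        {
            "species_id": np.arange(k),
            "t_opt": t_opt,
            "t_breadth": t_breadth,
            "p_opt": p_opt,
            "p_breadth": p_breadth,
            "ph_opt": ph_opt,
            "ph_breadth": config.ph_breadth,
            "cn_opt": cn_opt,
            "cn_breadth": config.cn_breadth,
            "prevalence": prevalence,
            "longevity": longevity,
            "ellenberg_l": ellenberg_l,
        }
    ).set_index("species_id", drop=False)
    if forced_optima:
        for sid, opt in forced_optima.items():
            pool.loc[sid, "t_opt"] = opt
    return pool


def _gauss(x: np.ndarray, opt: np.ndarray, breadth: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((x - opt) / breadth) ** 2)


def _place_surveys(
    landscape: Landscape, n: int, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-cluster placement restricted to forest cells."""
    cfg = landscape.config
    xmin, ymin, xmax, ymax = landscape.temperature_base.extent
    parents = np.column_stack(
        [rng.uniform(xmin, xmax, cfg.n_cluster_parents), rng.uniform(ymin, ymax, cfg.n_cluster_parents)]
    )
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place surveys on forest cells")
        p = parents[rng.integers(0, len(parents))]
        x = p[0] + rng.normal(0.0, cfg.cluster_sd)
        y = p[1] + rng.normal(0.0, cfg.cluster_sd)
        if not (xmin <= x < xmax and ymin <= y < ymax):
            continue
        iy = int((y - ymin) // cfg.cell_size)
        ix = int((x - xmin) // cfg.cell_size)
        if mask[iy, ix] < 0.5:
            continue
        xs[placed], ys[placed] = x, y
        placed += 1
    return xs, ys


def assemble_communities(
    landscape: Landscape,
    pool: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TrueState]:
    """Sample floristic surveys for both periods and record the ground truth.

    Occupancy of species *k* at a survey is Bernoulli with probability
    ``prevalence_k * suitability_k(T_eff, P, pH, C:N)``.  Surveys with fewer
    than ``config.min_richness`` species are redrawn (mirroring the downstream
    calibration filter); the planted debt ``lambda * dT`` is stored exactly.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    rows = []
    debts, lags, deltas = [], [], []
    sid = 0
    for period in ("baseline", "study"):
        mask = (landscape.forest_baseline if period == "baseline" else landscape.forest_study).values
        counts = config.surveys_per_year(period)
        n_period = sum(counts.values())
        xs, ys = _place_surveys(landscape, n_period, mask, rng)
        years = np.repeat(list(counts.keys()), list(counts.values()))
        iy, ix = landscape.temperature_base.cell_of(xs, ys)
        t_base = landscape.temperature_base.values[iy, ix]
        p_here = landscape.precipitation_base.values[iy, ix]
        ph_here = landscape.ph.values[iy, ix]
        cn_here = landscape.cn.values[iy, ix]
        delta = np.array([config.warming_at(int(y)) for y in years])
        if callable(config.lag_lambda):
            lam = np.asarray(config.lag_lambda(t_base), dtype=float)
        else:
            lam = np.full(n_period, float(config.lag_lambda))
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("lag_lambda must evaluate inside [0, 1]")
        t_eff = t_base + (1.0 - lam) * delta

        suit = (
            pool["prevalence"].to_numpy()[None, :]
            * _gauss(t_eff[:, None], pool["t_opt"].to_numpy()[None, :], pool["t_breadth"].to_numpy()[None, :])
            * _gauss(p_here[:, None], pool["p_opt"].to_numpy()[None, :], pool["p_breadth"].to_numpy()[None, :])
            * _gauss(ph_here[:, None], pool["ph_opt"].to_numpy()[None, :], pool["ph_breadth"].to_numpy()[None, :])
            * _gauss(cn_here[:, None], pool["cn_opt"].to_numpy()[None, :], pool["cn_breadth"].to_numpy()[None, :])
        )
        species_ids = pool["species_id"].to_numpy()
        for i in range(n_period):
            occ = rng.random(len(species_ids)) < suit[i]
            tries = 0
            while occ.sum() < config.min_richness:
                tries += 1
                if tries > config.max_resample:
                    raise RuntimeError(
                        f"survey at ({xs[i]:.0f}, {ys[i]:.0f}) stayed below "
                        f"{config.min_richness} species after {config.max_resample} redraws"
                    )
                occ = rng.random(len(species_ids)) < suit[i]
            flags = {
                name: int(rng.random() < prob)
                for name, prob in config.disturbance_prevalence.items()
            }
            # canopy temperature buffering, supplied as a pass-through covariate
            flags["tbuf"] = float(rng.normal(-1.0, 0.5))
            rows.append(
                {
                    "survey_id": sid,
                    "x": xs[i],
                    "y": ys[i],
                    "year": int(years[i]),
                    "period": period,
                    "species": list(species_ids[occ]),
                    "richness": int(occ.sum()),
                    **flags,
                }
            )
            debts.append(lam[i] * delta[i])
            lags.append(lam[i])
            deltas.append(delta[i])
            sid += 1

    surveys = pd.DataFrame(rows).set_index("survey_id", drop=False)
    truth = TrueState(
        true_debt=pd.Series(debts, index=surveys.index, name="true_debt"),
        lag=pd.Series(lags, index=surveys.index, name="lag"),
        delta_t=pd.Series(deltas, index=surveys.index, name="delta_t"),
        pool=pool,
    )
    return surveys, truth


def simulate(config: SimulationConfig) -> tuple[Landscape, pd.DataFrame, TrueState]:
    """Full generation pass: landscape, pool, communities, from one seed."""
    seq = np.random.SeedSequence(config.seed).spawn(3)
    landscape = generate_landscape(config, np.random.default_rng(seq[0]))
    pool = generate_species_pool(config, np.random.default_rng(seq[1]), landscape)
    surveys, truth = assemble_communities(
        landscape, pool, config, np.random.default_rng(seq[2])
    )
    return landscape, surveys, truth


def generate_infrastructure(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Synthetic human footprint: a sparse road network and a population grid.

    Roads are random polylines crossing the territory; population density is
    a patchy log-normal field.  Both are consumed as supplied covariate
    layers (road proximity, summed density within 10 km) — no mechanistic
    link to the vegetation is simulated.
    """
    from shapely.geometry import LineString, MultiLineString

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    nx, ny = config.grid_nx, config.grid_ny
    w = nx * config.cell_size
    h = ny * config.cell_size
    lines = []
    for _ in range(6):
        pts = np.column_stack(
            [rng.uniform(0, w, 4), rng.uniform(0, h, 4)]
        )
        lines.append(LineString(pts[np.argsort(pts[:, 0])]))
    roads = MultiLineString(lines)
    density = np.exp(rng.normal(2.0, 1.0, (ny, nx))) * (
        1.0 + 3.0 * _sigmoid(_smooth_field(rng, ny, nx, sigma=6.0))
    )
    population = Raster(
        density, x0=0.0, y0=0.0, cell_size=config.cell_size, crs=config.crs
    )
    return roads, population


# -- plain-text I/O -------------------------------------------------------

def write_surveys_csv(surveys: pd.DataFrame, path: str | Path) -> None:
    out = surveys.copy()
    out["species"] = out["species"].map(lambda ids: ";".join(str(i) for i in ids))
    out.to_csv(path, index=False)


def read_surveys_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["species"] = df["species"].map(
        lambda s: [int(t) for t in str(s).split(";")] if str(s) else []
    )
    return df.set_index("survey_id", drop=False)


def write_landscape(landscape: Landscape, out_dir: str | Path) -> list[Path]:
    """Dump all grids as ASCII-grid text files; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, raster in [
        ("temperature_base", landscape.temperature_base),
        ("precipitation_base", landscape.precipitation_base),
        ("fine_temperature", landscape.fine_temperature),
        ("ph", landscape.ph),
        ("cn", landscape.cn),
        ("forest_baseline", landscape.forest_baseline),
        ("forest_study", landscape.forest_study),
    ]:
        p = out_dir / f"{name}.asc"
        write_ascii_grid(raster, p)
        written.append(p)
    for year, raster in landscape.temperature.items():
        p = out_dir / f"temperature_{year}.asc"
        write_ascii_grid(raster, p)
        written.append(p)
    for year, raster in landscape.precipitation.items():
        p = out_dir / f"precipitation_{year}.asc"
        write_ascii_grid(raster, p)
        written.append(p)
    return written
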