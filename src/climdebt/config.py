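"""Run configuration for the synthetic study system and the inference pipeline.

The synthetic generator emulates a temperate forest territory observed over two
climate periods: a stable baseline (default 1965-1986) during which vegetation
and climate are assumed at equilibrium, and a warmed study period (default
1987-2008, mean warming +1.07 degC) during which communities may lag behind the
temperature they experience.  The lag fraction ``lag_lambda`` plants a known
climatic debt that downstream stages must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import yaml

__all__ = ["SimulationConfig", "PlsConfig"]


@dataclass
class SimulationConfig:
    # landscape geometry
    grid_nx: int = 80
    grid_ny: int = 80
    cell_size: float = 1000.0  # m
    crs: str = "synthetic-metric"

    # climate fields
    temperature_mean: float = 11.0      # degC, landscape average
    temperature_gradient: float = 7.0   # degC spanned south->north
    temperature_relief_sd: float = 0.8  # degC, smooth topographic field
    precipitation_mean: float = 900.0   # mm
    precipitation_gradient: float = 450.0
    precipitation_relief_sd: float = 80.0
    annual_noise_sd: float = 0.25       # degC, iid per cell and year
    precip_noise_sd: float = 50.0       # mm
    fine_subgrid: int = 4               # fine cells per 1-km cell side (THET)

    # soil fields (static)
    ph_range: tuple[float, float] = (4.0, 7.5)
    cn_range: tuple[float, float] = (12.0, 30.0)

    # periods and warming
    baseline_years: tuple[int, int] = (1965, 1986)
    study_years: tuple[int, int] = (1987, 2008)
    warming_total: float = 1.07         # degC reached in the last study year
    warming_profile: str = "linear"     # "linear" ramp or "step"

    # forest mask
    forest_cover: float = 0.6           # fraction of cells forested
    forest_fragmentation: float = 3.0   # smoothing sigma (cells); lower = more fragmented
    forest_loss_study: float = 0.05     # fraction of baseline forest lost by the study period

    # species pool
    n_species: int = 350
    # species pools extend beyond the realized climate of any one territory:
    # thermal optima are drawn this far (degC) beyond the landscape range
    niche_optimum_margin: float = 2.5
    niche_breadth_mean: float = 1.8     # degC
    niche_breadth_sd: float = 0.45
    precip_breadth_mean: float = 260.0  # mm
    precip_breadth_sd: float = 60.0
    ph_breadth: float = 1.3
    cn_breadth: float = 9.0
    prevalence_range: tuple[float, float] = (0.15, 0.6)

    # surveys
    n_surveys_baseline: int = 600
    n_surveys_study: int = 1200
    year_allocation: str = "geometric"  # "geometric" (uneven) or "uniform"
    geometric_q: float = 0.93
    n_cluster_parents: int = 25
    cluster_sd: float = 6000.0          # m, spread of surveys around cluster parents
    min_richness: int = 5
    max_resample: int = 30
    disturbance_prevalence: dict = field(
        default_factory=lambda: {"silvp": 0.25, "disturb": 0.15, "exot": 0.05}
    )

    # planted community lag: fraction of local warming NOT yet reflected in
    # composition; a float, or a callable(baseline_T_array) -> array in [0, 1]
    lag_lambda: float | Callable = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.warming_total < 0:
            raise ValueError("warming_total must be >= 0")
        if isinstance(self.lag_lambda, (int, float)) and not 0 <= self.lag_lambda <= 1:
            raise ValueError("lag_lambda must lie in [0, 1]")
        if self.warming_profile not in ("linear", "step"):
            raise ValueError("warming_profile must be 'linear' or 'step'")

    @property
    def all_years(self) -> list[int]:
        return list(range(self.baseline_years[0], self.study_years[1] + 1))

    def years_in(self, period: str) -> list[int]:
        lo, hi = self.baseline_years if period == "baseline" else self.study_years
        return list(range(lo, hi + 1))

    def warming_at(self, year: int) -> float:
        """Planted warming (degC over baseline) applied in a study year."""
        y0, y1 = self.study_years
        if year < y0:
            return 0.0
        if self.warming_profile == "step":
            return self.warming_total
        return self.warming_total * (year - y0 + 1) / (y1 - y0 + 1)

    def surveys_per_year(self, period: str, total: int | None = None) -> dict[int, int]:
        """Deliberately uneven (geometric) or uniform yearly survey counts."""
        years = self.years_in(period)
        if total is None:
            total = self.n_surveys_baseline if period == "baseline" else self.n_surveys_study
        if self.year_allocation == "uniform":
            base = total // len(years)
            counts = {y: base for y in years}
        else:
            q = self.geometric_q
            wts = [q ** i for i in range(len(years))]
            s = sum(wts)
            counts = {y: int(round(total * w / s)) for y, w in zip(years, wts)}
        # fix rounding drift, keep >= 1 per year
        for y in years:
            counts[y] = max(counts[y], 1)
        drift = total - sum(counts.values())
        counts[years[0]] += drift
        if counts[years[0]] < 1:
            raise ValueError("too few surveys for the number of years")
        return counts

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if callable(d["lag_lambda"]):
            d["lag_lambda"] = f"<callable {getattr(self.lag_lambda, '__name__', 'lambda')}>"
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("baseline_years", "study_years", "ph_range", "cn_range", "prevalence_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PlsConfig:
    """Settings of the bootstrapped weighted-PLS inference stage."""

    n_draws: int = 5000
    min_dist: float = 10_000.0  # m, spatial thinning distance
    alpha_components: float = 0.05  # Bonferroni-divided across tested components
    alpha_sign: float = 0.01        # bootstrap sign-test threshold
    max_components: int | None = None  # default: number of predictors
    late_period_start: int = 1993      # PLS1-4 survey filter
    seed: int = 0
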