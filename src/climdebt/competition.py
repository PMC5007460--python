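"""Resource-competition proxies from pairwise niche differentiation.

Niche differentiation between two species along a resource gradient
(annual precipitation for water, soil C:N for nitrogen) is 1 - D, the
complement of Schoener's overlap between their occupancy histograms.  A
community's competition index (C_W or C_N) is the mean pairwise
differentiation among its co-occurring species: values near 1 indicate
strong resource partitioning, consistent with competitive structuring.

A randomization test checks whether an observed community index could arise
from random assembly out of the regional species pool (species found within
10 km): random same-richness assemblages are drawn uniformly without
replacement and the observed index is ranked against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .niche import OccupancyDistribution, schoener_d

__all__ = [
    "DifferentiationMatrix",
    "NullModelResult",
    "pairwise_differentiation",
    "community_competition",
    "null_model_test",
    "regional_pool",
]


@dataclass
class DifferentiationMatrix:
    """Symmetric species x species matrix of 1 - D with zero diagonal."""

    values: np.ndarray
    species_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.species_ids):
            raise ValueError("matrix/id shape mismatch")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.species_ids)}

    def positions(self, species_list) -> np.ndarray:
        return np.array([self._index[s] for s in species_list if s in self._index])


def pairwise_differentiation(
    distributions: dict[int, OccupancyDistribution]
) -> DifferentiationMatrix:
    """1 - D for every species pair; all distributions must share bin edges."""
    ids = np.array(sorted(distributions))
    if any(distributions[s].n == 0 for s in ids):
        raise ValueError("species with empty distribution")
    freqs = np.stack([distributions[s].frequencies for s in ids])
    edges0 = distributions[ids[0]].edges
    for s in ids[1:]:
        if not np.allclose(distributions[s].edges, edges0):
            raise ValueError("distributions must share bin edges")
    # D matrix via pairwise L1 distances
    diff = 0.5 * np.abs(freqs[:, None, :] - freqs[None, :, :]).sum(axis=2)
    np.fill_diagonal(diff, 0.0)
    return DifferentiationMatrix(diff, ids)


def community_competition(species_list, matrix: DifferentiationMatrix) -> float:
    """Mean pairwise differentiation among a survey's co-occurring species."""
    pos = matrix.positions(species_list)
    if len(pos) < 2:
        raise ValueError("need >= 2 co-occurring species with distributions")
    sub = matrix.values[np.ix_(pos, pos)]
    iu = np.triu_indices(len(pos), k=1)
    return float(sub[iu].mean())


def regional_pool(surveys, x: float, y: float, radius: float = 10_000.0) -> list:
    """Union of species observed in surveys within ``radius`` of (x, y)."""
    d2 = (surveys["x"] - x) ** 2 + (surveys["y"] - y) ** 2
    nearby = surveys.loc[d2 <= radius**2, "species"]
    pool: set = set()
    for lst in nearby:
        pool.update(lst)
    return sorted(pool)


@dataclass
class NullModelResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    significant: bool
    n_draws: int
    null_values: np.ndarray | None = None


def null_model_test(
    species_list,
    pool,
    matrix: DifferentiationMatrix,
    n_draws: int = 2500,
    alpha: float = 0.05,
    seed: int = 0,
    keep_null: bool = False,
) -> NullModelResult:
    """Two-sided randomization test of a community's competition index.

    Draws ``n_draws`` random assemblages of the observed richness, uniformly
    without replacement from the regional pool, and ranks the observed index
    with the add-one convention p = (r + 1) / (n + 1), so p is never 0.
    """
    pool_pos = matrix.positions(pool)
    comm_pos = matrix.positions(species_list)
    k = len(comm_pos)
    if k < 2:
        raise ValueError("community must have >= 2 species in the matrix")
    if len(pool_pos) < k:
        raise ValueError("regional pool smaller than community richness")
    observed = community_competition(species_list, matrix)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(k, k=1)
    null = np.empty(n_draws)
    for d in range(n_draws):
        pick = rng.choice(pool_pos, size=k, replace=False)
        null[d] = matrix.values[np.ix_(pick, pick)][iu].mean()
    n_low = int(np.sum(null <= observed))
    n_high = int(np.sum(null >= observed))
    p = min(1.0, 2.0 * (min(n_low, n_high) + 1) / (n_draws + 1))
    return NullModelResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_draws > 1 else 0.0,
        p_value=p,
        significant=bool(p < alpha),
        n_draws=n_draws,
        null_values=null if keep_null else None,
    )
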