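"""Species-level climatic niches: tolerances, overlap, temporal conservatism.

A species' occupied climate in a period is summarized as a binned
relative-frequency histogram (:class:`OccupancyDistribution`).  Overlap
between two such histograms is Schoener's D = 1 - 0.5 * sum |p_b - q_b|,
bounded in [0, 1].

Two temporal indices compare a species' past thermal niche N_0 with what is
observed after warming, each as a ratio D_obs / D_ref in [0, 1]:

* distribution conservatism (DC): how much of its former *spatial*
  distribution the species kept, despite the climate having changed there
  (1 = full persistence in place, via tolerance/adaptation/plasticity);
* niche conservatism (NC): how closely the *occupied climate* tracks the
  former niche (1 = perfect climate tracking via migration).

Because occurrence counts and spatial coverage differ between periods, the
"observed" histograms are built by histogram-matched subsampling against a
reference shape, repeated and averaged, so that both size and shape of the
compared samples are equalized before computing overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OccupancyDistribution",
    "ConservatismResult",
    "climatic_tolerance",
    "schoener_d",
    "distribution_conservatism",
    "niche_conservatism",
    "community_mean",
    "shared_edges",
]

DEFAULT_BIN_TEMPERATURE = 0.5   # degC
DEFAULT_BIN_PRECIPITATION = 50  # mm


@dataclass
class OccupancyDistribution:
    """Binned relative-frequency histogram of occupied environmental values."""

    frequencies: np.ndarray
    edges: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.frequencies) != len(self.edges) - 1:
            raise ValueError("frequencies and edges are inconsistent")
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency")
        s = self.frequencies.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {s})")

    @classmethod
    def from_values(cls, values, edges) -> "OccupancyDistribution":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("empty occurrence set")
        counts, _ = np.histogram(values, bins=edges)
        if counts.sum() != values.size:
            raise ValueError("values fall outside the bin edges")
        return cls(counts / counts.sum(), np.asarray(edges, float), int(values.size))


def shared_edges(*value_sets, bin_width: float) -> np.ndarray:
    """Fixed-width bin edges spanning the pooled range of several value sets."""
    pooled = np.concatenate([np.asarray(v, float).ravel() for v in value_sets])
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def climatic_tolerance(values) -> float:
    """Niche breadth as the occupied range (max - min) of a climate variable."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty occurrence set")
    return float(values.max() - values.min())


def schoener_d(p: OccupancyDistribution, q: OccupancyDistribution) -> float:
    """Schoener's overlap D = 1 - 0.5 * sum |p_b - q_b|, in [0, 1]."""
    if len(p.edges) != len(q.edges) or not np.allclose(p.edges, q.edges):
        raise ValueError("distributions must share bin edges")
    return float(1.0 - 0.5 * np.abs(p.frequencies - q.frequencies).sum())


@dataclass
class ConservatismResult:
    d_ref: float
    d_obs: float
    index: float
    n_replicates: int
    defined: bool = True


def _matched_sample(
    source_values: np.ndarray,
    target: OccupancyDistribution,
    rng: np.random.Generator,
    strict: bool,
) -> np.ndarray | None:
    """Subsample ``source_values`` without replacement so its histogram matches
    the target's shape at the target's sample size.

    In strict mode, a target bin the source cannot populate makes the match
    impossible (None).  In best-effort mode each bin contributes what it has:
    the deficit then shows up as reduced overlap, which is the point — a
    species that no longer occupies part of the target niche should score a
    low D, not an error.
    """
    edges = target.edges
    bins = np.digitize(source_values, edges) - 1
    want = np.round(target.frequencies * target.n).astype(int)
    # keep total exactly at target n after rounding
    diff = target.n - want.sum()
    if diff != 0:
        order = np.argsort(-target.frequencies)
        for b in order[: abs(diff)]:
            want[b] += int(np.sign(diff))
    want = np.maximum(want, 0)
    out = []
    for b, k in enumerate(want):
        if k == 0:
            continue
        pool = source_values[bins == b]
        if pool.size == 0:
            if strict:
                return None
            continue
        if pool.size <= k:
            out.append(pool)
        else:
            out.append(rng.choice(pool, size=k, replace=False))
    if not out:
        return None if strict else np.empty(0)
    return np.concatenate(out)


def _matched_overlap(
    reference: OccupancyDistribution,
    source_values: np.ndarray,
    target: OccupancyDistribution,
    n_replicates: int,
    rng: np.random.Generator,
    strict: bool = False,
) -> tuple[float, bool]:
    """Mean D(reference, matched-sample histogram) over replicates."""
    ds = []
    for _ in range(n_replicates):
        sample = _matched_sample(source_values, target, rng, strict)
        if sample is None:
            return np.nan, False
        if sample.size == 0:
            ds.append(0.0)  # nothing of the target niche is occupied
            continue
        h = OccupancyDistribution.from_values(sample, reference.edges)
        ds.append(schoener_d(reference, h))
    return float(np.mean(ds)), True


def distribution_conservatism(
    baseline_climate_at_baseline_sites,
    study_climate_at_baseline_sites,
    study_climate_at_study_sites,
    bin_width: float = DEFAULT_BIN_TEMPERATURE,
    n_replicates: int = 100,
    seed: int = 0,
) -> ConservatismResult:
    """Distribution conservatism DC = D_obs / D_ref for one species.

    N_0 is the climate the species occupied in the baseline period; N_exp the
    *changed* climate at those same localities (the niche it would occupy had
    it not moved); N_obs is a matched sample of the climate at its actual
    study-period localities, matched against N_exp.  DC = 1 means the species
    held its ground despite the new climate.
    """
    rng = np.random.default_rng(seed)
    edges = shared_edges(
        baseline_climate_at_baseline_sites,
        study_climate_at_baseline_sites,
        study_climate_at_study_sites,
        bin_width=bin_width,
    )
    n0 = OccupancyDistribution.from_values(baseline_climate_at_baseline_sites, edges)
    n_exp = OccupancyDistribution.from_values(study_climate_at_baseline_sites, edges)
    d_ref = schoener_d(n0, n_exp)
    if d_ref == 0:
        raise ValueError("D_ref = 0: past and expected niches are disjoint")
    d_obs, ok = _matched_overlap(
        n0, np.asarray(study_climate_at_study_sites, float), n_exp, n_replicates, rng
    )
    if not ok:
        return ConservatismResult(d_ref, np.nan, np.nan, n_replicates, defined=False)
    index = float(np.clip(d_obs / d_ref, 0.0, 1.0))
    return ConservatismResult(d_ref, min(d_obs, d_ref), index, n_replicates)


def niche_conservatism(
    baseline_climate_at_baseline_sites,
    study_climate_at_study_sites,
    study_climate_at_background_sites,
    bin_width: float = DEFAULT_BIN_TEMPERATURE,
    n_replicates: int = 100,
    seed: int = 0,
) -> ConservatismResult:
    """Niche conservatism NC = D_obs / D_ref for one species.

    N_exp reconstructs N_0 from the *background* study-period surveys
    (irrespective of the species), providing the best-case overlap achievable
    with study-period sampling; N_obs is a matched sample of the climate at
    the species' study localities, matched against N_0.  NC = 1 means the
    species' occupied climate fully tracked its former niche.
    """
    rng = np.random.default_rng(seed)
    edges = shared_edges(
        baseline_climate_at_baseline_sites,
        study_climate_at_study_sites,
        study_climate_at_background_sites,
        bin_width=bin_width,
    )
    n0 = OccupancyDistribution.from_values(baseline_climate_at_baseline_sites, edges)
    d_ref, ok_ref = _matched_overlap(
        n0,
        np.asarray(study_climate_at_background_sites, float),
        n0,
        n_replicates,
        rng,
        strict=True,
    )
    if not ok_ref:
        return ConservatismResult(np.nan, np.nan, np.nan, n_replicates, defined=False)
    if d_ref == 0:
        raise ValueError("D_ref = 0: background cannot reconstruct the past niche")
    d_obs, ok = _matched_overlap(
        n0, np.asarray(study_climate_at_study_sites, float), n0, n_replicates, rng
    )
    if not ok:
        return ConservatismResult(d_ref, np.nan, np.nan, n_replicates, defined=False)
    index = float(np.clip(d_obs / d_ref, 0.0, 1.0))
    return ConservatismResult(d_ref, min(d_obs, d_ref), index, n_replicates)


def community_mean(values_by_species: dict, species_list) -> tuple[float, int]:
    """Unweighted mean of a species attribute over one survey's species.

    Species without a (finite) value are skipped and counted; raises if no
    species carries a value.
    """
    vals = []
    missing = 0
    for s in species_list:
        v = values_by_species.get(s)
        if v is None or not np.isfinite(v):
            missing += 1
        else:
            vals.append(float(v))
    if not vals:
        raise ValueError("no species with a defined value")
    return float(np.mean(vals)), missing
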