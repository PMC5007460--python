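"""Spatial autocorrelation diagnostics: Moran's I distance-class correlograms.

Moran's I with binary distance-class neighbour weights,

    I = (n / sum W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

has expectation -1/(n-1) under spatial independence.  Correlograms evaluate I
per distance class on the climatic debt and on model residuals; a class is
flagged when its mean I exceeds a fixed 0.05 screening threshold, and a
permutation p-value is reported alongside since a fixed threshold is not a
calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["CorrelogramResult", "morans_i", "correlogram", "plot_correlogram"]

FIXED_I_THRESHOLD = 0.05


def _pair_weights(coords: np.ndarray, lo: float, hi: float) -> np.ndarray:
    d = squareform(pdist(coords))
    w = ((d >= lo) & (d < hi)).astype(float)
    np.fill_diagonal(w, 0.0)
    return w


def _morans_i_from_w(x: np.ndarray, w: np.ndarray) -> float:
    n = len(x)
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance in values")
    sw = w.sum()
    if sw == 0:
        raise ValueError("no pairs in the distance class")
    return float(n / sw * (z @ w @ z) / denom)


def morans_i(values, coords, class_interval: tuple[float, float]) -> float:
    """Moran's I with binary weights for pairs inside the distance class."""
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    if len(values) < 8:
        raise ValueError("need at least 8 values")
    w = _pair_weights(coords, *class_interval)
    return _morans_i_from_w(values, w)


@dataclass
class CorrelogramResult:
    edges: np.ndarray            # class edges (m)
    mean_i: np.ndarray           # per class, across bootstrap draws
    ci_low: np.ndarray
    ci_high: np.ndarray
    pair_counts: np.ndarray      # full-data pairs per class
    exceeds_threshold: np.ndarray
    permutation_p: np.ndarray
    n_draws: int

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "class_low": self.edges[:-1],
                "class_high": self.edges[1:],
                "mean_i": self.mean_i,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pairs": self.pair_counts,
                "exceeds_0.05": self.exceeds_threshold,
                "perm_p": self.permutation_p,
            }
        )


def correlogram(
    values,
    coords,
    edges=None,
    n_draws: int = 100,
    subsample: float = 0.8,
    n_permutations: int = 199,
    seed: int = 0,
) -> CorrelogramResult:
    """Bootstrap correlogram of one variable.

    Per draw, a random ``subsample`` fraction of observations is taken and
    Moran's I computed for each distance class; classes without pairs in a
    draw are skipped.  Class edges default to 10-km steps up to 150 km.
    A permutation test (value labels shuffled over locations) supplies a
    calibrated per-class p-value on the full data.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    if edges is None:
        edges = np.arange(0.0, 150_001.0, 10_000.0)
    edges = np.asarray(edges, float)
    n_classes = len(edges) - 1
    n = len(values)

    d_full = squareform(pdist(coords))
    z_full = values - values.mean()
    denom_full = float(z_full @ z_full)
    class_idx = np.digitize(d_full, edges) - 1

    draws = np.full((n_draws, n_classes), np.nan)
    m = max(8, int(round(subsample * n)))
    for b in range(n_draws):
        sel = rng.choice(n, size=min(m, n), replace=False)
        dsub = d_full[np.ix_(sel, sel)]
        zsub = values[sel] - values[sel].mean()
        dn = float(zsub @ zsub)
        if dn == 0:
            continue
        ci = np.digitize(dsub, edges) - 1
        for c in range(n_classes):
            w = (ci == c).astype(float)
            np.fill_diagonal(w, 0.0)
            sw = w.sum()
            if sw == 0:
                continue
            draws[b, c] = len(sel) / sw * (zsub @ w @ zsub) / dn

    pair_counts = np.empty(n_classes, dtype=int)
    obs_i = np.full(n_classes, np.nan)
    perm_p = np.full(n_classes, np.nan)
    for c in range(n_classes):
        w = (class_idx == c).astype(float)
        np.fill_diagonal(w, 0.0)
        pair_counts[c] = int(w.sum() // 2)
        if pair_counts[c] == 0 or denom_full == 0:
            continue
        obs_i[c] = n / w.sum() * (z_full @ w @ z_full) / denom_full
        perm = np.empty(n_permutations)
        for k in range(n_permutations):
            zp = z_full[rng.permutation(n)]
            perm[k] = n / w.sum() * (zp @ w @ zp) / denom_full
        perm_p[c] = (np.sum(np.abs(perm) >= abs(obs_i[c])) + 1) / (n_permutations + 1)

    # distance classes with no pairs in any draw stay NaN
    mean_i = np.full(n_classes, np.nan)
    ci_low = np.full(n_classes, np.nan)
    ci_high = np.full(n_classes, np.nan)
    for c in range(n_classes):
        col = draws[:, c]
        col = col[np.isfinite(col)]
        if col.size:
            mean_i[c] = col.mean()
            ci_low[c] = np.percentile(col, 2.5)
            ci_high[c] = np.percentile(col, 97.5)
    return CorrelogramResult(
        edges=edges,
        mean_i=mean_i,
        ci_low=ci_low,
        ci_high=ci_high,
        pair_counts=pair_counts,
        exceeds_threshold=mean_i > FIXED_I_THRESHOLD,
        permutation_p=perm_p,
        n_draws=n_draws,
    )


def plot_correlogram(result: CorrelogramResult, path=None, title: str = "Spatial correlogram"):
    """Class midpoints vs Moran's I with CI whiskers and the 0.05 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mid = result.midpoints / 1000.0
    ax.errorbar(
        mid,
        result.mean_i,
        yerr=[result.mean_i - result.ci_low, result.ci_high - result.mean_i],
        fmt="o-",
        capsize=3,
    )
    ax.axhline(FIXED_I_THRESHOLD, color="red", linestyle=":")
    ax.axhline(0.0, color="grey", linewidth=0.5)
    ax.set_xlabel("Distance class midpoint (km)")
    ax.set_ylabel("Moran's I")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
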