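"""Bootstrapped weighted-PLS inference on the climatic debt.

The debt of a survey is regressed on the standardized abiotic, biotic and
anthropogenic covariates with partial least squares, which stays stable under
the strong collinearity typical of climate covariates and supports an exact
variance partitioning of the response.  One analysis consists of many
independent draws; each draw

1. thins the surveys to a random subset with all pairwise distances above a
   minimum (default 10 km), suppressing spatial autocorrelation,
2. weights observations by the inverse of their year's survey count,
3. standardizes response and predictors to weighted mean 0 / sd 1,
4. extracts weighted-NIPALS components, keeps those whose score slope is
   significant under a Bonferroni-corrected t-test, and
5. back-transforms to standardized coefficients, R-squared and per-variable
   variance shares.

Coefficients are summarized over draws by mean, 2.5/97.5 percentile CIs and a
sign test (significant when at least ``1 - alpha`` of the draws share a sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlsFit",
    "PlsBootstrapResult",
    "spatial_thinning",
    "observation_weights",
    "standardize",
    "fit_weighted_pls",
    "select_components",
    "coefficients_and_r2",
    "variance_partition",
    "bootstrap_pls",
    "coefficient_significance",
    "error_propagation",
    "run_variant",
    "VARIANT_COLUMNS",
    "BASE_PREDICTORS",
]

BASE_PREDICTORS = [
    "T", "P", "TC", "PC", "pH", "N", "L", "THET", "TO_T", "TO_W",
    "DC", "NC", "HP", "dHA", "LG", "C_W", "C_N", "road_prox", "HPD", "time",
]
EXTRA_PREDICTORS = ["TBUF", "SILVP", "DISTURB", "EXOT"]

VARIANT_COLUMNS = {
    "PLS0": BASE_PREDICTORS,
    "PLS1": BASE_PREDICTORS,
    "PLS2": BASE_PREDICTORS[:-1] + EXTRA_PREDICTORS + ["time"],
    "PLS3": BASE_PREDICTORS,
    "PLS4": BASE_PREDICTORS,
}


# -- draw machinery -------------------------------------------------------

def spatial_thinning(
    x: np.ndarray, y: np.ndarray, min_dist: float = 10_000.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random-order greedy thinning: indices of a subset whose pairwise
    distances all exceed ``min_dist``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = rng.permutation(len(x))
    kept: list[int] = []
    kx = np.empty(len(x))
    ky = np.empty(len(x))
    d2 = min_dist**2
    for i in order:
        k = len(kept)
        if k and np.any((kx[:k] - x[i]) ** 2 + (ky[:k] - y[i]) ** 2 < d2):
            continue
        kx[k], ky[k] = x[i], y[i]
        kept.append(i)
    return np.array(sorted(kept))


def observation_weights(years) -> np.ndarray:
    """w_i = 1 / (number of observations sharing survey i's year), so the
    weights of each year sum to 1 and years contribute evenly."""
    years = np.asarray(years)
    if years.size == 0:
        raise ValueError("empty year vector")
    _, inverse, counts = np.unique(years, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def standardize(values: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre/reduce to weighted mean 0, weighted sd 1."""
    w = np.asarray(w, float)
    wn = w / w.sum()
    mu = float(wn @ values)
    sd = float(np.sqrt(wn @ (values - mu) ** 2))
    if sd < 1e-12:
        raise ValueError("zero-variance column")
    return (values - mu) / sd, mu, sd


# -- weighted PLS ---------------------------------------------------------

@dataclass
class PlsFit:
    """Weighted-NIPALS extraction with everything needed downstream."""

    weights: np.ndarray          # (p, H) unit-norm component weight vectors
    scores: np.ndarray           # (n, H), mutually W-orthogonal
    x_loadings: np.ndarray       # (p, H)
    y_loadings: np.ndarray       # (H,) slopes of y on each score
    rotation: np.ndarray         # (p, H): scores = X @ rotation
    score_wss: np.ndarray        # (H,) weighted score sum of squares t' W t
    response_rd: np.ndarray      # (H,) weighted squared correlation of y with each score
    total_wss: float             # y' W y
    w: np.ndarray                # observation weights used
    predictor_names: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_weighted_pls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    max_components: int | None = None,
    predictor_names: list | None = None,
) -> PlsFit:
    """Extract weighted-PLS components from standardized X, y.

    All inner products use the observation weights; each component's weight
    vector maximizes the weighted covariance of its score with the response
    residual, and scores come out weighted-orthogonal through deflation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float) / np.sum(w)
    n, p = X.shape
    if max_components is None:
        max_components = p
    if max_components > p:
        raise ValueError("max_components exceeds number of predictors")
    col_sd = np.sqrt((w @ X**2) - (w @ X) ** 2)
    if np.any(col_sd < 1e-12):
        bad = np.flatnonzero(col_sd < 1e-12)
        names = [predictor_names[i] for i in bad] if predictor_names else bad.tolist()
        raise ValueError(f"zero-variance predictor column(s): {names}")

    E = X.copy()
    f = y.copy()
    Wc = np.zeros((p, max_components))
    T = np.zeros((n, max_components))
    P = np.zeros((p, max_components))
    q = np.zeros(max_components)
    total_wss = float(y @ (w * y))
    H = 0
    for h in range(max_components):
        c = E.T @ (w * f)
        norm = np.linalg.norm(c)
        if norm < 1e-12:
            break
        wh = c / norm
        t = E @ wh
        twt = float(t @ (w * t))
        if twt < 1e-14:
            break
        ph = E.T @ (w * t) / twt
        qh = float(f @ (w * t)) / twt
        Wc[:, h] = wh
        T[:, h] = t
        P[:, h] = ph
        q[h] = qh
        E = E - np.outer(t, ph)
        f = f - qh * t
        H += 1
    if H == 0:
        raise ValueError("response carries no covariance with the predictors")
    Wc, T, P, q = Wc[:, :H], T[:, :H], P[:, :H], q[:H]
    rotation = Wc @ np.linalg.inv(P.T @ Wc)
    score_wss = np.einsum("ih,i,ih->h", T, w, T)
    rd = q**2 * score_wss / total_wss
    return PlsFit(
        weights=Wc,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        rotation=rotation,
        score_wss=score_wss,
        response_rd=rd,
        total_wss=total_wss,
        w=w,
        predictor_names=list(predictor_names) if predictor_names else [],
    )


def select_components(
    fit: PlsFit, y: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Retain components whose score slope is significant at alpha / H.

    The response is regressed jointly on all extracted scores under the
    observation weights; because the scores are weighted-orthogonal the
    slopes decouple and each gets a Student's t-test.  The threshold is
    Bonferroni-divided by the number of components tested.  Returns
    (retained indices, per-component p-values); an empty retained set is the
    caller's signal to skip the draw.
    """
    w = fit.w
    T = fit.scores
    H = fit.n_components
    n = len(y)
    fitted = T @ fit.y_loadings
    resid = y - fitted
    dof = n - H - 1
    if dof < 1:
        raise ValueError("too few observations for component testing")
    sigma2 = float(resid @ (w * resid)) * n / dof
    se = np.sqrt(sigma2 / (fit.score_wss * n))
    tvals = fit.y_loadings / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    retained = np.flatnonzero(pvals < alpha / H)
    return retained, pvals


def coefficients_and_r2(fit: PlsFit, retained: np.ndarray) -> tuple[np.ndarray, float]:
    """Standardized per-variable coefficients and R-squared from the retained
    components: b = sum over retained of rotation_h * q_h."""
    retained = np.asarray(retained, int)
    if retained.size == 0:
        raise ValueError("empty retained component set")
    coefs = fit.rotation[:, retained] @ fit.y_loadings[retained]
    r2 = float(fit.response_rd[retained].sum())
    return coefs, r2


def variance_partition(fit: PlsFit, retained: np.ndarray) -> np.ndarray:
    """Per-variable share of explained variance.

    share_j = sum_h Rd(y, t_h) * w*_jh^2 over retained components, where the
    component weight vectors w* are unit-norm; the shares therefore sum
    exactly to R-squared.
    """
    retained = np.asarray(retained, int)
    return (fit.weights[:, retained] ** 2) @ fit.response_rd[retained]


# -- bootstrap ------------------------------------------------------------

@dataclass
class PlsBootstrapResult:
    """Aggregated per-draw coefficients of one model variant."""

    variant: str
    predictor_names: list
    coefficients: np.ndarray     # (n_ok, p) per-draw standardized slopes
    r2: np.ndarray               # (n_ok,)
    shares: np.ndarray           # (n_ok, p)
    n_components_retained: np.ndarray
    n_draws: int
    n_failed: int
    alpha_sign: float
    draw_sizes: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.predictor_names):
            c = self.coefficients[:, j]
            sig, direction, frac = coefficient_significance(c, self.alpha_sign)
            rows.append(
                {
                    "variable": name,
                    "mean": c.mean(),
                    "ci_low": np.percentile(c, 2.5),
                    "ci_high": np.percentile(c, 97.5),
                    "share_mean": self.shares[:, j].mean(),
                    "share_pct": 100.0 * self.shares[:, j].mean(),
                    "frac_positive": frac,
                    "significant": sig,
                    "direction": direction,
                }
            )
        return pd.DataFrame(rows).set_index("variable")

    def r2_summary(self) -> dict:
        return {
            "mean": float(self.r2.mean()),
            "ci_low": float(np.percentile(self.r2, 2.5)),
            "ci_high": float(np.percentile(self.r2, 97.5)),
        }


def coefficient_significance(draws: np.ndarray, alpha: float = 0.01) -> tuple[bool, str, float]:
    """Bootstrap sign test: significant when at least 1 - alpha of the draws
    lie on one side of zero.  Returns (significant, direction, frac_positive)."""
    draws = np.asarray(draws, float)
    if draws.size < 100:
        raise ValueError("need >= 100 draws for the sign test")
    n = draws.size
    n_pos = int(np.sum(draws > 0))
    n_neg = int(np.sum(draws < 0))
    need = (1.0 - alpha) * n - 1e-9
    if n_pos >= need:
        return True, "positive", n_pos / n
    if n_neg >= need:
        return True, "negative", n_pos / n
    return False, "none", n_pos / n


def bootstrap_pls(
    data: pd.DataFrame,
    predictors: list[str],
    response: str = "dT",
    n_draws: int = 5000,
    min_dist: float = 10_000.0,
    alpha_components: float = 0.05,
    alpha_sign: float = 0.01,
    max_components: int | None = None,
    seed: int = 0,
    error_sd: dict[str, float] | None = None,
    variant: str = "PLS0",
) -> PlsBootstrapResult:
    """Run the full draw pipeline ``n_draws`` times and aggregate.

    ``data`` must carry the predictor columns, the response, and projected
    ``x``/``y`` coordinates plus ``year``.  ``error_sd`` optionally perturbs
    each named predictor with centred Gaussian measurement noise (per draw,
    before standardization); the response is never perturbed.
    """
    missing = [c for c in predictors + [response, "x", "y", "year"] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns for {variant}: {missing}")
    if error_sd:
        bad = {k: v for k, v in error_sd.items() if v < 0}
        if bad:
            raise ValueError(f"negative error sd: {bad}")
    p = len(predictors)
    X_all = data[predictors].to_numpy(float)
    y_all = data[response].to_numpy(float)
    xs = data["x"].to_numpy(float)
    ys = data["y"].to_numpy(float)
    years = data["year"].to_numpy()
    err = np.zeros(p)
    if error_sd:
        for j, name in enumerate(predictors):
            err[j] = error_sd.get(name, 0.0)

    children = np.random.SeedSequence(seed).spawn(n_draws)
    coefs, r2s, shares, ncomp, sizes = [], [], [], [], []
    n_failed = 0
    for d in range(n_draws):
        rng = np.random.default_rng(children[d])
        idx = spatial_thinning(xs, ys, min_dist, rng)
        Xd = X_all[idx].copy()
        yd = y_all[idx]
        w = observation_weights(years[idx])
        if err.any():
            Xd += rng.normal(0.0, 1.0, Xd.shape) * err[None, :]
        try:
            Xs = np.empty_like(Xd)
            for j in range(p):
                Xs[:, j], _, _ = standardize(Xd[:, j], w)
            ys_std, _, _ = standardize(yd, w)
            fit = fit_weighted_pls(Xs, ys_std, w, max_components, predictors)
            retained, _ = select_components(fit, ys_std, alpha_components)
            if retained.size == 0:
                n_failed += 1
                continue
            b, r2 = coefficients_and_r2(fit, retained)
            sh = variance_partition(fit, retained)
        except ValueError:
            n_failed += 1
            continue
        coefs.append(b)
        r2s.append(r2)
        shares.append(sh)
        ncomp.append(retained.size)
        sizes.append(len(idx))
    if not coefs:
        raise RuntimeError("every bootstrap draw failed")
    return PlsBootstrapResult(
        variant=variant,
        predictor_names=list(predictors),
        coefficients=np.array(coefs),
        r2=np.array(r2s),
        shares=np.array(shares),
        n_components_retained=np.array(ncomp),
        n_draws=n_draws,
        n_failed=n_failed,
        alpha_sign=alpha_sign,
        draw_sizes=np.array(sizes),
    )


def single_fit_residuals(
    data: pd.DataFrame,
    predictors: list[str],
    response: str = "dT",
    min_dist: float = 10_000.0,
    alpha_components: float = 0.05,
    max_components: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One representative thinned fit; returns (row indices, residuals in
    response units).  Used to inspect spatial structure left in the model."""
    rng = np.random.default_rng(seed)
    xs = data["x"].to_numpy(float)
    ys = data["y"].to_numpy(float)
    idx = spatial_thinning(xs, ys, min_dist, rng)
    w = observation_weights(data["year"].to_numpy()[idx])
    X = data[predictors].to_numpy(float)[idx]
    yv = data[response].to_numpy(float)[idx]
    Xs = np.empty_like(X)
    for j in range(X.shape[1]):
        Xs[:, j], _, _ = standardize(X[:, j], w)
    ys_std, mu, sd = standardize(yv, w)
    fit = fit_weighted_pls(Xs, ys_std, w, max_components, predictors)
    retained, _ = select_components(fit, ys_std, alpha_components)
    if retained.size == 0:
        retained = np.array([0])
    fitted = fit.scores[:, retained] @ fit.y_loadings[retained]
    resid = (ys_std - fitted) * sd
    return idx, resid


def error_propagation(
    data: pd.DataFrame,
    predictors: list[str],
    error_sd: dict[str, float],
    response: str = "dT",
    **kwargs,
) -> PlsBootstrapResult:
    """Re-run the bootstrap with per-variable Gaussian measurement error
    injected into the predictors (never the response) before each draw's
    standardization; compare against the noise-free run to check robustness."""
    return bootstrap_pls(data, predictors, response=response, error_sd=error_sd, **kwargs)


def select_variant_surveys(data: pd.DataFrame, variant: str, late_start: int = 1993) -> pd.DataFrame:
    """Apply the survey filter of a model variant."""
    if variant == "PLS0":
        return data
    sub = data[data["year"] >= late_start]
    if variant in ("PLS1", "PLS2"):
        return sub
    flags = sub[["SILVP", "DISTURB", "EXOT"]].to_numpy() if set(
        ["SILVP", "DISTURB", "EXOT"]
    ).issubset(sub.columns) else None
    if flags is None:
        raise ValueError(f"{variant} requires disturbance flag columns")
    disturbed = flags.max(axis=1) > 0
    if variant == "PLS3":
        return sub[disturbed]
    if variant == "PLS4":
        return sub[~disturbed]
    raise ValueError(f"unknown variant {variant!r}")


def run_variant(
    data: pd.DataFrame,
    variant: str,
    late_start: int = 1993,
    **kwargs,
) -> PlsBootstrapResult:
    """Column set + survey filter of a variant, then the bootstrap."""
    if variant not in VARIANT_COLUMNS:
        raise ValueError(f"unknown variant {variant!r}")
    sub = select_variant_surveys(data, variant, late_start)
    return bootstrap_pls(sub, VARIANT_COLUMNS[variant], variant=variant, **kwargs)
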