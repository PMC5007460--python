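"""Transfer functions: reconstruct an environmental variable from composition.

The transfer function is a two-stage hybrid, standard in bioindication work:

1. a weighted-averaging partial least squares (WA-PLS) stage capturing the
   linear part of the species-environment relation.  Component 1 is classical
   weighted averaging (species optimum = occurrence-weighted mean of the
   response; site score = mean optimum of the species present) followed by a
   linear deshrinking regression of the observed response on the site scores.
   Higher components repeat the weighted-averaging cycle on the residuals of
   the previous fit, with site scores orthogonalized (richness-weighted
   Gram-Schmidt) against earlier components.
2. a random-forest stage fitted to the WA-PLS calibration residuals with the
   raw presence/absence columns as features, capturing nonlinear and
   interaction structure the averaging stage cannot.

Because both stages are inverse regressions (they estimate E[x | composition]),
their predictions shrink toward the calibration mean by the unexplained
fraction of variance.  Conditional on the true environment this attenuation
biases reconstructions toward the middle of the gradient, which matters
whenever the application distribution is shifted relative to calibration --
precisely the situation of a warming study period.  A final *classical
recalibration* therefore regresses out-of-fold hybrid predictions on the
observed response and inverts that line, the classical-deshrinking remedy of
the transfer-function literature.  The attenuation slope is estimated from
cross-validated (not in-sample) predictions so the overfit of the fitting
stages does not mask it.

Reconstructions remain undefined outside the climate window spanned by the
calibration response: species optima are themselves censored at the sampled
range, so no deshrinking can recover values beyond it.  Callers should screen
application samples against the model's ``calibration_range``.

The climatic debt of a survey is dT = CrT - FrT: the climatically observed
temperature minus the floristically reconstructed one.  The same machinery,
calibrated on soil pH or inverse C:N, yields the soil covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "CommunityMatrix",
    "WaplsModel",
    "TransferModel",
    "build_matrix",
    "filter_calibration",
    "fit_wapls",
    "fit_residual_learner",
    "fit_transfer",
    "predict_frt",
    "compute_debt",
    "validate_transfer",
]


@dataclass
class CommunityMatrix:
    """Presence/absence matrix (surveys x species) with an aligned response."""

    matrix: np.ndarray          # (n, m) in {0, 1}
    survey_ids: np.ndarray
    species_ids: np.ndarray
    response: np.ndarray        # calibration variable per survey

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.matrix.shape != (len(self.survey_ids), len(self.species_ids)):
            raise ValueError("matrix shape does not match id vectors")
        if len(self.response) != len(self.survey_ids):
            raise ValueError("response length does not match surveys")

    @property
    def n_surveys(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]

    def subset(self, row_idx=None, col_idx=None) -> "CommunityMatrix":
        r = np.arange(self.n_surveys) if row_idx is None else np.asarray(row_idx)
        c = np.arange(self.n_species) if col_idx is None else np.asarray(col_idx)
        return CommunityMatrix(
            self.matrix[np.ix_(r, c)],
            self.survey_ids[r],
            self.species_ids[c],
            self.response[r],
        )


def build_matrix(surveys: pd.DataFrame, response: pd.Series) -> CommunityMatrix:
    """Pivot survey species lists into a presence matrix aligned to a response."""
    ids = surveys["survey_id"].to_numpy()
    all_species = sorted({s for lst in surveys["species"] for s in lst})
    col = {s: j for j, s in enumerate(all_species)}
    mat = np.zeros((len(ids), len(all_species)))
    for i, lst in enumerate(surveys["species"]):
        for s in lst:
            mat[i, col[s]] = 1.0
    return CommunityMatrix(mat, ids, np.asarray(all_species), response.loc[ids].to_numpy())


def filter_calibration(
    matrix: CommunityMatrix, min_richness: int = 5, min_occurrences: int = 5
) -> tuple[CommunityMatrix, dict]:
    """Iteratively drop sparse surveys and rare species until both thresholds hold.

    Removing a rare species can push a survey below the richness threshold and
    vice versa, so the two filters are applied alternately until a fixed point.
    Returns the filtered matrix and removal counts.
    """
    m = matrix
    dropped_surveys = 0
    dropped_species = 0
    while True:
        rows = m.matrix.sum(axis=1)
        keep_r = rows >= min_richness
        if not keep_r.all():
            dropped_surveys += int((~keep_r).sum())
            m = m.subset(row_idx=np.flatnonzero(keep_r))
            continue
        cols = m.matrix.sum(axis=0)
        keep_c = cols >= min_occurrences
        if not keep_c.all():
            dropped_species += int((~keep_c).sum())
            m = m.subset(col_idx=np.flatnonzero(keep_c))
            continue
        break
    if m.n_surveys == 0 or m.n_species == 0:
        raise ValueError(
            "calibration matrix is empty after filtering "
            f"(dropped {dropped_surveys} surveys, {dropped_species} species)"
        )
    report = {"dropped_surveys": dropped_surveys, "dropped_species": dropped_species}
    return m, report


# -- WA-PLS stage ---------------------------------------------------------

@dataclass
class WaplsModel:
    """Fitted WA-PLS stage: per-component species scores and deshrinking fit."""

    species_ids: np.ndarray
    species_scores: np.ndarray      # (m, H) optima per component
    orth_coefs: list[np.ndarray]    # Gram-Schmidt coefficients per component
    beta: np.ndarray                # (H + 1,) deshrinking regression, intercept first
    n_components: int
    fitted: np.ndarray              # calibration predictions at n_components
    rmsd_per_component: np.ndarray  # training RMSD for 1..H components

    def site_scores(self, matrix: np.ndarray) -> np.ndarray:
        """Orthogonalized site scores (n, H) for a presence matrix over
        ``self.species_ids`` columns.  Rows must have >= 1 presence."""
        rows = matrix.sum(axis=1)
        if np.any(rows == 0):
            raise ValueError("survey shares no species with the model")
        scores = np.empty((matrix.shape[0], self.n_components))
        for h in range(self.n_components):
            raw = matrix @ self.species_scores[:, h] / rows
            for j, g in enumerate(self.orth_coefs[h]):
                raw = raw - g * scores[:, j]
            scores[:, h] = raw
        return scores

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        s = self.site_scores(matrix)
        return self.beta[0] + s @ self.beta[1:]


def _deshrink(x: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of the observed response on the site scores (classical deshrinking)."""
    design = np.column_stack([np.ones(len(x)), scores])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return beta, design @ beta


def fit_wapls(matrix: CommunityMatrix, n_components: int = 2) -> WaplsModel:
    """Fit the weighted-averaging PLS stage.

    Component 1 reduces exactly to classical weighted averaging with linear
    deshrinking; each further component runs the same averaging cycle on the
    residuals of the previous fit, orthogonalizing site scores against earlier
    ones under richness weights.
    """
    Y = matrix.matrix
    x = matrix.response
    if np.ptp(x) == 0:
        raise ValueError("constant response vector")
    col_sums = Y.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("species with zero occurrences must be filtered out")
    row_sums = Y.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("survey with empty species list")
    max_rank = min(matrix.n_surveys - 1, matrix.n_species)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")

    H = n_components
    species_scores = np.empty((matrix.n_species, H))
    orth_coefs: list[np.ndarray] = []
    scores = np.empty((matrix.n_surveys, H))
    resid = x.copy()
    rmsds = np.empty(H)
    beta = None
    fitted = None
    for h in range(H):
        u = (Y.T @ resid) / col_sums
        raw = (Y @ u) / row_sums
        gs = np.empty(h)
        for j in range(h):
            gs[j] = np.sum(row_sums * raw * scores[:, j]) / np.sum(
                row_sums * scores[:, j] ** 2
            )
            raw = raw - gs[j] * scores[:, j]
        orth_coefs.append(gs)
        scores[:, h] = raw
        species_scores[:, h] = u
        beta, fitted = _deshrink(x, scores[:, : h + 1])
        resid = x - fitted
        rmsds[h] = float(np.sqrt(np.mean(resid**2)))

    return WaplsModel(
        species_ids=matrix.species_ids.copy(),
        species_scores=species_scores,
        orth_coefs=orth_coefs,
        beta=beta,
        n_components=H,
        fitted=fitted,
        rmsd_per_component=rmsds,
    )


def select_wapls_components(
    matrix: CommunityMatrix,
    max_components: int = 5,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the component count minimizing 10-fold cross-validated RMSD."""
    rng = np.random.default_rng(seed)
    n = matrix.n_surveys
    max_components = min(max_components, n - 2, matrix.n_species)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    sq_err = np.zeros(max_components)
    counts = np.zeros(max_components)
    for fold in folds:
        test = np.zeros(n, bool)
        test[fold] = True
        train = matrix.subset(row_idx=np.flatnonzero(~test))
        occupied = np.flatnonzero(train.matrix.sum(axis=0) > 0)
        train = train.subset(col_idx=occupied)
        model = fit_wapls(train, min(max_components, train.n_surveys - 1))
        test_m = matrix.subset(row_idx=np.flatnonzero(test), col_idx=occupied)
        shared = test_m.matrix.sum(axis=1) > 0
        if not shared.any():
            continue
        test_m = test_m.subset(row_idx=np.flatnonzero(shared))
        s = model.site_scores(test_m.matrix)
        train_scores = model.site_scores(train.matrix)
        for h in range(model.n_components):
            # refit the deshrinking regression for each candidate count
            design = np.column_stack([np.ones(train.n_surveys), train_scores[:, : h + 1]])
            bh, *_ = np.linalg.lstsq(design, train.response, rcond=None)
            pred = bh[0] + s[:, : h + 1] @ bh[1:]
            sq_err[h] += float(np.sum((pred - test_m.response) ** 2))
            counts[h] += len(pred)
    cv_rmsd = np.sqrt(sq_err / np.maximum(counts, 1))
    cv_rmsd[counts == 0] = np.inf
    best = int(np.argmin(cv_rmsd[:max_components])) + 1
    return best, cv_rmsd


# -- hybrid model ---------------------------------------------------------

@dataclass
class TransferModel:
    """Hybrid WA-PLS + random-forest transfer function.

    ``recal_intercept``/``recal_slope`` hold the classical recalibration line
    (out-of-fold prediction regressed on the observed response); predictions
    are passed through its inverse.  The identity line (0, 1) means no
    recalibration.  ``calibration_range`` is the (min, max) of the calibration
    response: predictions are only meaningful for samples whose true value
    plausibly lies inside it.
    """

    wapls: WaplsModel
    forest: RandomForestRegressor
    variable: str = "temperature"
    recal_intercept: float = 0.0
    recal_slope: float = 1.0
    calibration_range: tuple[float, float] = (-np.inf, np.inf)
    calibration_r2: float = float("nan")
    calibration_rmsd: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def species_ids(self) -> np.ndarray:
        return self.wapls.species_ids


def fit_residual_learner(
    wapls: WaplsModel,
    matrix: CommunityMatrix,
    n_trees: int = 500,
    seed: int = 0,
    variable: str = "temperature",
) -> TransferModel:
    """Fit the random-forest stage on the WA-PLS calibration residuals."""
    resid = matrix.response - wapls.predict(matrix.matrix)
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    forest.fit(matrix.matrix, resid)
    model = TransferModel(
        wapls=wapls,
        forest=forest,
        variable=variable,
        calibration_range=(float(matrix.response.min()), float(matrix.response.max())),
    )
    pred = predict_frt(model, matrix.matrix)
    obs = matrix.response
    model.calibration_rmsd = float(np.sqrt(np.mean((pred - obs) ** 2)))
    model.calibration_r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    model.metadata = {
        "n_components": wapls.n_components,
        "n_trees": n_trees,
        "seed": seed,
        "n_calibration_surveys": matrix.n_surveys,
        "n_species": matrix.n_species,
    }
    return model


MIN_RECALIBRATION_SURVEYS = 30
MIN_RECALIBRATION_SLOPE = 0.2


def _out_of_fold_predictions(
    matrix: CommunityMatrix,
    n_components: int,
    n_trees: int,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated hybrid predictions on the calibration matrix.

    Rows whose fold-test communities share no species with the fold-train
    model come back NaN.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_surveys
    folds = np.array_split(rng.permutation(n), n_folds)
    pred = np.full(n, np.nan)
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        rows = np.flatnonzero(test)
        train = matrix.subset(row_idx=np.flatnonzero(~test))
        occupied = np.flatnonzero(train.matrix.sum(axis=0) > 0)
        train = train.subset(col_idx=occupied)
        wapls = fit_wapls(train, min(n_components, train.n_surveys - 1))
        model = fit_residual_learner(wapls, train, n_trees=n_trees, seed=seed)
        test_m = matrix.subset(row_idx=rows, col_idx=occupied)
        shared = test_m.matrix.sum(axis=1) > 0
        p = np.full(len(rows), np.nan)
        if shared.any():
            p[shared] = predict_frt(model, test_m.matrix[shared])
        pred[rows] = p
    return pred


def fit_transfer(
    matrix: CommunityMatrix,
    n_components: int | str = "cv",
    max_components: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    variable: str = "temperature",
    recalibrate: bool = True,
    n_recal_folds: int = 5,
) -> TransferModel:
    """Calibrate the full hybrid transfer function on a filtered matrix.

    With ``recalibrate=True`` (default) the hybrid model's out-of-fold
    predictions are regressed on the observed response and the fitted line is
    inverted at prediction time (classical deshrinking).  This removes the
    regression-to-the-mean attenuation of the inverse stages, which otherwise
    biases reconstructions whenever application samples sit away from the
    calibration mean.  Recalibration is skipped for calibration sets smaller
    than ``MIN_RECALIBRATION_SURVEYS``; a fitted attenuation slope below
    ``MIN_RECALIBRATION_SLOPE`` signals a model with essentially no
    environmental signal and raises.
    """
    if n_components == "cv":
        n_components, _ = select_wapls_components(matrix, max_components, seed=seed)
    wapls = fit_wapls(matrix, int(n_components))
    model = fit_residual_learner(
        wapls, matrix, n_trees=n_trees, seed=seed, variable=variable
    )
    if recalibrate and matrix.n_surveys >= MIN_RECALIBRATION_SURVEYS:
        oof = _out_of_fold_predictions(
            matrix, int(n_components), n_trees, n_folds=n_recal_folds, seed=seed
        )
        good = np.isfinite(oof)
        obs = matrix.response[good]
        slope, intercept = np.polyfit(obs, oof[good], 1)
        if not np.isfinite(slope) or slope < MIN_RECALIBRATION_SLOPE:
            raise ValueError(
                f"attenuation slope {slope:.3f} below {MIN_RECALIBRATION_SLOPE}: "
                "the calibration carries too little environmental signal"
            )
        model.recal_intercept = float(intercept)
        model.recal_slope = float(slope)
        model.metadata["recalibration"] = {
            "slope": float(slope),
            "intercept": float(intercept),
            "n_folds": n_recal_folds,
            "oof_rmsd": float(np.sqrt(np.mean((oof[good] - obs) ** 2))),
            "n_used": int(good.sum()),
        }
        # refresh in-sample figures with the recalibration applied
        pred = predict_frt(model, matrix.matrix)
        model.calibration_rmsd = float(np.sqrt(np.mean((pred - matrix.response) ** 2)))
        model.calibration_r2 = float(np.corrcoef(pred, matrix.response)[0, 1] ** 2)
    return model


def align_to_model(
    model: TransferModel, species_lists: list[list] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Presence matrix over the model's species; counts unknown species per survey."""
    col = {s: j for j, s in enumerate(model.species_ids)}
    n = len(species_lists)
    mat = np.zeros((n, len(col)))
    unknown = np.zeros(n, dtype=int)
    for i, lst in enumerate(species_lists):
        for s in lst:
            j = col.get(s)
            if j is None:
                unknown[i] += 1
            else:
                mat[i, j] = 1.0
    return mat, unknown


def predict_frt(model: TransferModel, matrix: np.ndarray) -> np.ndarray:
    """Hybrid reconstruction for presence rows over the model's species.

    Species unknown to the model must already have been dropped (see
    :func:`align_to_model`); rows with no shared species raise.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    raw = model.wapls.predict(matrix) + model.forest.predict(matrix)
    return (raw - model.recal_intercept) / model.recal_slope


def predict_surveys(
    model: TransferModel, surveys: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Reconstruct the variable for raw surveys; returns (FrT, unknown counts).

    Surveys sharing no species with the model get NaN rather than raising:
    real regional data routinely contain a few such no-analogue communities
    and they must flow through (and be flagged), not abort a run.
    """
    mat, unknown = align_to_model(model, list(surveys["species"]))
    shared = mat.sum(axis=1) > 0
    pred = np.full(len(mat), np.nan)
    if shared.any():
        pred[shared] = predict_frt(model, mat[shared])
    idx = surveys.index
    return pd.Series(pred, index=idx, name="FrT"), pd.Series(unknown, index=idx, name="unknown_species")


def compute_debt(crt, frt):
    """Climatic debt dT = CrT - FrT (positive: composition lags warming)."""
    crt = np.asarray(crt, dtype=float)
    frt = np.asarray(frt, dtype=float)
    if not (np.all(np.isfinite(crt)) and np.all(np.isfinite(frt))):
        raise ValueError("non-finite temperature input")
    out = crt - frt
    return float(out) if out.ndim == 0 else out


def validate_transfer(model: TransferModel, holdout: CommunityMatrix) -> dict:
    """Squared correlation and RMSD of predictions on an independent holdout."""
    if holdout.n_surveys < 2:
        raise ValueError("holdout must contain at least 2 surveys")
    col = {s: j for j, s in enumerate(holdout.species_ids)}
    mat = np.zeros((holdout.n_surveys, len(model.species_ids)))
    for j, s in enumerate(model.species_ids):
        if s in col:
            mat[:, j] = holdout.matrix[:, col[s]]
    shared = mat.sum(axis=1) > 0
    mat, obs = mat[shared], holdout.response[shared]
    pred = predict_frt(model, mat)
    rmsd = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    return {"r2": r2, "rmsd": rmsd, "n": int(shared.sum())}
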