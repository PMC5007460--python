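"""End-to-end orchestration: simulate -> bioindicate -> determinants -> fit -> diagnose.

Each stage is an importable function; :func:`run_all` sequences them, writes
plain-text outputs and a digest manifest, and returns everything in memory.
The stages accept the synthetic generator's outputs but depend only on their
shapes, so user-supplied tables in the same schemas work identically.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioindication as bio
from . import competition as comp
from . import diagnostics as diag
from . import inference as inf
from . import landscape as lm
from . import niche
from .config import PlsConfig, SimulationConfig
from .synthetic import (
    Landscape,
    TrueState,
    generate_infrastructure,
    simulate,
    write_surveys_csv,
)

__all__ = ["PipelineResult", "bioindicate", "species_metrics", "habitat_metrics",
           "competition_metrics", "assemble_predictors", "run_all"]

MIN_OCCURRENCES_CONSERVATISM = 3


@dataclass
class PipelineResult:
    config: SimulationConfig
    landscape: Landscape
    surveys: pd.DataFrame
    truth: TrueState
    transfer_models: dict
    validation: dict
    equilibrium_mean_dt: float
    species_table: pd.DataFrame
    predictors: pd.DataFrame
    pls_results: dict
    correlograms: dict
    null_models: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


# -- helpers --------------------------------------------------------------

def _annual_value(landscape: Landscape, grids: dict, sub: pd.DataFrame) -> np.ndarray:
    """Raster value at each survey's cell for its own year."""
    out = np.empty(len(sub))
    for year, g in sub.groupby("year"):
        r = grids[int(year)]
        iy, ix = r.cell_of(g["x"].to_numpy(), g["y"].to_numpy())
        out[sub.index.get_indexer(g.index)] = r.values[iy, ix]
    return out


def _raster_at(raster, sub: pd.DataFrame) -> np.ndarray:
    iy, ix = raster.cell_of(sub["x"].to_numpy(), sub["y"].to_numpy())
    return raster.values[iy, ix]


# -- stage: bioindication -------------------------------------------------

def bioindicate(
    landscape: Landscape,
    surveys: pd.DataFrame,
    seed: int = 0,
    n_components: int | str = 3,
    n_trees: int = 500,
    holdout_fraction: float = 0.3,
) -> dict:
    """Calibrate the transfer functions on baseline surveys and compute dT.

    Three transfer functions are calibrated on the (equilibrium) baseline
    period: temperature, soil pH and soil C:N.  Temperature reconstruction
    is validated on a held-out baseline subset, then applied to the study
    surveys; dT = CrT - FrT.  Soil predictions provide the pH and N (inverse
    C:N) covariates.  The baseline-period mean dT is reported as an
    equilibrium check (it should be ~0).

    ``n_components`` defaults to a fixed 3 rather than cross-validated
    selection ("cv").  Cross-validation scores interpolation error inside the
    calibration climate window; the debt application evaluates the model on a
    distribution shifted toward the warm edge, where one-component weighted
    averaging compresses reconstructions toward the calibration mean and
    higher components progressively undo that edge compression.  Pass
    ``n_components="cv"`` to recover CV-minimum selection.

    Each survey gets a ``supported`` flag: True when it shares at least one
    species with the temperature model and its observed climate (CrT) lies
    inside the calibration response range.  Outside that range species optima
    are censored at the sampled gradient ends, so reconstructions (and hence
    dT) are biased by construction; downstream debt averages and regressions
    should use supported surveys only.
    """
    rng = np.random.default_rng(seed)
    base = surveys[surveys["period"] == "baseline"]
    study = surveys[surveys["period"] == "study"]
    n_hold = int(round(holdout_fraction * len(base)))
    hold_ids = rng.choice(base.index.to_numpy(), size=n_hold, replace=False)
    calib = base.drop(index=hold_ids)
    hold = base.loc[hold_ids]

    temp_resp = pd.Series(
        _annual_value(landscape, landscape.temperature, base), index=base.index
    )
    models: dict[str, bio.TransferModel] = {}
    matrices = {}
    for var, resp in [
        ("temperature", temp_resp),
        ("ph", pd.Series(_raster_at(landscape.ph, base), index=base.index)),
        ("cn", pd.Series(_raster_at(landscape.cn, base), index=base.index)),
    ]:
        m = bio.build_matrix(calib, resp)
        m, _ = bio.filter_calibration(m)
        # classical recalibration corrects attenuation bias under the warmed
        # study distribution; soils are static, so their models face no shift
        # and recalibration would only amplify prediction noise (1/slope can
        # push C:N outside its physical range)
        models[var] = bio.fit_transfer(
            m,
            n_components=n_components,
            n_trees=n_trees,
            seed=seed,
            variable=var,
            recalibrate=(var == "temperature"),
        )
        matrices[var] = m

    hold_matrix = bio.build_matrix(hold, temp_resp)
    validation = bio.validate_transfer(models["temperature"], hold_matrix)

    out = surveys.copy()
    frt, unknown = bio.predict_surveys(models["temperature"], out)
    crt = pd.Series(
        _annual_value(landscape, landscape.temperature, out), index=out.index
    )
    out["FrT"] = frt
    out["CrT"] = crt
    out["dT"] = crt - frt
    out["unknown_species"] = unknown
    lo, hi = models["temperature"].calibration_range
    out["supported"] = frt.notna() & (crt >= lo) & (crt <= hi)
    ph_pred, _ = bio.predict_surveys(models["ph"], out)
    cn_pred, _ = bio.predict_surveys(models["cn"], out)
    out["pH"] = ph_pred
    out["CN"] = cn_pred
    out["N"] = 1.0 / cn_pred

    eq_rows = out.loc[base.index]
    eq = float(eq_rows.loc[eq_rows["supported"], "dT"].mean())
    return {
        "surveys": out,
        "models": models,
        "validation": validation,
        "equilibrium_mean_dt": eq,
        "calibration_ids": calib.index.to_numpy(),
        "holdout_ids": hold.index.to_numpy(),
    }


# -- stage: species-level niche metrics -----------------------------------

def _occurrence_frame(surveys: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, lst in surveys["species"].items():
        for sp in lst:
            rows.append((sid, sp))
    return pd.DataFrame(rows, columns=["survey_id", "species_id"])


def species_metrics(
    landscape: Landscape,
    surveys: pd.DataFrame,
    traits: pd.DataFrame,
    seed: int = 0,
    n_replicates: int = 100,
    bin_width: float = niche.DEFAULT_BIN_TEMPERATURE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species tolerances and conservatism indices, plus community means.

    Returns (species_table, per-survey community means for study surveys).
    Tolerances use baseline-period occurrences; DC/NC need at least
    ``MIN_OCCURRENCES_CONSERVATISM`` occurrences in each period.
    """
    t_base = landscape.period_mean("temperature", "baseline")
    t_study = landscape.period_mean("temperature", "study")
    p_base = landscape.period_mean("precipitation", "baseline")

    base = surveys[surveys["period"] == "baseline"]
    study = surveys[surveys["period"] == "study"]
    occ = _occurrence_frame(surveys)
    occ = occ.merge(
        surveys[["survey_id", "period", "x", "y"]].reset_index(drop=True),
        on="survey_id",
        how="left",
    )
    iy, ix = t_base.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())
    occ["t_baseline"] = t_base.values[iy, ix]
    occ["t_study"] = t_study.values[iy, ix]
    occ["p_baseline"] = p_base.values[iy, ix]

    background_t = _raster_at(t_study, study)

    rows = []
    ss = np.random.SeedSequence(seed)
    for k, (sp, g) in enumerate(occ.groupby("species_id")):
        gb = g[g["period"] == "baseline"]
        gs = g[g["period"] == "study"]
        rec = {
            "species": sp,
            "n": len(g),
            "L": float(traits.loc[sp, "ellenberg_l"]) if sp in traits.index else np.nan,
            "LG": float(traits.loc[sp, "longevity"]) if sp in traits.index else np.nan,
            "TO_T": np.nan,
            "TO_W": np.nan,
            "DC": np.nan,
            "NC": np.nan,
        }
        if len(gb):
            rec["TO_T"] = niche.climatic_tolerance(gb["t_baseline"])
            rec["TO_W"] = niche.climatic_tolerance(gb["p_baseline"])
            rec["t_lower"] = float(gb["t_baseline"].min())
            rec["t_upper"] = float(gb["t_baseline"].max())
        if len(gb) >= MIN_OCCURRENCES_CONSERVATISM and len(gs) >= MIN_OCCURRENCES_CONSERVATISM:
            sp_seed = int(ss.generate_state(1)[0] % (2**31)) + k
            try:
                dc = niche.distribution_conservatism(
                    gb["t_baseline"].to_numpy(),
                    gb["t_study"].to_numpy(),
                    gs["t_study"].to_numpy(),
                    bin_width=bin_width,
                    n_replicates=n_replicates,
                    seed=sp_seed,
                )
                if dc.defined:
                    rec["DC"] = dc.index
            except ValueError:
                pass
            try:
                nc = niche.niche_conservatism(
                    gb["t_baseline"].to_numpy(),
                    gs["t_study"].to_numpy(),
                    background_t,
                    bin_width=bin_width,
                    n_replicates=n_replicates,
                    seed=sp_seed + 1,
                )
                if nc.defined:
                    rec["NC"] = nc.index
            except ValueError:
                pass
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("species", drop=False)

    comm_rows = []
    for sid, lst in study["species"].items():
        rec = {"survey_id": sid}
        for col in ("TO_T", "TO_W", "DC", "NC", "L", "LG"):
            vals = table.loc[[s for s in lst if s in table.index], col].dropna()
            rec[col] = float(vals.mean()) if len(vals) else np.nan
        comm_rows.append(rec)
    community = pd.DataFrame(comm_rows).set_index("survey_id")
    return table, community


# -- stage: habitat connectivity metrics ----------------------------------

def habitat_metrics(
    landscape: Landscape,
    surveys: pd.DataFrame,
    species_table: pd.DataFrame,
    radius: float = 10_000.0,
) -> pd.DataFrame:
    """Community-mean past-habitat proximity (HP) and aggregation change (dHA)."""
    t_base = landscape.period_mean("temperature", "baseline")
    t_study = landscape.period_mean("temperature", "study")
    study = surveys[surveys["period"] == "study"]

    habitats = {}
    for sp, rec in species_table.iterrows():
        if not np.isfinite(rec.get("t_lower", np.nan)):
            continue
        try:
            past = lm.potential_habitat(
                rec["t_lower"], rec["t_upper"], t_base, landscape.forest_baseline,
                period="baseline", species_id=sp,
            )
            cur = lm.potential_habitat(
                rec["t_lower"], rec["t_upper"], t_study, landscape.forest_study,
                period="study", species_id=sp,
            )
        except ValueError:
            continue
        if past.cells.any():
            habitats[sp] = (past, cur)

    r = landscape.forest_baseline
    X, Y = r.cell_centers()
    from scipy.spatial import cKDTree

    trees = {
        sp: cKDTree(np.column_stack([X[past.cells], Y[past.cells]]))
        for sp, (past, _cur) in habitats.items()
    }

    ncells = int(np.ceil(radius / r.cell_size))
    rows = []
    for sid, rec in study.iterrows():
        x, y = rec["x"], rec["y"]
        iy0, ix0 = r.cell_of(x, y)
        sl = (
            slice(max(iy0 - ncells, 0), iy0 + ncells + 1),
            slice(max(ix0 - ncells, 0), ix0 + ncells + 1),
        )
        disc = (X[sl] - x) ** 2 + (Y[sl] - y) ** 2 <= radius**2
        hp_vals, dha_vals = [], []
        for sp in rec["species"]:
            hc = habitats.get(sp)
            if hc is None:
                continue
            past, cur = hc
            if past.cells[iy0, ix0]:
                d = 0.0
            else:
                d, _ = trees[sp].query([x, y])
            hp_vals.append(1.0 / (d + r.cell_size))
            pc = past.cells[sl] & disc
            cc = cur.cells[sl] & disc
            if pc.any() and cc.any():
                dha_vals.append(
                    lm.aggregation_index(cc) - lm.aggregation_index(pc)
                )
        rows.append(
            {
                "survey_id": sid,
                "HP": float(np.mean(hp_vals)) if hp_vals else np.nan,
                "dHA": float(np.mean(dha_vals)) if dha_vals else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("survey_id")


# -- stage: competition ---------------------------------------------------

def competition_metrics(
    landscape: Landscape,
    surveys: pd.DataFrame,
    cn_by_survey: pd.Series,
    seed: int = 0,
    n_null_surveys: int = 0,
    n_null_draws: int = 2500,
    pool_radius: float = 10_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Community competition indices C_W / C_N, plus optional null models.

    Species occupancy distributions run along the baseline precipitation
    gradient (C_W) and along the bioindicated soil C:N gradient (C_N).
    """
    p_base = landscape.period_mean("precipitation", "baseline")
    base = surveys[surveys["period"] == "baseline"]
    study = surveys[surveys["period"] == "study"]

    occ = _occurrence_frame(base).merge(
        base[["survey_id", "x", "y"]].reset_index(drop=True), on="survey_id", how="left"
    )
    iy, ix = p_base.cell_of(occ["x"].to_numpy(), occ["y"].to_numpy())
    occ["precip"] = p_base.values[iy, ix]
    occ["cn"] = cn_by_survey.loc[occ["survey_id"]].to_numpy()

    matrices = {}
    for name, col, width in [("C_W", "precip", 50.0), ("C_N", "cn", 0.5)]:
        # bioindicated gradients can be NaN for no-analogue surveys
        sub = occ[np.isfinite(occ[col])]
        edges = niche.shared_edges(sub[col].to_numpy(), bin_width=width)
        dists = {}
        for sp, g in sub.groupby("species_id"):
            if len(g) >= 2:
                dists[sp] = niche.OccupancyDistribution.from_values(g[col], edges)
        matrices[name] = comp.pairwise_differentiation(dists)

    rows = []
    for sid, lst in study["species"].items():
        rec = {"survey_id": sid}
        for name, mat in matrices.items():
            try:
                rec[name] = comp.community_competition(lst, mat)
            except ValueError:
                rec[name] = np.nan
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("survey_id")

    null_df = None
    if n_null_surveys > 0:
        rng = np.random.default_rng(seed)
        pick = rng.choice(study.index.to_numpy(), size=min(n_null_surveys, len(study)), replace=False)
        nm_rows = []
        for sid in pick:
            rec = study.loc[sid]
            pool = comp.regional_pool(study, rec["x"], rec["y"], pool_radius)
            for name, mat in matrices.items():
                try:
                    res = comp.null_model_test(
                        rec["species"], pool, mat,
                        n_draws=n_null_draws, seed=int(rng.integers(2**31)),
                    )
                except ValueError:
                    continue
                nm_rows.append(
                    {
                        "survey_id": sid,
                        "index": name,
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "p": res.p_value,
                        "significant": res.significant,
                    }
                )
        null_df = pd.DataFrame(nm_rows)
    return table, null_df


# -- stage: predictor assembly --------------------------------------------

def assemble_predictors(
    landscape: Landscape,
    surveys: pd.DataFrame,
    community: pd.DataFrame,
    habitat: pd.DataFrame,
    competition_table: pd.DataFrame,
    roads,
    population,
) -> pd.DataFrame:
    """Build the per-survey response + covariate table for the PLS models.

    Only supported study surveys (see :func:`bioindicate`) enter the table:
    debts reconstructed outside the calibration climate window are biased by
    construction and would contaminate the regression.
    """
    study = surveys[surveys["period"] == "study"]
    if "supported" in study.columns:
        study = study[study["supported"]]
    baseline_years = landscape.config.years_in("baseline")
    t_base = landscape.period_mean("temperature", "baseline")
    p_base = landscape.period_mean("precipitation", "baseline")

    df = pd.DataFrame(index=study.index)
    df["x"] = study["x"]
    df["y"] = study["y"]
    df["year"] = study["year"]
    df["dT"] = study["dT"]
    df["T"] = _raster_at(t_base, study)
    df["P"] = _raster_at(p_base, study)
    df["TC"] = _annual_value(landscape, landscape.temperature, study) - df["T"]
    df["PC"] = _annual_value(landscape, landscape.precipitation, study) - df["P"]
    df["pH"] = study["pH"]
    df["N"] = study["N"]
    thet = np.array(
        [
            lm.temperature_heterogeneity(
                rec["x"], rec["y"], t_base, landscape.fine_temperature
            )
            for _, rec in study.iterrows()
        ]
    )
    df["THET"] = thet
    for col in ("TO_T", "TO_W", "DC", "NC", "L", "LG"):
        df[col] = community[col]
    df["HP"] = habitat["HP"]
    df["dHA"] = habitat["dHA"]
    df["C_W"] = competition_table["C_W"]
    df["C_N"] = competition_table["C_N"]
    df["road_prox"] = [
        lm.distance_to_network(rec["x"], rec["y"], roads) for _, rec in study.iterrows()
    ]
    df["HPD"] = [
        lm.population_within_radius(rec["x"], rec["y"], population)
        for _, rec in study.iterrows()
    ]
    df["time"] = study["year"].astype(float)
    df["TBUF"] = study["tbuf"] if "tbuf" in study.columns else 0.0
    for flag, col in [("silvp", "SILVP"), ("disturb", "DISTURB"), ("exot", "EXOT")]:
        df[col] = study[flag] if flag in study.columns else 0
    return df


# -- full run -------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: SimulationConfig,
    pls: PlsConfig | None = None,
    variants: tuple[str, ...] = ("PLS0",),
    out_dir: str | Path | None = None,
    n_null_surveys: int = 20,
    n_null_draws: int = 500,
    n_trees: int = 500,
    with_correlograms: bool = True,
    write_rasters: bool = False,
) -> PipelineResult:
    """Run every stage on a fresh synthetic system and collect the results."""
    pls = pls or PlsConfig()
    timers: dict[str, float] = {}
    t0 = _time.perf_counter()

    landscape, surveys, truth = simulate(config)
    roads, population = generate_infrastructure(config)
    timers["simulate"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    bi = bioindicate(landscape, surveys, seed=config.seed, n_trees=n_trees)
    surveys = bi["surveys"]
    timers["bioindicate"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    species_table, community = species_metrics(
        landscape, surveys, truth.pool, seed=config.seed
    )
    habitat = habitat_metrics(landscape, surveys, species_table)
    competition_table, null_df = competition_metrics(
        landscape,
        surveys,
        surveys["CN"],
        seed=config.seed,
        n_null_surveys=n_null_surveys,
        n_null_draws=n_null_draws,
    )
    predictors = assemble_predictors(
        landscape, surveys, community, habitat, competition_table, roads, population
    )
    n_before = len(predictors)
    predictors = predictors.dropna()
    timers["determinants"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    pls_results = {}
    for variant in variants:
        pls_results[variant] = inf.run_variant(
            predictors,
            variant,
            late_start=pls.late_period_start,
            n_draws=pls.n_draws,
            min_dist=pls.min_dist,
            alpha_components=pls.alpha_components,
            alpha_sign=pls.alpha_sign,
            max_components=pls.max_components,
            seed=pls.seed,
        )
    timers["fit"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    correlograms = {}
    if with_correlograms:
        coords = predictors[["x", "y"]].to_numpy()
        correlograms["dT"] = diag.correlogram(
            predictors["dT"].to_numpy(), coords, n_draws=50, seed=config.seed
        )
        first = variants[0]
        idx, resid = inf.single_fit_residuals(
            predictors,
            inf.VARIANT_COLUMNS[first],
            min_dist=pls.min_dist,
            alpha_components=pls.alpha_components,
            seed=pls.seed,
        )
        correlograms["residuals"] = diag.correlogram(
            resid, coords[idx], n_draws=50, seed=config.seed
        )
    timers["diagnose"] = _time.perf_counter() - t0

    manifest = {
        "seed": config.seed,
        "n_surveys": int(len(surveys)),
        "n_predictor_rows": int(len(predictors)),
        "n_predictor_rows_dropped": int(n_before - len(predictors)),
        "variants": list(variants),
        "timers_s": {k: round(v, 3) for k, v in timers.items()},
        "files": {},
    }

    result = PipelineResult(
        config=config,
        landscape=landscape,
        surveys=surveys,
        truth=truth,
        transfer_models=bi["models"],
        validation=bi["validation"],
        equilibrium_mean_dt=bi["equilibrium_mean_dt"],
        species_table=species_table,
        predictors=predictors,
        pls_results=pls_results,
        correlograms=correlograms,
        null_models=null_df,
        manifest=manifest,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        write_surveys_csv(surveys, out_dir / "surveys.csv")
        species_out = species_table[["species", "n", "L", "TO_T", "TO_W", "LG", "NC", "DC"]]
        species_out.to_csv(out_dir / "species_table.csv", index=False)
        keep = (surveys["period"] == "study") & surveys["supported"]
        debt = surveys.loc[keep, ["survey_id", "x", "y", "year", "dT"]]
        debt.to_csv(out_dir / "survey_debt.csv", index=False)
        predictors.to_csv(out_dir / "predictors.csv")
        for variant, res in pls_results.items():
            res.summary().to_csv(out_dir / f"{variant.lower()}_summary.csv")
        for name, c in correlograms.items():
            c.to_frame().to_csv(out_dir / f"correlogram_{name}.csv", index=False)
            diag.plot_correlogram(c, out_dir / f"correlogram_{name}.png",
                                  title=f"Correlogram ({name})")
        if null_df is not None and len(null_df):
            null_df.to_csv(out_dir / "null_models.csv", index=False)
        if write_rasters:
            from .synthetic import write_landscape

            write_landscape(landscape, out_dir / "rasters")
        for p in sorted(out_dir.rglob("*")):
            if p.is_file() and p.suffix != ".png":
                manifest["files"][str(p.relative_to(out_dir))] = _digest(p)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
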