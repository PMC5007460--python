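"""Readers for the two published per-species / per-survey benchmark tables.

The species table carries, for each of the modelled herbaceous species, its
Ellenberg light value (L), thermal and precipitation tolerance ranges
(TO_T, TO_W), longevity (LG) and the niche- and distribution-conservatism
indices (NC, DC).  The survey table carries one row per floristic survey with
its coordinates, year and climatic debt (dT).  Both are consumed as optional
benchmark inputs: the loaders validate the schema and report summary
statistics for comparison with a pipeline run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_TABLE_COLUMNS",
    "SURVEY_TABLE_COLUMNS",
    "load_species_table",
    "load_survey_table",
]

SPECIES_TABLE_COLUMNS = ["species", "n", "L", "TO_T", "TO_W", "LG", "NC", "DC"]
SURVEY_TABLE_COLUMNS = ["survey_id", "x", "y", "year", "dT"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def load_species_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Load and validate the per-species benchmark table.

    Checks column presence and that the conservatism indices lie in [0, 1];
    returns the table and summary statistics (species count, trait means).
    """
    df = pd.read_csv(path)
    _check_columns(df, SPECIES_TABLE_COLUMNS, "species table")
    for col in ("NC", "DC"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"species table: column {col} outside [0, 1]")
    stats = {
        "n_species": int(len(df)),
        "mean_TO_T": float(df["TO_T"].mean()),
        "mean_TO_W": float(df["TO_W"].mean()),
        "mean_NC": float(df["NC"].mean()),
        "mean_DC": float(df["DC"].mean()),
        "mean_LG": float(df["LG"].mean()),
    }
    return df, stats


def load_survey_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Load and validate the per-survey debt table.

    Checks column presence and that every dT is finite; returns the table and
    the debt summary (mean, sd, n) used for benchmark comparison.
    """
    df = pd.read_csv(path)
    _check_columns(df, SURVEY_TABLE_COLUMNS, "survey table")
    dt = df["dT"].to_numpy(float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("survey table: column dT contains non-finite values")
    stats = {
        "n_surveys": int(len(df)),
        "mean_dT": float(dt.mean()),
        "sd_dT": float(dt.std(ddof=1)) if len(dt) > 1 else 0.0,
    }
    return df, stats
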