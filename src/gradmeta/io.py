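"""Study-level data schemas, CSV I/O, validation and climate derivation.

Two tabular schemas drive the pipeline:

* **experimental** — one row per treatment-vs-control observation of a soil
  variable (C, N, P concentration in g/kg, or a log-analyzed stoichiometric
  ratio), with group means, SDs and sample sizes plus site climate
  (MAT in deg C, MAP in mm/yr) and ecosystem / soil-class labels.
* **observational** — one row per field site, with the site's soil value,
  MAT, MAP, mean annual potential evapotranspiration (MAE, mm/yr), a region
  label for geographic clustering, and ecosystem / soil labels.

The aridity index AI = MAP/MAE is derived per site; *aridity* is defined
relative to the loaded dataset as (max AI in the dataset) - AI, so it
increases with dryness and the wettest site scores exactly zero.

Files are UTF-8 comma-separated CSV with a mandatory header, "." decimal
and empty fields for missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TREATMENTS = ("water_addition", "drought", "warming")
VARIABLES = ("C", "N", "P", "CN", "CP", "NP")
COVARIATES = ("map", "mat", "aridity")

#: experimental driver -> observational covariate pairing used by the contrast
DRIVER_PAIRS = {"water_addition": "map", "drought": "aridity", "warming": "mat"}

EXPERIMENTAL_COLUMNS = [
    "study_id", "record_id", "treatment", "variable",
    "x_e", "s_e", "n_e", "x_c", "s_c", "n_c",
    "mat", "map", "ecosystem", "soil",
]
OBSERVATIONAL_COLUMNS = [
    "study_id", "region", "site_id", "variable", "value",
    "mat", "map", "mae", "ecosystem", "soil",
]


class SchemaError(ValueError):
    """A CSV file does not conform to the declared column schema."""


class RecordValidationError(ValueError):
    """A row violates a record-level invariant; names the offending row."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} data is missing column(s): {', '.join(missing)}")


def validate_experimental(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an experimental-record table; return it with canonical dtypes.

    Raises
    ------
    SchemaError
        If a required column is absent.
    RecordValidationError
        Naming ``(study_id, record_id)`` of the first offending row.
    """
    _require_columns(df, EXPERIMENTAL_COLUMNS, "experimental")
    df = df.copy()
    for col in ("x_e", "s_e", "x_c", "s_c", "mat", "map"):
        df[col] = pd.to_numeric(df[col])
    for col in ("n_e", "n_c"):
        df[col] = pd.to_numeric(df[col]).astype(int)

    def _bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            row = df[mask].iloc[0]
            raise RecordValidationError(
                f"record ({row['study_id']}, {row['record_id']}): {why}"
            )

    _bad(~df["treatment"].isin(TREATMENTS), "unknown treatment")
    _bad(~df["variable"].isin(VARIABLES), "unknown variable")
    _bad((df["x_e"] <= 0) | (df["x_c"] <= 0),
         "group means must be positive (log response ratio undefined)")
    _bad((df["s_e"] < 0) | (df["s_c"] < 0), "SDs must be non-negative")
    _bad((df["n_e"] < 2) | (df["n_c"] < 2), "group sizes must be >= 2")
    dup = df.duplicated(subset=["study_id", "record_id"], keep=False)
    _bad(dup, "duplicate (study_id, record_id)")
    return df


def validate_observational(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observational-site table; return it with canonical dtypes."""
    _require_columns(df, OBSERVATIONAL_COLUMNS, "observational")
    df = df.copy()
    for col in ("value", "mat", "map", "mae"):
        df[col] = pd.to_numeric(df[col])

    def _bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            row = df[mask].iloc[0]
            raise RecordValidationError(
                f"site ({row['study_id']}, {row['site_id']}): {why}"
            )

    _bad(~df["variable"].isin(VARIABLES), "unknown variable")
    _bad(df["value"] <= 0, "soil value must be positive")
    _bad(df["map"] < 0, "MAP must be non-negative")
    return df


def read_experimental(path) -> pd.DataFrame:
    """Read and validate an experimental CSV (one row per record)."""
    return validate_experimental(pd.read_csv(path))


def write_experimental(df: pd.DataFrame, path) -> None:
    validate_experimental(df)[EXPERIMENTAL_COLUMNS].to_csv(path, index=False)


def read_observational(path) -> pd.DataFrame:
    """Read and validate an observational CSV (one row per site)."""
    return validate_observational(pd.read_csv(path))


def write_observational(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c in OBSERVATIONAL_COLUMNS + ["ai", "aridity"]]
    validate_observational(df)[cols].to_csv(path, index=False)


def aridity_index(map_mm, mae_mm):
    """Aridity index AI = MAP / MAE (both mm/yr, result dimensionless).

    ``mae_mm`` must be strictly positive.
    """
    map_mm = np.asarray(map_mm, dtype=float)
    mae_mm = np.asarray(mae_mm, dtype=float)
    if np.any(mae_mm <= 0):
        raise ValueError("MAE must be > 0 to derive the aridity index")
    out = map_mm / mae_mm
    return float(out) if out.ndim == 0 else out


def derive_aridity(sites: pd.DataFrame) -> pd.DataFrame:
    """Fill ``ai`` and ``aridity`` columns on a copy of an observational table.

    ``ai`` is computed from MAP and MAE if not already present. ``aridity``
    is (max AI over the table) - AI, so it is non-negative, exactly zero at
    the wettest site, and perfectly anti-correlated with AI. The maximum is
    taken over the rows given here — callers synthesizing multi-variable
    datasets should derive once over the full table.
    """
    if len(sites) == 0:
        raise ValueError("cannot derive aridity for an empty site collection")
    sites = sites.copy()
    if "ai" not in sites.columns or sites["ai"].isna().any():
        if "mae" not in sites.columns or sites["mae"].isna().any():
            raise ValueError(
                "cannot derive AI: column 'mae' is absent or incomplete"
            )
        sites["ai"] = aridity_index(sites["map"].to_numpy(),
                                    sites["mae"].to_numpy())
    ai_max = float(sites["ai"].max())
    sites["aridity"] = ai_max - sites["ai"]
    sites.attrs["ai_max"] = ai_max
    return sites
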