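"""CSV interchange schemas.

All stages exchange plain CSV with documented headers, ISO-8601
timestamps, UTF-8 and a decimal point.  Schemas:

samples:  subject_id, period_id, timestamp, time_since_dose, enrichment, is_baseline
doses:    subject_id, period_id, dose_time, dose_mass_g, purity, body_mass_kg
weather:  date, tmean, tmax, tmin, dewpoint, precip
species:  species, group, seasonal_stress_flag, mass_kg, water_turnover_l_d
fits:     subject_id, period_id, e0_excess, kd, r_squared, n_points, qc_pass
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "samples": [
        "subject_id",
        "period_id",
        "timestamp",
        "time_since_dose",
        "enrichment",
        "is_baseline",
    ],
    "doses": [
        "subject_id",
        "period_id",
        "dose_time",
        "dose_mass_g",
        "purity",
        "body_mass_kg",
    ],
    "weather": ["date", "tmean", "tmax", "tmin", "dewpoint", "precip"],
    "species": [
        "species",
        "group",
        "seasonal_stress_flag",
        "mass_kg",
        "water_turnover_l_d",
    ],
    "fits": [
        "subject_id",
        "period_id",
        "e0_excess",
        "kd",
        "r_squared",
        "n_points",
        "qc_pass",
    ],
}

_STRING_COLS = {"subject_id", "period_id", "species", "group"}


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the documented CSV tables, validating its header."""
    expected = SCHEMAS[kind]
    df = pd.read_csv(path, dtype={c: str for c in _STRING_COLS if c in expected})
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for schema {kind!r}")
    return df[expected]


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a table in the documented column order with canonical floats."""
    expected = SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write schema {kind!r}: missing {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[expected].to_csv(path, index=False, float_format="%.10g")
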