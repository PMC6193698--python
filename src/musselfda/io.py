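"""CSV dialects for measurement and diet tables.

External files carry unit-suffixed column names (``L_mm``, ``CR_l_h``, ...)
and a ``date_or_day`` column holding either ISO-8601 dates or integer day
offsets; internally everything is canonical short names with ``t`` in days
since the earliest record.  Empty cells are missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MEASUREMENT_DIALECT = {
    "individual_id": "individual_id",
    "tank_id": "tank_id",
    "date_or_day": "t",
    "L_mm": "L",
    "TFW_g": "TFW",
    "CR_l_h": "CR",
    "AE": "AE",
    "VO2_ml_h": "VO2",
    "VNH4_ug_h": "VNH4",
}
DIET_DIALECT = {
    "tank_id": "tank_id",
    "date_or_day": "t",
    "TPM_mg_l": "TPM",
    "PIM_mg_l": "PIM",
    "POM_mg_l": "POM",
}


def _to_days(col: pd.Series, origin=None):
    """Convert ISO dates or numeric offsets to float days since origin."""
    try:
        days = pd.to_numeric(col)
        return days.astype(float), origin
    except (ValueError, TypeError):
        pass
    dates = pd.to_datetime(col, format="ISO8601")
    origin = dates.min() if origin is None else origin
    return (dates - origin).dt.total_seconds() / 86400.0, origin


def read_measurements(path, origin=None):
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_DIALECT) - set(df.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")
    df = df[list(MEASUREMENT_DIALECT)].rename(columns=MEASUREMENT_DIALECT)
    df["t"], origin = _to_days(df["t"], origin)
    return df, origin


def read_diet(path, origin=None):
    df = pd.read_csv(path)
    missing = set(DIET_DIALECT) - set(df.columns)
    if missing:
        raise ValueError(f"diet file missing columns: {sorted(missing)}")
    df = df[list(DIET_DIALECT)].rename(columns=DIET_DIALECT)
    df["t"], origin = _to_days(df["t"], origin)
    return df, origin


_REVERSE_M = {v: k for k, v in MEASUREMENT_DIALECT.items()}
_REVERSE_D = {v: k for k, v in DIET_DIALECT.items()}


def write_measurements(df: pd.DataFrame, path) -> None:
    df.rename(columns=_REVERSE_M).to_csv(path, index=False)


def write_diet(df: pd.DataFrame, path) -> None:
    df.rename(columns=_REVERSE_D).to_csv(path, index=False)
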