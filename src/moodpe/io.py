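"""CSV/JSON interchange with schema validation.

All tables travel as UTF-8 CSV with a header row and ISO-8601 dates; fitted
objects and ground truth travel as JSON.  Readers validate column presence
and value constraints up front and name the offending column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "read_json", "write_json"]

# column name -> dtype kind ("date", "str", "float", "int")
SCHEMAS: dict[str, dict[str, str]] = {
    "games": {"date": "date", "msa_id": "str", "team_id": "str", "outcome": "float"},
    "irradiance": {"timestamp": "date", "msa_id": "str", "dni_wm2": "float"},
    "sentiment": {
        "date": "date", "msa_id": "str", "county_id": "str",
        "mean_valence": "float", "n_tweets": "int",
    },
    "lottery": {"date": "date", "postal_code": "str", "sales_usd": "float"},
    "population": {"unit_id": "str", "adult_population": "int", "total_population": "int"},
    "weather": {"date": "date", "msa_id": "str", "snow": "int", "visibility_miles": "float"},
    "geography": {"postal_code": "str", "county_id": "str", "msa_id": "str"},
    "pe": {"date": "date", "msa_id": "str", "series": "str", "pe": "float"},
}

_CASTS = {"date": "datetime64[ns]", "str": str, "float": float, "int": int}


def _validate_games(df: pd.DataFrame) -> None:
    bad = ~df["outcome"].isin((0.0, 0.5, 1.0))
    if bad.any():
        raise ValueError(
            f"column 'outcome': sports outcomes must be 0, 0.5 or 1 "
            f"(first bad value {df.loc[bad, 'outcome'].iloc[0]!r})"
        )


def _validate_irradiance(df: pd.DataFrame) -> None:
    if (df["dni_wm2"] < 0).any():
        raise ValueError("column 'dni_wm2': negative irradiance")


_EXTRA_CHECKS = {"games": _validate_games, "irradiance": _validate_irradiance}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one interchange table."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    path = Path(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    for col, kind in spec.items():
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
        try:
            if kind == "date":
                df[col] = pd.to_datetime(df[col], format="ISO8601")
            else:
                df[col] = df[col].astype(_CASTS[kind])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: column '{col}' failed {kind} parsing: {err}") from err
    check = _EXTRA_CHECKS.get(schema)
    if check is not None:
        check(df)
    return df[list(spec)]


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a table in the interchange dialect (ISO dates, header row)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            if (out[col].dt.time == pd.Timestamp(0).time()).all():
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            else:
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Timestamp):
            return o.isoformat()
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_Encoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
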