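"""Schema-validated tabular I/O for every pipeline input and output.

All tables travel as :class:`pandas.DataFrame` with canonical column names.
Six input schemas are defined (``temperature``, ``health``, ``size``,
``dissection``, ``symbiont``, ``polyp_density``); each is validated on read
and on write so a malformed file fails loudly with the offending row index
rather than propagating silently.

Egg diameters are stored in a single text cell: eggs separated by ``;``,
the two perpendicular axis measurements of one egg separated by ``|``
(e.g. ``"0.58|0.61;0.55|0.57"`` for a two-egg polyp).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Ordinal fragment health categories, worst last. The index (1-based) of a
#: category is its ordinal level; the bleaching/mortality weight is index-1.
HEALTH_CATEGORIES = (
    "healthy",
    "half_bleached",
    "bleached",
    "partial_mortality",
    "dead",
)
N_CATEGORIES = len(HEALTH_CATEGORIES)
CATEGORY_WEIGHT = {c: i for i, c in enumerate(HEALTH_CATEGORIES)}

_DATETIME = "datetime64[ns]"

SCHEMAS: dict[str, dict] = {
    "temperature": {
        "columns": {"tank_id": str, "timestamp": _DATETIME, "temp_c": float},
    },
    "health": {
        "columns": {
            "colony_id": str,
            "fragment_id": str,
            "tank_id": str,
            "survey_time": _DATETIME,
            "category": str,
        },
    },
    "size": {
        "columns": {
            "colony_id": str,
            "survey_date": _DATETIME,
            "diameter_cm": float,  # optional per row (NaN allowed)
            "sa_cm2": float,
            "livesa_cm2": float,
            "volume_cm3": float,
            "partial_mortality": bool,
        },
        "optional": {"diameter_cm"},
    },
    "dissection": {
        "columns": {
            "colony_id": str,
            "fragment_id": str,
            "polyp_index": int,
            "egg_count": int,
            "egg_diameters_mm": str,
        },
        "optional": {"egg_diameters_mm"},
    },
    "symbiont": {
        "columns": {
            "colony_id": str,
            "its2_profile": str,
            "relative_abundance": float,
        },
    },
    "polyp_density": {
        "columns": {"colony_id": str, "polyps_per_cm2": float},
    },
}


def encode_egg_diameters(diameter_pairs: Iterable[tuple[float, float]]) -> str:
    """Serialize per-egg axis pairs into the single-cell text format."""
    return ";".join(f"{a:.4g}|{b:.4g}" for a, b in diameter_pairs)


def decode_egg_diameters(cell: str | float) -> list[tuple[float, float]]:
    """Parse the single-cell text format back into per-egg axis pairs."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    pairs = []
    for egg in str(cell).split(";"):
        axes = egg.split("|")
        if len(axes) != 2:
            raise ValidationError(f"egg diameter entry {egg!r} does not have two axes")
        pairs.append((float(axes[0]), float(axes[1])))
    return pairs


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _coerce(df: pd.DataFrame, schema: dict, path: Path) -> pd.DataFrame:
    cols = schema["columns"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = df.loc[:, list(cols)].copy()
    for name, typ in cols.items():
        try:
            if typ is _DATETIME:
                out[name] = pd.to_datetime(out[name], format="ISO8601")
            elif typ is bool:
                out[name] = out[name].map(
                    {True: True, False: False, "True": True, "False": False,
                     "true": True, "false": False, 1: True, 0: False}
                )
                if out[name].isna().any():
                    row = int(out[name].isna().idxmax())
                    raise ValidationError(f"{path}: non-boolean value in '{name}'", row)
                out[name] = out[name].astype(bool)
            elif typ is str:
                opt = name in schema.get("optional", set())
                if opt:
                    out[name] = out[name].where(out[name].notna(), "")
                out[name] = out[name].astype(str)
            else:
                out[name] = out[name].astype(typ, errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column '{name}' not coercible to {typ}: {exc}")
    return out


def _first_bad_row(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def validate_records(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Check all type invariants of ``schema_name`` on an in-memory table."""
    if schema_name == "temperature":
        bad = (df["temp_c"] < 20) | (df["temp_c"] > 40) | df["temp_c"].isna()
        if bad.any():
            raise ValidationError("temp_c outside [20, 40] degC", _first_bad_row(bad))
        for tank, grp in df.groupby("tank_id", sort=False):
            if not grp["timestamp"].is_monotonic_increasing or grp["timestamp"].duplicated().any():
                raise ValidationError(
                    f"timestamps not strictly increasing within tank {tank}")
    elif schema_name == "health":
        bad = ~df["category"].isin(HEALTH_CATEGORIES)
        if bad.any():
            row = _first_bad_row(bad)
            raise ValidationError(
                f"unknown health category {df['category'].iloc[row]!r}", row)
        dup = df.duplicated(subset=["fragment_id", "survey_time"])
        if dup.any():
            raise ValidationError("fragment surveyed twice at one time",
                                  _first_bad_row(dup))
    elif schema_name == "size":
        for col in ("sa_cm2", "livesa_cm2", "volume_cm3"):
            bad = df[col] <= 0
            if bad.any():
                raise ValidationError(f"{col} must be > 0", _first_bad_row(bad))
        bad = df["diameter_cm"].notna() & (df["diameter_cm"] <= 0)
        if bad.any():
            raise ValidationError("diameter_cm must be > 0 when present",
                                  _first_bad_row(bad))
        bad = df["livesa_cm2"] > df["sa_cm2"] * (1 + 1e-9)
        if bad.any():
            raise ValidationError("livesa_cm2 exceeds sa_cm2", _first_bad_row(bad))
    elif schema_name == "dissection":
        bad = df["egg_count"] < 0
        if bad.any():
            raise ValidationError("egg_count must be >= 0", _first_bad_row(bad))
        for row, rec in enumerate(df.itertuples(index=False)):
            pairs = decode_egg_diameters(rec.egg_diameters_mm)
            if len(pairs) != rec.egg_count:
                raise ValidationError(
                    f"{len(pairs)} diameter entries for egg_count {rec.egg_count}",
                    row)
            for a, b in pairs:
                if not (0 < a < 2 and 0 < b < 2):
                    raise ValidationError(
                        f"egg diameter outside (0, 2) mm: {a}, {b}", row)
    elif schema_name == "symbiont":
        bad = (df["relative_abundance"] < 0) | (df["relative_abundance"] > 1)
        if bad.any():
            raise ValidationError("relative_abundance outside [0, 1]",
                                  _first_bad_row(bad))
        sums = df.groupby("colony_id")["relative_abundance"].sum()
        off = sums[(sums - 1).abs() > 1e-6]
        if len(off):
            raise ValidationError(
                f"colony {off.index[0]} abundances sum to {off.iloc[0]:.6f}, not 1")
    elif schema_name == "polyp_density":
        bad = df["polyps_per_cm2"] <= 0
        if bad.any():
            raise ValidationError("polyps_per_cm2 must be > 0", _first_bad_row(bad))
    else:
        raise SchemaError(f"unknown schema '{schema_name}'")
    return df


def read_table(path: str | Path, schema_name: str,
               column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited text file and validate it against a named schema.

    Parameters
    ----------
    path
        CSV (``.csv``) or TSV (``.tsv``) file with a header row.
    schema_name
        One of ``temperature, health, size, dissection, symbiont,
        polyp_density``.
    column_map
        Optional mapping from canonical column names to the names used in
        the file, for interoperating with externally deposited tables.
    """
    path = Path(path)
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema_name}'")
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    df = _coerce(raw, SCHEMAS[schema_name], path)
    return validate_records(df, schema_name)


def write_results(records: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as CSV/TSV with a stable column order.

    ``read_table(write_results(df, p), schema)`` is the identity on the
    shared input schemas (floats preserved to full repr precision; NaN
    serialized as an empty cell).
    """
    path = Path(path)
    if records is None or len(records) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep=_sep_for(path), index=False)
    return path
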