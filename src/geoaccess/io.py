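"""Readers and writers for facility/enrollee tables (CSV, GeoJSON) and polygons.

CSV dialect: comma-separated, UTF-8, header row required.  Booleans are
accepted case-insensitively as true/false, 1/0 or yes/no and written back
as ``true``/``false``.  GeoJSON follows RFC 7946: point features carry the
tabular attributes as properties and coordinates in (x, y) order; the
format is plain JSON, written and parsed with the standard library.

Ids are opaque strings — ``007`` and ``7`` are different facilities.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .types import (
    ENROLLEE_COLUMNS,
    FACILITY_COLUMNS,
    LGA_COLUMNS,
    CARE_LEVELS,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_facilities",
    "read_enrollees",
    "read_lga_table",
    "write_facilities",
    "write_enrollees",
    "write_geojson",
    "read_geojson",
    "polygon_area",
    "validate_facilities",
    "validate_enrollees",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {column}={value!r}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def _check_coords(df: pd.DataFrame, what: str) -> None:
    xy = df[["x", "y"]].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(xy).all(axis=1))
    if bad.size:
        raise ValidationError(f"{what} table has non-finite coordinates at row index {bad[0]}")


def _check_unique_ids(df: pd.DataFrame, what: str) -> None:
    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{what} table has duplicate id(s): {', '.join(map(str, dup))}")


def validate_facilities(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a facility table in place; returns the table.

    Enforces: required columns, unique ids, finite planar coordinates,
    care level one of primary/secondary/tertiary, boolean accreditation flag.
    """
    _require_columns(df, FACILITY_COLUMNS, "facility")
    df = df.copy()
    df["id"] = df["id"].astype(str)
    df["name"] = df["name"].astype(str)
    df["lga"] = df["lga"].astype(str)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    _check_unique_ids(df, "facility")
    _check_coords(df, "facility")
    df["level"] = df["level"].astype(str).str.strip().str.lower()
    bad = df.index[~df["level"].isin(CARE_LEVELS)]
    if len(bad):
        raise ValidationError(
            f"facility row {bad[0]}: level must be one of {CARE_LEVELS}, "
            f"got {df.loc[bad[0], 'level']!r}"
        )
    df["nhis_accredited"] = [
        _parse_bool(v, "nhis_accredited", i) for i, v in enumerate(df["nhis_accredited"])
    ]
    return df[FACILITY_COLUMNS + [c for c in df.columns if c not in FACILITY_COLUMNS]]


def validate_enrollees(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an enrollee table; used_facility_id must be non-empty.

    Whether each used_facility_id resolves against a facility table is
    checked at analysis time (accessibility.assign_nearest), not here.
    """
    _require_columns(df, ENROLLEE_COLUMNS, "enrollee")
    df = df.copy()
    df["id"] = df["id"].astype(str)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df["used_facility_id"] = df["used_facility_id"].fillna("").astype(str)
    _check_unique_ids(df, "enrollee")
    _check_coords(df, "enrollee")
    empty = df.index[df["used_facility_id"].str.strip() == ""]
    if len(empty):
        raise ValidationError(f"enrollee row {empty[0]}: used_facility_id is empty")
    return df[ENROLLEE_COLUMNS + [c for c in df.columns if c not in ENROLLEE_COLUMNS]]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".geojson", ".json"}:
        return "geojson"
    return "csv"


def read_facilities(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a facility table from CSV or GeoJSON; row order is preserved."""
    path = Path(path)
    if _infer_format(path, fmt) == "geojson":
        df = read_geojson(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_facilities(df)


def read_enrollees(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read an enrollee table from CSV or GeoJSON; row order is preserved."""
    path = Path(path)
    if _infer_format(path, fmt) == "geojson":
        df = read_geojson(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_enrollees(df)


def read_lga_table(path) -> pd.DataFrame:
    """Read an administrative-area summary table (one row per LGA)."""
    df = pd.read_csv(path)
    _require_columns(df, LGA_COLUMNS, "LGA")
    df = df.copy()
    df["stratum"] = df["stratum"].astype(str).str.strip().str.lower()
    bad = df.index[~df["stratum"].isin(["urban", "semiurban"])]
    if len(bad):
        raise ValidationError(f"LGA row {bad[0]}: stratum must be 'urban' or 'semiurban'")
    counts = [
        "population",
        "facilities_primary",
        "facilities_secondary",
        "facilities_tertiary",
        "nhis_facilities",
        "enrollees",
    ]
    for c in counts:
        df[c] = pd.to_numeric(df[c]).astype(int)
        if (df[c] < 0).any():
            raise ValidationError(f"LGA column {c} has a negative count")
    over = df["nhis_facilities"] > df["facilities_secondary"] + df["facilities_tertiary"]
    if over.any():
        raise ValidationError(
            "accredited facilities exceed secondary+tertiary count for LGA(s): "
            + ", ".join(df.loc[over, "name"].astype(str))
        )
    return df


def _bool_str(b) -> str:
    return "true" if b else "false"


def write_facilities(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    df = validate_facilities(df)
    if _infer_format(path, fmt) == "geojson":
        write_geojson(df, path, kind="facility")
        return
    out = df[FACILITY_COLUMNS].copy()
    out["nhis_accredited"] = out["nhis_accredited"].map(_bool_str)
    out.to_csv(path, index=False)


def write_enrollees(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    df = validate_enrollees(df)
    if _infer_format(path, fmt) == "geojson":
        write_geojson(df, path, kind="enrollee")
        return
    df[ENROLLEE_COLUMNS].to_csv(path, index=False)


def _point_feature(x: float, y: float, properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        "properties": properties,
    }


def write_geojson(records, path, kind: Optional[str] = None) -> None:
    """Write records as an RFC 7946 FeatureCollection.

    ``records`` may be a facility table, an enrollee table (Point features
    whose non-coordinate columns become properties) or an iterable of
    ready-made Feature dicts (used for hub lines).
    """
    features: list[dict]
    if isinstance(records, pd.DataFrame):
        if kind is None:
            kind = "facility" if "level" in records.columns else "enrollee"
        cols = FACILITY_COLUMNS if kind == "facility" else ENROLLEE_COLUMNS
        props = [c for c in cols if c not in ("x", "y")]
        features = [
            _point_feature(row["x"], row["y"], {c: _jsonable(row[c]) for c in props})
            for _, row in records.iterrows()
        ]
    else:
        features = list(records)
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection), encoding="utf-8")


def _jsonable(v):
    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


def read_geojson(path) -> pd.DataFrame:
    """Read a Point FeatureCollection back into a table (properties + x, y)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for feat in data.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError(f"{path}: only Point features can be read as a table")
        x, y = geom["coordinates"][:2]
        row = dict(feat.get("properties") or {})
        row["x"] = x
        row["y"] = y
        rows.append(row)
    return pd.DataFrame(rows)


def polygon_area(polygon) -> float:
    """Absolute planar area of a polygon in m², holes subtracted.

    Accepts a shapely geometry, a single ring (sequence of (x, y) vertices,
    closed or open), or a (shell, [hole, ...]) pair.  Orientation does not
    matter.  Fewer than three distinct vertices is an error.
    """
    if isinstance(polygon, BaseGeometry):
        return abs(polygon.area)
    seq = list(polygon)
    if len(seq) == 2 and seq and not _is_vertex(seq[0]):
        shell, holes = seq
    elif seq and _is_vertex(seq[0]):
        shell, holes = seq, []
    else:
        shell, holes = (seq[0] if seq else []), seq[1:]
    shell = [tuple(map(float, v)) for v in shell]
    distinct = {v for v in shell}
    if len(distinct) < 3:
        raise ValidationError("polygon needs at least 3 distinct vertices")
    poly = Polygon(shell, [list(h) for h in holes])
    area = abs(poly.area)
    if not math.isfinite(area):
        raise ValidationError("polygon area is not finite")
    return area


def _is_vertex(obj) -> bool:
    try:
        return len(obj) == 2 and all(isinstance(float(c), float) for c in obj)
    except (TypeError, ValueError):
        return False
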