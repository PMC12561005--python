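"""Reading and writing cell tables (CSV) and region geometries (GeoJSON).

Cell tables use a fixed CSV schema — required columns ``cell_id, x_um,
y_um, cell_type``; optional ``marker, parent_id``; comma delimiter, ``.``
decimal point, mandatory header. Geometries are RFC 7946 GeoJSON
FeatureCollections whose features are tagged with a ``role`` property:
``interface`` (LineString), ``stromal_band``, ``tumor_nest`` (repeatable)
and ``bone`` (Polygons). Both formats round-trip exactly (coordinates via
repr, so to the last bit).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape

from .cells import CELL_COLUMNS, CellTable, CellType, Marker
from .errors import GeometryError, IntegrityError, RowParseError, SchemaError
from .geometry import TissueGeometry

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_geometry",
    "write_geometry",
]

REQUIRED_COLUMNS = ["cell_id", "x_um", "y_um", "cell_type"]

PathOrStream = Union[str, Path, IO[str]]


def read_cell_table(source: PathOrStream) -> CellTable:
    """Parse and validate a cell-coordinate CSV into a :class:`CellTable`.

    Raises
    ------
    SchemaError: a required column is missing (named in the message).
    RowParseError: a coordinate fails to parse; carries the 1-based file
        line number (header is line 1).
    IntegrityError: duplicate ``cell_id`` or a cell type / marker outside
        the closed vocabulary (allowed values are listed).
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals.fillna(np.inf))
        if bad.any():
            i = int(bad.idxmax())
            raise RowParseError(
                line=i + 2,
                message=f"column '{col}' value {df.loc[i, col]!r} is not a finite number",
            )
        df[col] = vals.astype(float)
    if "marker" not in df.columns:
        df["marker"] = Marker.NONE.value
    else:
        df["marker"] = df["marker"].replace("", Marker.NONE.value)
    if "parent_id" not in df.columns:
        df["parent_id"] = pd.NA
    else:
        df["parent_id"] = df["parent_id"].replace("", pd.NA)
    return CellTable(df[CELL_COLUMNS])


def write_cell_table(table: CellTable, sink: PathOrStream) -> None:
    """Write one header line plus one line per record, in table order."""
    df = table.df.copy()
    df["parent_id"] = df["parent_id"].fillna("")
    text = df.to_csv(index=False, lineterminator="\n")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


# ---------------------------------------------------------------------------
# GeoJSON geometry
# ---------------------------------------------------------------------------

_ROLES = {"interface", "stromal_band", "tumor_nest", "bone"}


def _feature(geom, role: str) -> dict:
    return {"type": "Feature", "properties": {"role": role}, "geometry": mapping(geom)}


def write_geometry(geom: TissueGeometry, sink: PathOrStream) -> None:
    """Serialize a :class:`TissueGeometry` as a role-tagged FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "frame": {"width": geom.frame_width, "height": geom.frame_height},
        "features": [
            _feature(geom.interface, "interface"),
            _feature(geom.stromal_band, "stromal_band"),
            *[_feature(n, "tumor_nest") for n in geom.tumor_nests],
            _feature(geom.bone_region, "bone"),
        ],
    }
    text = json.dumps(fc, indent=1)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def read_geometry(source: PathOrStream) -> TissueGeometry:
    """Parse a role-tagged GeoJSON FeatureCollection into a TissueGeometry.

    Raises SchemaError when a feature lacks a ``role`` or a required role
    is absent, and GeometryError for invalid (self-intersecting) polygons.
    """
    if hasattr(source, "read"):
        fc = json.load(source)
    else:
        fc = json.loads(Path(source).read_text())
    if fc.get("type") != "FeatureCollection":
        raise SchemaError("geometry file is not a GeoJSON FeatureCollection")
    by_role: dict[str, list] = {r: [] for r in _ROLES}
    for feat in fc.get("features", []):
        role = (feat.get("properties") or {}).get("role")
        if role is None:
            raise SchemaError("feature missing the 'role' property")
        if role not in _ROLES:
            raise SchemaError(
                f"unknown role {role!r}; allowed: {sorted(_ROLES)}"
            )
        g = shape(feat["geometry"])
        if isinstance(g, Polygon) and not g.is_valid:
            raise GeometryError(f"{role} polygon is invalid (self-intersecting?)")
        by_role[role].append(g)
    for required in ("interface", "stromal_band", "bone"):
        if not by_role[required]:
            raise SchemaError(f"missing required feature with role '{required}'")
    interface = by_role["interface"][0]
    if not isinstance(interface, LineString):
        raise SchemaError("interface feature must be a LineString")
    frame = fc.get("frame") or {}
    xs: list[float] = []
    ys: list[float] = []
    for geoms in by_role.values():
        for g in geoms:
            minx, miny, maxx, maxy = g.bounds
            xs += [minx, maxx]
            ys += [miny, maxy]
    width = float(frame.get("width", max(xs)))
    height = float(frame.get("height", max(ys)))
    return TissueGeometry(
        interface=interface,
        stromal_band=by_role["stromal_band"][0],
        tumor_nests=list(by_role["tumor_nest"]),
        bone_region=by_role["bone"][0],
        frame_width=width,
        frame_height=height,
    )
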